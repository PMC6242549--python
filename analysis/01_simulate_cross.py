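"""Generate the synthetic two-breed cross used by the downstream analyses.

Produces, under scratch/simdata: the gene annotation (GTF), parental WGS
genotypes (VCF), per-embryo RNA genotypes (VCF + sample sheet), stranded
read intervals per embryo (BED-like), and the planted truth table.

Run:  python analysis/01_simulate_cross.py [seed]
"""
import sys
from pathlib import Path

from zga_ase.simulate import SimConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    out = ROOT / "scratch" / "simdata"
    config = SimConfig(seed=seed)
    dataset = simulate_dataset(config, out)
    n_residual = sum(
        1
        for program in dataset.truth.gene_program.values()
        if program[config.biallelic_stage] == "maternal"
    )
    print(f"wrote synthetic cross to {out}")
    print(f"  genes: {len(dataset.annotation)} on {config.n_chromosomes} chromosomes")
    print(f"  breed-fixed SNP sites: {len(dataset.truth.sites)} "
          f"(+{config.n_shared_polymorphic_sites} shared-polymorphic decoys)")
    print(f"  embryos: {len(dataset.offspring)} "
          f"({len(config.stages)} stages x {config.n_offspring_replicates} replicates)")
    print(f"  origin program: maternal-only before {config.biallelic_stage}, "
          f"bi-allelic at {config.biallelic_stage}; {n_residual} genes stay maternal")
    print(f"  genotype error {config.genotype_error_rate}, RNA dropout {config.rna_dropout_rate}")


if __name__ == "__main__":
    main()
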
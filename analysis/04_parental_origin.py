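"""Call parental origin of expression per gene per stage from the cross.

Detects breed-specific SNPs in the parental genotypes, joins them with
per-embryo RNA genotypes, runs the three-step filter cascade, classifies
each surviving marker per stage, and summarises per gene. Compares the
gene-level calls against the generator's planted truth. Writes the marker
table, cascade report and gene summary to results/ase/.

Run:  python analysis/04_parental_origin.py   (after 01)
"""
import json
from collections import Counter
from pathlib import Path

from zga_ase.ase import AseConfig, run_ase
from zga_ase.simulate import SimConfig, parent_sample_ids

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sim = ROOT / "scratch" / "simdata"
    if not sim.exists():
        raise SystemExit("run analysis/01_simulate_cross.py first")
    config = SimConfig()  # sample naming layout only; data come from files
    maternal, paternal = parent_sample_ids(config)
    out_dir = ROOT / "results" / "ase"
    summaries, report, markers = run_ase(
        AseConfig(
            parents_vcf=sim / "parents.vcf",
            maternal_samples=maternal,
            paternal_samples=paternal,
            offspring_sheet=sim / "sample_sheet.tsv",
            gtf=sim / "annotation.gtf",
            out_dir=out_dir,
            stages=list(config.stages),
        )
    )
    print("filter cascade:", json.dumps(report.to_dict()))
    print(f"marker SNPs: {len(markers)}")
    for stage in config.stages:
        counts = Counter(markers[f"origin_{stage}"])
        print(f"  {stage:>8}: {dict(counts)}")
    called = [s for s in summaries if not s.filtered]
    filtered = Counter(s.filter_reason for s in summaries if s.filtered)
    print(f"genes with origin calls: {len(called)} "
          f"(filtered: {dict(filtered) or 'none'})")

    truth_path = sim / "truth.json"
    truth = json.loads(truth_path.read_text())["gene_program"]
    correct = sum(
        1
        for s in called
        if all(truth[s.gene_id][st] == o for st, o in s.stage_origin.items())
    )
    print(f"planted origin program recovered for {correct}/{len(called)} called genes")
    print(f"outputs under {out_dir}")


if __name__ == "__main__":
    main()
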
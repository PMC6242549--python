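"""Synthetic cross: annotation, parental genotypes, embryo RNA genotypes, reads.

The generator emulates the experimental design the pipeline was built for: a
two-breed chicken cross (three whole-genome-sequenced parents per breed),
with single F1 embryos sampled at five pre-oviposition stages (oocyte,
zygote, EGK.III, EGK.VI, EGK.X) and genotyped from RNA-seq. Ground truth is
planted at three levels:

* breed-fixed SNP sites inside gene spans, at which the two breeds are
  homozygous for opposite alleles (the offspring is then obligate
  heterozygous at the DNA level);
* a per-gene origin program: by default every gene expresses only the
  maternal allele through EGK.VI and becomes bi-allelic at EGK.X, with a
  small residual set that stays maternal throughout;
* per-read region-class labels for the stage-dependent primary-transcript
  (intronic) signal: low intronic fraction in the oocyte, elevated in the
  zygote (first activation wave), elevated again from EGK.VI (second wave),
  with a constant small intergenic fraction.

Everything is deterministic under the config seed, and every emitted file
is parseable by the corresponding consumer module.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneRecord, write_annotation_gtf
from .genotypes import (
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleInfo,
    merge_tables,
    write_vcf,
)
from .quantify import ReadRecord
from .regions import define_intergenic, define_introns, define_merged_exons

BASES = np.array(["A", "C", "G", "T"])

DEFAULT_STAGES = ("oocyte", "zygote", "EGK.III", "EGK.VI", "EGK.X")

#: stage-specific intronic read fractions: first wave at the zygote, second
#: wave from EGK.VI on; free parameters chosen to give a clear two-wave shape
DEFAULT_INTRON_FRACTIONS = {
    "oocyte": 0.05,
    "zygote": 0.25,
    "EGK.III": 0.10,
    "EGK.VI": 0.30,
    "EGK.X": 0.30,
}


@dataclass
class SimConfig:
    seed: int = 1
    n_chromosomes: int = 2
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    intergenic_gap: tuple[int, int] = (200, 1000)
    n_overlapping_gene_pairs: int = 1
    lincrna_fraction: float = 0.2
    n_breed_fixed_sites: int = 300
    n_shared_polymorphic_sites: int = 100
    n_parent_replicates: int = 3
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_offspring_replicates: int = 3
    genotype_error_rate: float = 0.0
    rna_dropout_rate: float = 0.0
    residual_maternal_fraction: float = 0.05
    biallelic_stage: str = "EGK.X"
    intron_read_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_FRACTIONS)
    )
    intergenic_read_fraction: float = 0.02
    reads_per_sample: int = 2000
    read_length: int = 150

    def __post_init__(self) -> None:
        for rate in (
            self.genotype_error_rate,
            self.rna_dropout_rate,
            self.residual_maternal_fraction,
            self.intergenic_read_fraction,
            self.lincrna_fraction,
            *self.intron_read_fraction.values(),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if min(self.n_genes, self.n_breed_fixed_sites, self.reads_per_sample) <= 0:
            raise ValueError("counts must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        # independent deterministic stream per generator stage
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class SiteTruth:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    orientation: str  # "ref_maternal" | "alt_maternal"

    @property
    def maternal_allele(self) -> str:
        return self.ref if self.orientation == "ref_maternal" else self.alt


@dataclass
class TruthTable:
    """Planted ground truth every emitted record traces back to."""

    gene_program: dict[str, dict[str, str]] = field(default_factory=dict)
    sites: dict[tuple[str, int], SiteTruth] = field(default_factory=dict)
    read_class: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_program": self.gene_program,
            "sites": {
                f"{c}:{p}": asdict(t) for (c, p), t in sorted(self.sites.items())
            },
            "read_class": self.read_class,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> AnnotationSet:
    """Multi-exon genes laid out left to right, a few with a second transcript
    whose exon structure overlaps the first (exercises exon merging), and
    ``n_overlapping_gene_pairs`` gene pairs that overlap each other on
    opposite strands (exercises intergenic merging)."""
    rng = config.rng(11)
    annotation = AnnotationSet(source_build="synthetic")
    genes_per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    overlap_budget = config.n_overlapping_gene_pairs
    gene_index = 0
    for chrom_i, n_genes in enumerate(genes_per_chrom):
        chrom = f"chr{chrom_i + 1}"
        cursor = 1000
        prev_span: tuple[int, int] | None = None
        for _ in range(n_genes):
            make_overlap = overlap_budget > 0 and prev_span is not None
            if make_overlap:
                overlap_budget -= 1
                cursor = prev_span[0] + (prev_span[1] - prev_span[0]) // 2
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = []
            pos = cursor
            for exon_i in range(n_exons):
                length = int(rng.integers(*config.exon_length))
                exons.append((pos, pos + length))
                pos += length
                if exon_i < n_exons - 1:
                    pos += int(rng.integers(*config.intron_length))
            strand = "+" if rng.random() < 0.5 else "-"
            if make_overlap and prev_span is not None:
                strand = "-" if annotation.genes[f"gene{gene_index - 1:04d}"].strand == "+" else "+"
            gene_id = f"gene{gene_index:04d}"
            biotype = "lincRNA" if rng.random() < config.lincrna_fraction else "mRNA"
            transcripts = {f"{gene_id}.t1": list(exons)}
            if n_exons >= 3 and rng.random() < 0.4:
                # skipped internal exon: overlapping structure, same exon union
                skip = int(rng.integers(1, n_exons - 1))
                transcripts[f"{gene_id}.t2"] = [e for i, e in enumerate(exons) if i != skip]
            annotation.genes[gene_id] = GeneRecord(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                biotype=biotype,
                transcripts=transcripts,
            )
            prev_span = (exons[0][0], exons[-1][1])
            cursor = max(cursor, prev_span[1]) + int(rng.integers(*config.intergenic_gap))
            gene_index += 1
    return annotation


# ---------------------------------------------------------------------------
# parental genotypes


def parent_sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    """Maternal-breed and paternal-breed WGS sample names (hens fWL, cocks mKO)."""
    maternal = [f"fWL{i + 1}" for i in range(config.n_parent_replicates)]
    paternal = [f"mKO{i + 1}" for i in range(config.n_parent_replicates)]
    return maternal, paternal


def _corrupt(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-call corruption to a uniformly chosen different genotype."""
    if error_rate <= 0:
        return codes
    out = codes.copy()
    flat = out.ravel()
    hit = np.flatnonzero((rng.random(flat.size) < error_rate) & (flat != MISSING))
    if hit.size:
        shift = rng.integers(1, 3, size=hit.size)  # +1 or +2 mod 3 is always different
        flat[hit] = (flat[hit] + shift) % 3
    return out


def simulate_parent_genotypes(
    config: SimConfig, annotation: AnnotationSet
) -> tuple[GenotypeTable, TruthTable]:
    """Breed-fixed sites inside gene spans plus shared-polymorphic decoys.

    Breed-fixed sites are spread evenly over genes so every gene has enough
    markers for a gene-level call; decoy sites always include at least one
    heterozygous parent, so by construction they are never breed-specific.
    """
    rng = config.rng(22)
    genes = sorted(annotation.genes.values(), key=lambda g: g.gene_id)
    per_gene = config.n_breed_fixed_sites // len(genes)
    extra = config.n_breed_fixed_sites % len(genes)
    if per_gene == 0:
        raise ValueError("fewer breed-fixed sites than genes; every gene needs markers")

    maternal_ids, paternal_ids = parent_sample_ids(config)
    truth = TruthTable()
    rows: dict[tuple, np.ndarray] = {}
    n_parents = 2 * config.n_parent_replicates

    used: set[tuple[str, int]] = set()
    for i, gene in enumerate(genes):
        span = gene.span
        n_sites = per_gene + (1 if i < extra else 0)
        if len(span) < n_sites:
            raise ValueError(f"gene {gene.gene_id} span too short for {n_sites} sites")
        positions = rng.choice(len(span), size=n_sites, replace=False) + span.start
        for pos in sorted(int(p) for p in positions):
            if (gene.chrom, pos) in used:
                continue
            used.add((gene.chrom, pos))
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt = BASES[ref], BASES[alt]
            orientation = "ref_maternal" if rng.random() < 0.5 else "alt_maternal"
            maternal_code = HOM_REF if orientation == "ref_maternal" else HOM_ALT
            paternal_code = HOM_ALT if orientation == "ref_maternal" else HOM_REF
            codes = np.array(
                [maternal_code] * config.n_parent_replicates
                + [paternal_code] * config.n_parent_replicates,
                dtype=np.int8,
            )
            rows[(gene.chrom, pos, str(ref), str(alt))] = codes
            truth.sites[(gene.chrom, pos)] = SiteTruth(
                gene.chrom, pos, str(ref), str(alt), gene.gene_id, orientation
            )

    # decoys: shared polymorphisms, never breed-fixed (>=1 het parent)
    chrom_extents = {}
    for gene in genes:
        span = gene.span
        lo, hi = chrom_extents.get(gene.chrom, (span.start, span.end))
        chrom_extents[gene.chrom] = (min(lo, span.start), max(hi, span.end))
    chroms = sorted(chrom_extents)
    for _ in range(config.n_shared_polymorphic_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = chrom_extents[chrom]
        pos = int(rng.integers(lo, hi))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        codes = rng.integers(0, 3, size=n_parents).astype(np.int8)
        codes[int(rng.integers(n_parents))] = HET
        rows[(chrom, pos, str(BASES[ref]), str(BASES[alt]))] = codes

    codes = _corrupt(np.vstack(list(rows.values())), config.genotype_error_rate, rng)
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["chrom", "pos", "ref", "alt"])
    calls = pd.DataFrame(codes, index=index, columns=maternal_ids + paternal_ids, dtype=np.int8).sort_index()
    samples = {
        **{s: SampleInfo(s, "maternal_parent") for s in maternal_ids},
        **{s: SampleInfo(s, "paternal_parent") for s in paternal_ids},
    }
    return GenotypeTable(calls, samples), truth


# ---------------------------------------------------------------------------
# origin program and offspring RNA genotypes


def plant_origin_program(config: SimConfig, annotation: AnnotationSet) -> dict[str, dict[str, str]]:
    """Default program: maternal-only until ``biallelic_stage``, then
    bi-allelic; a residual fraction of genes stays maternal at every stage."""
    rng = config.rng(33)
    program: dict[str, dict[str, str]] = {}
    gene_ids = sorted(annotation.genes)
    n_residual = int(round(config.residual_maternal_fraction * len(gene_ids)))
    residual = set(
        rng.choice(len(gene_ids), size=n_residual, replace=False).tolist()
    ) if n_residual else set()
    for i, gene_id in enumerate(gene_ids):
        program[gene_id] = {
            stage: (
                "maternal"
                if (i in residual or stage != config.biallelic_stage)
                else "biallelic"
            )
            for stage in config.stages
        }
    return program


_ORIGIN_CODE = {
    ("maternal", "ref_maternal"): HOM_REF,
    ("maternal", "alt_maternal"): HOM_ALT,
    ("paternal", "ref_maternal"): HOM_ALT,
    ("paternal", "alt_maternal"): HOM_REF,
}


def true_genotype_code(origin: str, orientation: str) -> int:
    """RNA genotype implied by an origin call at a breed-fixed site."""
    if origin == "biallelic":
        return HET
    return _ORIGIN_CODE[(origin, orientation)]


def offspring_sample_ids(config: SimConfig) -> list[tuple[str, str, int]]:
    """(sample_id, stage, replicate) for every embryo, in deterministic order."""
    return [
        (f"{stage}_r{rep + 1}", stage, rep + 1)
        for stage in config.stages
        for rep in range(config.n_offspring_replicates)
    ]


def simulate_offspring_rna(
    config: SimConfig, truth: TruthTable
) -> dict[str, GenotypeTable]:
    """Per-embryo RNA genotype tables driven by the planted origin program.

    Each expressed site's genotype follows the gene's origin at the embryo's
    stage (the oocyte transcriptome is maternal by construction), then is
    corrupted at ``genotype_error_rate`` and thinned at ``rna_dropout_rate``
    (dropout removes the site from that embryo's callset, emulating SNP
    dropout in RNA-derived genotyping).
    """
    rng = config.rng(44)
    site_keys = sorted(truth.sites)
    tables: dict[str, GenotypeTable] = {}
    for sample_id, stage, rep in offspring_sample_ids(config):
        codes = np.empty(len(site_keys), dtype=np.int8)
        for i, key in enumerate(site_keys):
            site = truth.sites[key]
            origin = (
                "maternal"
                if stage == "oocyte"
                else truth.gene_program[site.gene_id][stage]
            )
            codes[i] = true_genotype_code(origin, site.orientation)
        codes = _corrupt(codes, config.genotype_error_rate, rng)
        if config.rna_dropout_rate > 0:
            # dropout removes the site from this embryo's callset entirely
            codes[rng.random(len(site_keys)) < config.rna_dropout_rate] = MISSING
        index = pd.MultiIndex.from_tuples(
            [
                (site.chrom, site.pos, site.ref, site.alt)
                for site in (truth.sites[k] for k in site_keys)
            ],
            names=["chrom", "pos", "ref", "alt"],
        )
        calls = pd.DataFrame({sample_id: codes}, index=index).sort_index()
        calls = calls[calls[sample_id] != MISSING]
        tables[sample_id] = GenotypeTable(
            calls, {sample_id: SampleInfo(sample_id, "offspring", stage, rep)}
        )
    return tables


# ---------------------------------------------------------------------------
# read intervals


def simulate_read_intervals(
    config: SimConfig, annotation: AnnotationSet, truth: TruthTable | None = None
) -> dict[str, list[ReadRecord]]:
    """Single-block stranded read intervals per embryo sample.

    Region class per read is drawn from the stage's intronic fraction, a
    constant intergenic fraction, and the exonic remainder; the read is
    placed uniformly inside a uniformly chosen region of that class, and its
    alignment strand follows the reverse-stranded (RF) library convention
    (opposite the region's annotated strand). Per-read class labels are
    recorded in the truth table when given.
    """
    rng = config.rng(55)
    catalogs = {
        "exon_merged": define_merged_exons(annotation).regions,
        "intron": define_introns(annotation).regions,
        "intergenic": define_intergenic(annotation).regions,
    }
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    for sample_id, stage, _ in offspring_sample_ids(config):
        p_intron = config.intron_read_fraction.get(stage, 0.0)
        p_inter = config.intergenic_read_fraction
        classes = rng.choice(
            ["intron", "intergenic", "exon_merged"],
            size=config.reads_per_sample,
            p=[p_intron, p_inter, 1.0 - p_intron - p_inter],
        )
        reads = []
        labels: dict[str, str] = {}
        for i, region_class in enumerate(classes):
            pool = catalogs[region_class]
            region = pool[int(rng.integers(len(pool)))]
            iv = region.interval
            length = min(config.read_length, len(iv))
            start = iv.start + int(rng.integers(0, len(iv) - length + 1))
            if iv.strand in "+-":
                strand = "-" if iv.strand == "+" else "+"  # RF: read1 antisense
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            read_id = f"{sample_id}.r{i:06d}"
            reads.append(ReadRecord(read_id, iv.chrom, [(start, start + length)], strand))
            labels[read_id] = str(region_class)
        reads_by_sample[sample_id] = reads
        if truth is not None:
            truth.read_class[sample_id] = labels
    return reads_by_sample


def write_reads_bed(reads: list[ReadRecord], path: str | Path) -> None:
    lines = [
        f"{read.chrom}\t{start}\t{end}\t{read.strand}\t{read.read_id}"
        for read in reads
        for start, end in read.blocks
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: AnnotationSet
    parents: GenotypeTable
    offspring: dict[str, GenotypeTable]
    reads: dict[str, list[ReadRecord]]
    truth: TruthTable
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def rna(self) -> GenotypeTable:
        return merge_tables(list(self.offspring.values()))


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate the full synthetic cross; optionally write every file.

    Written layout: ``annotation.gtf``, ``parents.vcf``,
    ``offspring/<sample>.vcf``, ``sample_sheet.tsv``, ``reads/<sample>.bed``
    and ``truth.json``.
    """
    annotation = simulate_annotation(config)
    parents, truth = simulate_parent_genotypes(config, annotation)
    truth.gene_program = plant_origin_program(config, annotation)
    offspring = simulate_offspring_rna(config, truth)
    reads = simulate_read_intervals(config, annotation, truth)
    dataset = SimulatedDataset(config, annotation, parents, offspring, reads, truth)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "offspring").mkdir(parents=True, exist_ok=True)
        (out / "reads").mkdir(parents=True, exist_ok=True)
        write_annotation_gtf(annotation, out / "annotation.gtf")
        write_vcf(parents, out / "parents.vcf")
        sheet_rows = []
        for sample_id in sorted(offspring):
            info = offspring[sample_id].samples[sample_id]
            vcf_path = out / "offspring" / f"{sample_id}.vcf"
            write_vcf(offspring[sample_id], vcf_path)
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "role": "offspring",
                    "stage": info.stage,
                    "replicate": info.replicate,
                    "vcf": f"offspring/{sample_id}.vcf",
                }
            )
        pd.DataFrame(sheet_rows).to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        for sample_id in sorted(reads):
            write_reads_bed(reads[sample_id], out / "reads" / f"{sample_id}.bed")
        truth.to_json(out / "truth.json")
        dataset.paths = {
            "gtf": out / "annotation.gtf",
            "parents_vcf": out / "parents.vcf",
            "sample_sheet": out / "sample_sheet.tsv",
            "truth": out / "truth.json",
        }
    return dataset


# ---------------------------------------------------------------------------
# evaluation against planted truth


def true_origin(truth: TruthTable, site_key: tuple[str, int], stage: str) -> str:
    """Planted origin for a breed-fixed site at a stage (oocytes are maternal)."""
    if stage == "oocyte":
        return "maternal"
    return truth.gene_program[truth.sites[site_key].gene_id][stage]


def measure_site_calls(truth: TruthTable, surviving_sites, stages) -> dict[str, int]:
    """Compare surviving site-level origin calls against the planted program.

    Returns counts of determined stage calls and of miscalls among them.
    """
    from .ase import classify_site_origin

    n_calls = n_miscalls = 0
    for site in surviving_sites:
        key = (site.snp.chrom, site.snp.pos)
        if key not in truth.sites:
            continue
        for stage in stages:
            call = classify_site_origin(site, stage)
            if call == "undetermined":
                continue
            n_calls += 1
            if call != true_origin(truth, key, stage):
                n_miscalls += 1
    return {"n_calls": n_calls, "n_miscalls": n_miscalls}


def measure_gene_recovery(truth: TruthTable, summaries) -> dict[str, int]:
    """How many unfiltered genes carry exactly the planted per-stage program."""
    n_called = n_correct = 0
    for summary in summaries:
        if summary.filtered:
            continue
        n_called += 1
        program = truth.gene_program[summary.gene_id]
        determined = {
            stage: origin
            for stage, origin in summary.stage_origin.items()
            if origin != "undetermined"
        }
        if determined and all(program[s] == o for s, o in determined.items()):
            n_correct += 1
    return {"n_called": n_called, "n_correct": n_correct}


# ---------------------------------------------------------------------------
# independent Monte-Carlo oracle for the error-rate property


def predict_miscall_rate(
    error_rate: float,
    config: SimConfig,
    n_sim: int = 20000,
    seed: int = 12345,
) -> tuple[float, float]:
    """Direct Monte-Carlo prediction of the post-filter site miscall rate.

    Simulates ``n_sim`` independent sites through the genotype-corruption and
    filtering *process* (not through the pipeline code): per stage, each of
    the replicate calls is corrupted with probability ``error_rate`` to a
    uniformly chosen different genotype; a site is discarded when any stage's
    replicates disagree or the concordant oocyte genotype is not homozygous
    maternal; surviving concordant stage calls are compared with the planted
    genotype. Returns (miscall rate among surviving determined stage calls,
    site survival rate). Genes are assumed maternal at every stage except the
    bi-allelic stage of the default program.
    """
    rng = np.random.default_rng(seed)
    stages = list(config.stages)
    n_rep = config.n_offspring_replicates
    true_codes = np.array(
        [HET if s == config.biallelic_stage else HOM_REF for s in stages]
    )  # orientation is symmetric; WLOG maternal allele = ref
    oocyte_i = stages.index("oocyte")

    calls = np.broadcast_to(true_codes[None, :, None], (n_sim, len(stages), n_rep)).copy()
    err = rng.random(calls.shape) < error_rate
    shift = rng.integers(1, 3, size=calls.shape)
    calls = np.where(err, (calls + shift) % 3, calls)

    concordant = (calls == calls[:, :, :1]).all(axis=2)
    site_ok = concordant.all(axis=1)
    stage_call = calls[:, :, 0]
    site_ok &= stage_call[:, oocyte_i] == HOM_REF  # maternal-oocyte concordance

    surviving = stage_call[site_ok]
    truth = np.broadcast_to(true_codes, surviving.shape)
    n_calls = surviving.size
    miscall = float((surviving != truth).sum() / n_calls) if n_calls else 0.0
    return miscall, float(site_ok.mean())
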
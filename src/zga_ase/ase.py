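"""Parental-origin calling from breed-specific SNPs in an F1 hybrid cross.

A site fixed for opposite homozygous genotypes in the two parental breeds is
a breed-specific SNP: the offspring of the cross is obligate heterozygous
there at the DNA level, so a *homozygous* RNA-derived genotype in an embryo
is evidence of mono-allelic expression, and which allele is present tells
the parental origin. The pipeline joins breed-specific SNPs (parental WGS
genotypes) with offspring RNA-derived genotypes, applies an ordered
three-step filter cascade

  1. allele mismatch — the DNA and RNA callsets disagree on ref/alt at the
     position;
  2. replicate discordance — within any developmental stage the biological
     replicates' genotypes differ;
  3. maternal–oocyte mismatch — the oocyte RNA genotype contains an allele
     the maternal DNA genotype lacks (the oocyte transcriptome is maternal
     by construction, so anything else flags a bad site);

and then classifies each surviving site per stage (hom maternal allele ->
maternal, het -> biallelic, hom paternal allele -> paternal). Gene-level
calls require at least two supporting SNPs that agree at every shared
stage, and SNPs not overlapping exactly one annotated gene span are
dropped.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import AnnotationSet, read_annotation
from .genotypes import (
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SampleInfo,
    merge_tables,
    read_vcf,
)

logger = logging.getLogger(__name__)

ORIGINS = ("maternal", "paternal", "biallelic", "undetermined")
FILTER_STEPS = ("allele_mismatch", "replicate_discordance", "maternal_oocyte_mismatch")
FILTER_REASONS = ("single_snp", "inconsistent_pattern", "unannotated", "none")

OOCYTE_STAGE = "oocyte"


@dataclass(frozen=True)
class BreedSpecificSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    maternal_allele: str
    paternal_allele: str
    orientation: str  # "ref_maternal" | "alt_maternal"

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError("parental alleles must differ")
        if {self.maternal_allele, self.paternal_allele} != {self.ref, self.alt}:
            raise ValueError("parental alleles must be the site's ref and alt")


@dataclass
class CombinedSite:
    """A breed-specific SNP joined with every offspring RNA genotype."""

    snp: BreedSpecificSnp
    rna_ref: str
    rna_alt: str
    # (stage, replicate) -> genotype code; includes oocyte samples
    offspring_calls: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def maternal_dna_call(self) -> int:
        return HOM_REF if self.snp.orientation == "ref_maternal" else HOM_ALT

    def stage_calls(self, stage: str) -> list[int]:
        return [
            code
            for (s, _), code in sorted(self.offspring_calls.items())
            if s == stage and code != MISSING
        ]

    def stages(self) -> list[str]:
        seen: list[str] = []
        for stage, _ in sorted(self.offspring_calls):
            if stage not in seen:
                seen.append(stage)
        return seen


@dataclass
class CascadeReport:
    n_input: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {s: 0 for s in FILTER_STEPS})
    n_surviving: int = 0
    removed_sites: dict[str, list[tuple[str, int]]] = field(
        default_factory=lambda: {s: [] for s in FILTER_STEPS}
    )

    def check_conservation(self) -> bool:
        return self.n_input == sum(self.removed.values()) + self.n_surviving

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            **{f"removed_{step}": n for step, n in self.removed.items()},
            "n_surviving": self.n_surviving,
        }

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        frame = pd.DataFrame(
            [{"step": k, "count": v} for k, v in self.to_dict().items()]
        )
        frame.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class GeneOriginSummary:
    gene_id: str
    biotype: str
    stage_origin: dict[str, str]  # stage -> origin
    n_snps: int
    filtered: bool = False
    filter_reason: str = "none"


# ---------------------------------------------------------------------------
# breed-specific SNP detection


def call_breed_specific_snps(
    dna: GenotypeTable, maternal_ids: list[str], paternal_ids: list[str]
) -> list[BreedSpecificSnp]:
    """Sites fixed for opposite homozygous genotypes between the breeds.

    Admissible configurations: all maternal samples 0/0 with all paternal
    1/1 (maternal allele = ref), or all maternal 1/1 with all paternal 0/0
    (maternal allele = alt). Any heterozygous or missing parental call
    excludes the site.
    """
    if not maternal_ids or not paternal_ids:
        raise ValueError("need at least one sample per parental group")
    for sample_id in (*maternal_ids, *paternal_ids):
        if sample_id not in dna.calls.columns:
            raise KeyError(f"sample {sample_id!r} not present in the genotype table")

    maternal = dna.calls[maternal_ids]
    paternal = dna.calls[paternal_ids]
    ref_maternal = (maternal == HOM_REF).all(axis=1) & (paternal == HOM_ALT).all(axis=1)
    alt_maternal = (maternal == HOM_ALT).all(axis=1) & (paternal == HOM_REF).all(axis=1)

    snps = []
    for (chrom, pos, ref, alt), is_ref_m, is_alt_m in zip(
        dna.calls.index, ref_maternal, alt_maternal
    ):
        if not (is_ref_m or is_alt_m):
            continue
        orientation = "ref_maternal" if is_ref_m else "alt_maternal"
        maternal_allele = ref if is_ref_m else alt
        paternal_allele = alt if is_ref_m else ref
        snps.append(
            BreedSpecificSnp(chrom, pos, ref, alt, maternal_allele, paternal_allele, orientation)
        )
    logger.info(
        "breed-specific SNPs: %d of %d parental sites", len(snps), len(dna.calls)
    )
    return sorted(snps, key=lambda s: (s.chrom, s.pos))


def join_offspring(
    breed_snps: list[BreedSpecificSnp], rna: GenotypeTable
) -> list[CombinedSite]:
    """Join on chrom+pos: only sites called in BOTH datasets survive.

    The RNA callset's own ref/alt at the position is recorded so the
    allele-mismatch filter can compare the two callsets.
    """
    rna_by_pos: dict[tuple[str, int], tuple[str, str]] = {}
    for chrom, pos, ref, alt in rna.calls.index:
        rna_by_pos[(chrom, pos)] = (ref, alt)

    offspring = [
        (sid, info)
        for sid, info in rna.samples.items()
        if info.role == "offspring"
    ]

    combined = []
    for snp in breed_snps:
        rna_alleles = rna_by_pos.get((snp.chrom, snp.pos))
        if rna_alleles is None:
            continue
        rna_ref, rna_alt = rna_alleles
        key = (snp.chrom, snp.pos, rna_ref, rna_alt)
        calls: dict[tuple[str, int], int] = {}
        row = rna.calls.loc[key]
        for sample_id, info in offspring:
            code = int(row[sample_id])
            calls[(info.stage, info.replicate if info.replicate is not None else 0)] = code
        combined.append(CombinedSite(snp, rna_ref, rna_alt, calls))
    logger.info("joined %d of %d breed-specific SNPs with RNA calls", len(combined), len(breed_snps))
    return combined


# ---------------------------------------------------------------------------
# filter cascade


def _fails_allele_mismatch(site: CombinedSite) -> bool:
    return (site.rna_ref, site.rna_alt) != (site.snp.ref, site.snp.alt)


def _fails_replicate_discordance(site: CombinedSite) -> bool:
    # per-stage scope: missing calls do not discord, two distinct non-missing do
    for stage in site.stages():
        if len(set(site.stage_calls(stage))) > 1:
            return True
    return False


def _allele_set(code: int, ref: str, alt: str) -> set[str]:
    return {HOM_REF: {ref}, HET: {ref, alt}, HOM_ALT: {alt}}[code]


def _fails_maternal_oocyte_mismatch(site: CombinedSite) -> bool:
    # mismatch = any oocyte RNA call carries an allele the maternal DNA lacks
    maternal_alleles = {site.snp.maternal_allele}
    for code in site.stage_calls(OOCYTE_STAGE):
        if not _allele_set(code, site.snp.ref, site.snp.alt) <= maternal_alleles:
            return True
    return False


_FILTERS = {
    "allele_mismatch": _fails_allele_mismatch,
    "replicate_discordance": _fails_replicate_discordance,
    "maternal_oocyte_mismatch": _fails_maternal_oocyte_mismatch,
}


def apply_filter_cascade(
    combined: list[CombinedSite],
    order: tuple[str, ...] = FILTER_STEPS,
) -> tuple[list[CombinedSite], CascadeReport]:
    """Run the filters in ``order``; a site is attributed to its first failure.

    Each filter is a pure predicate of the site, so the *surviving* set is
    invariant under reordering; only the per-step attribution changes.
    """
    unknown = set(order) - set(_FILTERS)
    if unknown:
        raise ValueError(f"unknown filter step(s) {sorted(unknown)}")
    report = CascadeReport(n_input=len(combined))
    report.removed = {step: 0 for step in order}
    report.removed_sites = {step: [] for step in order}
    surviving = []
    for site in combined:
        for step in order:
            if _FILTERS[step](site):
                report.removed[step] += 1
                report.removed_sites[step].append((site.snp.chrom, site.snp.pos))
                break
        else:
            surviving.append(site)
    report.n_surviving = len(surviving)
    assert report.check_conservation()
    return surviving, report


# ---------------------------------------------------------------------------
# origin classification


def classify_site_origin(site: CombinedSite, stage: str) -> str:
    """Origin of expression at one stage from the replicate-concordant genotype."""
    calls = set(site.stage_calls(stage))
    if len(calls) != 1:
        return "undetermined"
    code = calls.pop()
    if code == HET:
        return "biallelic"
    hom_allele = site.snp.ref if code == HOM_REF else site.snp.alt
    return "maternal" if hom_allele == site.snp.maternal_allele else "paternal"


def site_origin_table(sites: list[CombinedSite], stages: list[str] | None = None) -> pd.DataFrame:
    """Marker table: one row per surviving SNP with per-stage origin calls."""
    rows = []
    for site in sites:
        row = {
            "chrom": site.snp.chrom,
            "pos": site.snp.pos,
            "ref": site.snp.ref,
            "alt": site.snp.alt,
            "maternal_allele": site.snp.maternal_allele,
            "paternal_allele": site.snp.paternal_allele,
        }
        for stage in stages or site.stages():
            row[f"origin_{stage}"] = classify_site_origin(site, stage)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return frame


def assign_snps_to_genes(
    sites: list[CombinedSite], annotation: AnnotationSet
) -> tuple[dict[str, list[CombinedSite]], list[CombinedSite]]:
    """Map each SNP to the single gene span containing it.

    SNPs in no gene, or in two or more overlapping genes, are unannotated
    (ambiguous positions cannot support a gene-level call).
    """
    spans = []
    for gene in annotation.genes.values():
        span = gene.span
        spans.append((span.chrom, span.start, span.end, gene.gene_id))
    by_gene: dict[str, list[CombinedSite]] = {}
    unannotated = []
    for site in sites:
        hits = [
            gid
            for chrom, start, end, gid in spans
            if chrom == site.snp.chrom and start <= site.snp.pos < end
        ]
        if len(hits) == 1:
            by_gene.setdefault(hits[0], []).append(site)
        else:
            if len(hits) > 1:
                logger.info(
                    "SNP %s:%d overlaps %d genes; dropped as unannotated",
                    site.snp.chrom, site.snp.pos, len(hits),
                )
            unannotated.append(site)
    return by_gene, unannotated


def summarize_gene_origin(
    sites: list[CombinedSite],
    annotation: AnnotationSet,
    stages: list[str] | None = None,
) -> list[GeneOriginSummary]:
    """Per-gene consensus origin with the conservative consistency filters.

    Filter order: unannotated SNPs are dropped first; genes with a single
    supporting SNP are filtered (single_snp); genes whose SNPs disagree at
    any stage where two or more of them have determined calls are filtered
    (inconsistent_pattern). Surviving genes get the per-stage consensus and
    their supporting SNP count.
    """
    by_gene, _ = assign_snps_to_genes(sites, annotation)
    summaries = []
    for gene_id in sorted(by_gene):
        gene_sites = by_gene[gene_id]
        biotype = annotation.genes[gene_id].biotype
        all_stages = stages or sorted({s for site in gene_sites for s in site.stages()})
        if len(gene_sites) < 2:
            summaries.append(
                GeneOriginSummary(gene_id, biotype, {}, len(gene_sites), True, "single_snp")
            )
            continue
        stage_origin: dict[str, str] = {}
        consistent = True
        for stage in all_stages:
            calls = [
                origin
                for site in gene_sites
                if (origin := classify_site_origin(site, stage)) != "undetermined"
            ]
            if len(set(calls)) > 1:
                consistent = False
                break
            stage_origin[stage] = calls[0] if calls else "undetermined"
        if not consistent:
            summaries.append(
                GeneOriginSummary(
                    gene_id, biotype, {}, len(gene_sites), True, "inconsistent_pattern"
                )
            )
        else:
            summaries.append(
                GeneOriginSummary(gene_id, biotype, stage_origin, len(gene_sites))
            )
    return summaries


def gene_summary_frame(summaries: list[GeneOriginSummary]) -> pd.DataFrame:
    stages = sorted({s for summary in summaries for s in summary.stage_origin})
    rows = []
    for summary in summaries:
        row = {
            "gene_id": summary.gene_id,
            "biotype": summary.biotype,
            "n_snps": summary.n_snps,
            "filtered": summary.filtered,
            "filter_reason": summary.filter_reason,
        }
        for stage in stages:
            row[f"origin_{stage}"] = summary.stage_origin.get(stage, "")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    dna: GenotypeTable,
    rna: GenotypeTable,
    annotation: AnnotationSet,
    maternal_ids: list[str],
    paternal_ids: list[str],
    stages: list[str] | None = None,
) -> tuple[list[GeneOriginSummary], CascadeReport, list[CombinedSite]]:
    """In-memory end-to-end run: detection, join, cascade, gene summary."""
    breed_snps = call_breed_specific_snps(dna, maternal_ids, paternal_ids)
    combined = join_offspring(breed_snps, rna)
    surviving, report = apply_filter_cascade(combined)
    summaries = summarize_gene_origin(surviving, annotation, stages)
    return summaries, report, surviving


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class AseConfig:
    parents_vcf: str | Path
    maternal_samples: list[str]
    paternal_samples: list[str]
    offspring_sheet: str | Path  # sample sheet with a vcf column per sample
    gtf: str | Path
    out_dir: str | Path
    stages: list[str] | None = None

    def validate(self) -> None:
        sheet = Path(self.offspring_sheet)
        for path in (Path(self.parents_vcf), sheet, Path(self.gtf)):
            if not path.exists():
                raise FileNotFoundError(f"input not found: {path}")


def run_ase(config: AseConfig) -> tuple[list[GeneOriginSummary], CascadeReport, pd.DataFrame]:
    """Run the full parental-origin pipeline and write its three outputs.

    Outputs under ``config.out_dir``: ``marker_snps.tsv`` (the final marker
    set with per-stage origins), ``cascade_report.tsv``/``.json``, and
    ``gene_origin.tsv``. Fully deterministic: same inputs, same bytes.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    parent_roles = {
        **{s: SampleInfo(s, "maternal_parent") for s in config.maternal_samples},
        **{s: SampleInfo(s, "paternal_parent") for s in config.paternal_samples},
    }
    dna = read_vcf(config.parents_vcf, sample_info=parent_roles, default_role="offspring", stage="unknown")

    sheet = pd.read_csv(config.offspring_sheet, sep="\t", dtype={"replicate": int})
    sheet_dir = Path(config.offspring_sheet).parent
    tables = []
    for _, row in sheet.iterrows():
        vcf_path = Path(row["vcf"])
        if not vcf_path.is_absolute():
            vcf_path = sheet_dir / vcf_path
        info = SampleInfo(row["sample_id"], "offspring", row["stage"], int(row["replicate"]))
        tables.append(read_vcf(vcf_path, sample_info={row["sample_id"]: info}))
    rna = merge_tables(tables)

    annotation = read_annotation(config.gtf)

    breed_snps = call_breed_specific_snps(dna, config.maternal_samples, config.paternal_samples)
    combined = join_offspring(breed_snps, rna)
    surviving, report = apply_filter_cascade(combined)
    stages = config.stages or sorted({s for site in surviving for s in site.stages()})
    markers = site_origin_table(surviving, stages)
    summaries = summarize_gene_origin(surviving, annotation, stages)

    markers.to_csv(out_dir / "marker_snps.tsv", sep="\t", index=False)
    report.write(out_dir / "cascade_report.tsv", out_dir / "cascade_report.json")
    gene_summary_frame(summaries).to_csv(out_dir / "gene_origin.tsv", sep="\t", index=False)
    return summaries, report, markers
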
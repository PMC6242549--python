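"""Intron and intergenic region catalogs derived from a gene annotation.

Intron regions are the gaps between a gene's merged exons: exon annotations
of different transcripts of the same gene overlap freely, so exons are first
collapsed per gene and only then are the gaps taken. Intergenic regions are
the gaps between merged gene blocks on a chromosome (strand-ignored);
flanks before the first and after the last gene are not emitted, so no
chromosome length table is needed. Both catalogs round-trip through GTF.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import AnnotationSet, read_annotation
from .intervals import GenomicInterval, interval_gaps, merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

REGION_CLASSES = ("exon_merged", "intron", "intergenic")


@dataclass(frozen=True)
class Region:
    region_id: str
    interval: GenomicInterval
    region_class: str
    gene_id: str | None = None


@dataclass
class RegionCatalog:
    region_class: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES + ("mixed",):
            raise ValueError(f"unknown region class {self.region_class!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def by_gene(self, gene_id: str) -> list[Region]:
        return [r for r in self.regions if r.gene_id == gene_id]


def merge_gene_exons(annotation: AnnotationSet, gene_id: str) -> list[tuple[int, int]]:
    """Disjoint sorted intervals whose union is the union of the gene's exons."""
    if gene_id not in annotation.genes:
        raise KeyError(f"unknown gene_id {gene_id!r}")
    return annotation.genes[gene_id].merged_exons()


def _sorted_genes(annotation: AnnotationSet):
    # deterministic order: (chrom, start, end, gene_id) breaks span ties
    return sorted(
        annotation.genes.values(),
        key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id),
    )


def define_merged_exons(annotation: AnnotationSet) -> RegionCatalog:
    """Per-gene merged exon blocks, as a catalog countable like introns."""
    regions = []
    for gene in _sorted_genes(annotation):
        for ordinal, (start, end) in enumerate(gene.merged_exons(), start=1):
            regions.append(
                Region(
                    region_id=f"{gene.gene_id}:exon_merged:{ordinal}",
                    interval=GenomicInterval(gene.chrom, start, end, gene.strand),
                    region_class="exon_merged",
                    gene_id=gene.gene_id,
                )
            )
    return RegionCatalog("exon_merged", regions)


def define_introns(annotation: AnnotationSet, mask_foreign_exons: bool = False) -> RegionCatalog:
    """Gaps between each gene's consecutive merged exons, strand inherited.

    With ``mask_foreign_exons`` the merged exons of *other* genes are
    subtracted from each intron, for annotations where nested or overlapping
    genes would otherwise place exonic bases inside an intron.
    """
    foreign: dict[str, list[tuple[int, int, str]]] = {}
    if mask_foreign_exons:
        for gene in annotation.genes.values():
            for start, end in gene.merged_exons():
                foreign.setdefault(gene.chrom, []).append((start, end, gene.gene_id))

    regions = []
    for gene in _sorted_genes(annotation):
        gaps = interval_gaps(gene.merged_exons())
        if mask_foreign_exons and gaps:
            cuts = [
                (s, e)
                for s, e, gid in foreign.get(gene.chrom, [])
                if gid != gene.gene_id
            ]
            gaps = subtract_intervals(gaps, cuts) if cuts else gaps
        for ordinal, (start, end) in enumerate(gaps, start=1):
            regions.append(
                Region(
                    region_id=f"{gene.gene_id}:intron:{ordinal}",
                    interval=GenomicInterval(gene.chrom, start, end, gene.strand),
                    region_class="intron",
                    gene_id=gene.gene_id,
                )
            )
    logger.info("defined %d introns across %d genes", len(regions), len(annotation))
    return RegionCatalog("intron", regions)


def define_intergenic(annotation: AnnotationSet) -> RegionCatalog:
    """Unstranded gaps between merged gene blocks, per chromosome.

    Overlapping or nested gene spans merge into one block, so no intergenic
    region is emitted between them; a chromosome with a single gene block
    yields nothing.
    """
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes.values():
        span = gene.span
        spans_by_chrom.setdefault(gene.chrom, []).append((span.start, span.end))

    regions = []
    for chrom in sorted(spans_by_chrom):
        blocks = merge_intervals(spans_by_chrom[chrom])
        for ordinal, (start, end) in enumerate(interval_gaps(blocks), start=1):
            regions.append(
                Region(
                    region_id=f"{chrom}:intergenic:{ordinal}",
                    interval=GenomicInterval(chrom, start, end, "."),
                    region_class="intergenic",
                    gene_id=None,
                )
            )
    logger.info("defined %d intergenic regions on %d chromosomes", len(regions), len(spans_by_chrom))
    return RegionCatalog("intergenic", regions)


def write_region_gtf(catalog: RegionCatalog, path: str | Path) -> None:
    """Emit one GTF feature line per region, 1-based inclusive coordinates.

    The feature type column carries the region class; attributes carry the
    region_id and, for gene-owned regions, the parent gene_id. Writing then
    re-reading yields identical intervals, and a second write is
    byte-identical.
    """
    lines = []
    for region in sorted(
        catalog.regions,
        key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.region_id),
    ):
        attrs = f'region_id "{region.region_id}";'
        if region.gene_id is not None:
            attrs += f' gene_id "{region.gene_id}";'
        lines.append(
            "\t".join(
                [
                    region.interval.chrom,
                    "zga_ase",
                    region.region_class,
                    str(region.interval.start + 1),
                    str(region.interval.end),
                    ".",
                    region.interval.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_region_gtf(path: str | Path) -> RegionCatalog:
    """Read a catalog written by :func:`write_region_gtf` (or compatible GTF)."""
    regions = []
    classes = set()
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {line_no}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature_type, start, end, _, strand, _, attr_str = fields
            attrs = _parse_attrs(attr_str)
            region_id = attrs.get("region_id", f"{feature_type}:{line_no}")
            regions.append(
                Region(
                    region_id=region_id,
                    interval=GenomicInterval(
                        chrom, int(start) - 1, int(end), strand if strand in "+-" else "."
                    ),
                    region_class=feature_type,
                    gene_id=attrs.get("gene_id"),
                )
            )
            classes.add(feature_type)
    region_class = classes.pop() if len(classes) == 1 else "mixed"
    return RegionCatalog(region_class or "mixed", regions)


def _parse_attrs(attr_str: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_str.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip('"')
    return attrs


def build_catalogs(
    gtf_path: str | Path, mask_foreign_exons: bool = False
) -> dict[str, RegionCatalog]:
    """Convenience: read a GTF and build all three catalogs."""
    annotation = read_annotation(gtf_path)
    return {
        "exon_merged": define_merged_exons(annotation),
        "intron": define_introns(annotation, mask_foreign_exons=mask_foreign_exons),
        "intergenic": define_intergenic(annotation),
    }
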
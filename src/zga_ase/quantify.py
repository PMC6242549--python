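"""Union-mode read counting against region catalogs.

Counting reproduces htseq-count union semantics: a fragment overlapping
exactly one region (on a compatible strand) increments that region, a
fragment hitting two or more regions is ambiguous, and one hitting none is
unassigned. Strand handling follows the dUTP reverse-stranded protocol
("RF"): the originating transcript of a fragment sits on the strand opposite
to its first read's alignment strand, so a region is compatible when its
annotated strand is opposite the fragment's recorded alignment strand.
Unstranded regions (intergenic) accept either strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

from .regions import RegionCatalog

logger = logging.getLogger(__name__)

STRANDNESS = ("RF", "FR", "unstranded")


@dataclass
class ReadRecord:
    """One sequenced fragment: aligned blocks plus its alignment strand.

    ``blocks`` are 0-based half-open, sorted and disjoint, all on ``chrom``;
    spliced alignments and mate pairs contribute multiple blocks. ``strand``
    is the alignment strand of the fragment's first read.
    """

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    strand: str = "."

    def __post_init__(self) -> None:
        blocks = sorted(self.blocks)
        for (s1, e1), (s2, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                # overlapping mate blocks are unioned, htseq-style
                blocks = _union_blocks(blocks)
                break
        for s, e in blocks:
            if s >= e:
                raise ValueError(f"empty block ({s}, {e}) in read {self.read_id}")
        self.blocks = blocks


def _union_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class CountDiagnostics:
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    unknown_chrom: int = 0
    wrong_strand: int = 0  # subset bookkeeping: reads rejected purely by strand

    @property
    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unassigned + self.unknown_chrom


@dataclass
class CountMatrix:
    """Per-region counts across samples with region metadata alongside."""

    counts: pd.DataFrame  # index: region_id, columns: sample_id
    region_meta: pd.DataFrame  # index: region_id; columns: region_class, gene_id
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)  # stage labels

    def to_tsv(self, path: str | Path) -> None:
        out = self.region_meta.join(self.counts)
        out.index.name = "region_id"
        out.to_csv(path, sep="\t")


def _build_index(catalog: RegionCatalog) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    seen: set[str] = set()
    for region in catalog.regions:
        if region.region_id in seen:
            raise ValueError(f"duplicate region_id {region.region_id}")
        seen.add(region.region_id)
        trees.setdefault(region.interval.chrom, IntervalTree()).addi(
            region.interval.start, region.interval.end, region
        )
    return trees


def _resolved_strand(read_strand: str, strandness: str) -> str:
    if strandness == "RF":
        return {"+": "-", "-": "+"}.get(read_strand, ".")
    return read_strand


def count_overlaps(
    reads: Iterable[ReadRecord],
    catalog: RegionCatalog,
    strandness: str = "RF",
    drop_duplicates: bool = False,
) -> tuple[pd.Series, CountDiagnostics]:
    """Count fragments against a catalog with union-mode semantics.

    Returns a count Series over every region_id of the catalog (zeros
    included) plus diagnostics satisfying
    ``assigned + ambiguous + unassigned + unknown_chrom == total reads``.
    """
    if strandness not in STRANDNESS:
        raise ValueError(f"strandness must be one of {STRANDNESS}")
    trees = _build_index(catalog)
    counts: dict[str, int] = {r.region_id: 0 for r in catalog.regions}
    diag = CountDiagnostics()
    seen_fragments: set[tuple] = set()
    warned_chroms: set[str] = set()

    for read in reads:
        if drop_duplicates:
            key = (read.chrom, read.strand, tuple(read.blocks))
            if key in seen_fragments:
                continue
            seen_fragments.add(key)
        tree = trees.get(read.chrom)
        if tree is None:
            if read.chrom not in warned_chroms:
                logger.warning("reads on unknown chromosome %s skipped", read.chrom)
                warned_chroms.add(read.chrom)
            diag.unknown_chrom += 1
            continue
        hits = set()
        any_position_hit = False
        for start, end in read.blocks:
            for hit in tree.overlap(start, end):
                region = hit.data
                any_position_hit = True
                if strandness != "unstranded" and region.interval.strand in "+-":
                    if _resolved_strand(read.strand, strandness) != region.interval.strand:
                        continue
                hits.add(region.region_id)
        if len(hits) == 1:
            counts[hits.pop()] += 1
            diag.assigned += 1
        elif len(hits) > 1:
            diag.ambiguous += 1
        else:
            diag.unassigned += 1
            if any_position_hit:
                diag.wrong_strand += 1
    return pd.Series(counts, name="count", dtype=int), diag


def count_samples(
    sample_reads: dict[str, Iterable[ReadRecord]],
    catalog: RegionCatalog,
    strandness: str = "RF",
    sample_stages: dict[str, str] | None = None,
) -> tuple[CountMatrix, dict[str, CountDiagnostics]]:
    """Count several samples into one matrix; column order = dict order."""
    columns = {}
    diagnostics = {}
    for sample_id, reads in sample_reads.items():
        columns[sample_id], diagnostics[sample_id] = count_overlaps(
            reads, catalog, strandness=strandness
        )
    counts = pd.DataFrame(columns)
    meta = pd.DataFrame(
        {
            "region_class": {r.region_id: r.region_class for r in catalog.regions},
            "gene_id": {r.region_id: r.gene_id or "" for r in catalog.regions},
        }
    ).loc[counts.index]
    sample_meta = pd.DataFrame(
        {"stage": sample_stages or {s: "" for s in columns}}
    )
    return CountMatrix(counts, meta, sample_meta), diagnostics


def summarize_expressed(
    matrix: CountMatrix, threshold: int = 1, classes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per sample and region class: how many regions reach ``threshold`` counts.

    A region is "expressed" in a sample iff its raw count >= threshold (the
    threshold is a sensitivity knob, default one read). Returns a tidy frame
    with columns sample, region_class, n_expressed, n_total, proportion.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if matrix.counts.empty:
        return pd.DataFrame(
            columns=["sample", "region_class", "n_expressed", "n_total", "proportion", "threshold"]
        )
    wanted = classes or tuple(sorted(matrix.region_meta["region_class"].unique()))
    rows = []
    for sample in matrix.counts.columns:
        for region_class in wanted:
            mask = matrix.region_meta["region_class"] == region_class
            total = int(mask.sum())
            expressed = int((matrix.counts.loc[mask, sample] >= threshold).sum())
            rows.append(
                {
                    "sample": sample,
                    "region_class": region_class,
                    "n_expressed": expressed,
                    "n_total": total,
                    "proportion": expressed / total if total else 0.0,
                    "threshold": threshold,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers


def read_bed_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Read fragments from a BED-like table: chrom, start, end, strand, read_id.

    Rows sharing a read_id are the blocks of one fragment and must be
    contiguous in the file.
    """
    pending_id: str | None = None
    pending: list[tuple[str, int, int, str]] = []

    def flush() -> ReadRecord:
        chroms = {c for c, _, _, _ in pending}
        if len(chroms) != 1:
            raise ValueError(f"read {pending_id} has blocks on multiple chromosomes")
        strand = pending[0][3]
        return ReadRecord(
            read_id=pending_id,
            chrom=pending[0][0],
            blocks=[(s, e) for _, s, e, _ in pending],
            strand=strand,
        )

    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, strand, read_id = line.split("\t")[:5]
            if pending_id is not None and read_id != pending_id:
                yield flush()
                pending = []
            pending_id = read_id
            pending.append((chrom, int(start), int(end), strand))
    if pending:
        yield flush()


def read_sam_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Read fragments from SAM/BAM via pysam, pairing mates by query name.

    Secondary, supplementary and unmapped records are skipped. The fragment
    strand recorded is the read-1 alignment strand (read-2 strands are
    flipped), matching the convention of :func:`count_overlaps`.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    fragments: dict[str, ReadRecord] = {}
    with pysam.AlignmentFile(str(path), mode) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            raw_strand = "-" if aln.is_reverse else "+"
            if aln.is_paired and aln.is_read2:
                raw_strand = "+" if raw_strand == "-" else "-"
            blocks = aln.get_blocks()
            if not blocks:
                continue
            existing = fragments.get(aln.query_name)
            if existing is None:
                fragments[aln.query_name] = ReadRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    blocks=list(blocks),
                    strand=raw_strand,
                )
            elif existing.chrom == aln.reference_name:
                existing.blocks = _union_blocks(existing.blocks + list(blocks))
    yield from fragments.values()
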
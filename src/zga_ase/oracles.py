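"""Naive reference implementations for verification.

Everything here recomputes a result by exhaustive enumeration over integer
base positions — deliberately slow and deliberately independent of the
interval-arithmetic and counting code paths it is used to check. Only the
test-suite and the reproduction script should import this module.
"""
from __future__ import annotations

from .annotation import AnnotationSet
from .quantify import ReadRecord
from .regions import RegionCatalog


def _runs(bases: set[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as half-open intervals."""
    runs = []
    for base in sorted(bases):
        if runs and base == runs[-1][1]:
            runs[-1] = (runs[-1][0], base + 1)
        else:
            runs.append((base, base + 1))
    return runs


def merged_exons_bruteforce(annotation: AnnotationSet, gene_id: str) -> list[tuple[int, int]]:
    gene = annotation.genes[gene_id]
    bases: set[int] = set()
    for start, end in gene.exons:
        bases.update(range(start, end))
    return _runs(bases)


def introns_bruteforce(annotation: AnnotationSet, gene_id: str) -> list[tuple[int, int]]:
    """Gene-span bases minus exon bases."""
    gene = annotation.genes[gene_id]
    span = gene.span
    exon_bases: set[int] = set()
    for start, end in gene.exons:
        exon_bases.update(range(start, end))
    return _runs(set(range(span.start, span.end)) - exon_bases)


def intergenic_bruteforce(annotation: AnnotationSet, chrom: str) -> list[tuple[int, int]]:
    """Bases between the first gene start and last gene end not in any span."""
    spans = [g.span for g in annotation.genes.values() if g.chrom == chrom]
    if not spans:
        return []
    lo = min(s.start for s in spans)
    hi = max(s.end for s in spans)
    gene_bases: set[int] = set()
    for span in spans:
        gene_bases.update(range(span.start, span.end))
    return _runs(set(range(lo, hi)) - gene_bases)


def count_overlaps_bruteforce(
    reads: list[ReadRecord], catalog: RegionCatalog, strandness: str = "RF"
) -> tuple[dict[str, int], dict[str, int]]:
    """Union-mode counting by per-base membership tests.

    Returns (counts per region_id, diagnostics with assigned / ambiguous /
    unassigned / unknown_chrom).
    """
    flip = {"+": "-", "-": "+", ".": "."}
    chroms = {r.interval.chrom for r in catalog.regions}
    counts = {r.region_id: 0 for r in catalog.regions}
    diag = {"assigned": 0, "ambiguous": 0, "unassigned": 0, "unknown_chrom": 0}
    for read in reads:
        if read.chrom not in chroms:
            diag["unknown_chrom"] += 1
            continue
        read_bases = {b for start, end in read.blocks for b in range(start, end)}
        if strandness == "RF":
            resolved = flip[read.strand]
        else:
            resolved = read.strand
        hits = set()
        for region in catalog.regions:
            iv = region.interval
            if iv.chrom != read.chrom:
                continue
            if strandness != "unstranded" and iv.strand in "+-" and resolved != iv.strand:
                continue
            if read_bases & set(range(iv.start, iv.end)):
                hits.add(region.region_id)
        if len(hits) == 1:
            counts[hits.pop()] += 1
            diag["assigned"] += 1
        elif hits:
            diag["ambiguous"] += 1
        else:
            diag["unassigned"] += 1
    return counts, diag
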
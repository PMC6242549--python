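"""GTF gene-model parsing into an in-memory annotation set.

The annotation is the substrate for region arithmetic: genes own transcripts,
transcripts own exons, and a gene's span is the union of its exons. GTF
coordinates (1-based inclusive) are converted to the internal 0-based
half-open convention on read and restored on write.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from gffutils.feature import feature_from_line

from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

#: biotype attribute values mapped onto the three classes the analysis uses
_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "lincRNA": "lincRNA",
    "lncRNA": "lincRNA",
}


class GtfParseError(ValueError):
    """A GTF line could not be interpreted; carries the 1-based line number."""


@dataclass
class GeneRecord:
    """One gene: its transcripts' exon intervals plus a biotype label."""

    gene_id: str
    chrom: str
    strand: str
    biotype: str = "other"
    # transcript_id -> list of (start, end), 0-based half-open
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def exons(self) -> list[tuple[int, int]]:
        return [iv for exon_list in self.transcripts.values() for iv in exon_list]

    @property
    def span(self) -> GenomicInterval:
        exons = self.exons
        if not exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return GenomicInterval(
            self.chrom,
            min(s for s, _ in exons),
            max(e for _, e in exons),
            self.strand,
        )

    def merged_exons(self) -> list[tuple[int, int]]:
        """Minimal disjoint intervals covering every exon base of the gene."""
        return merge_intervals(self.exons)


@dataclass
class AnnotationSet:
    genes: dict[str, GeneRecord] = field(default_factory=dict)
    source_build: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def chromosomes(self) -> list[str]:
        return sorted({g.chrom for g in self.genes.values()})

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.chrom == chrom]


def _first_attr(feature, key: str) -> str | None:
    values = feature.attributes.get(key)
    return values[0] if values else None


def read_annotation(gtf_path: str | Path, source_build: str = "") -> AnnotationSet:
    """Parse exon features of a GTF into an :class:`AnnotationSet`.

    Only ``exon`` features contribute coordinates; other feature types are
    ignored apart from ``gene``/``transcript`` lines, which may supply a
    biotype. Raises :class:`GtfParseError` naming the offending line for
    malformed lines or exons lacking a transcript_id.
    """
    annotation = AnnotationSet(source_build=source_build)
    with open(gtf_path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions on bad lines
                raise GtfParseError(f"line {line_no}: malformed GTF line: {exc}") from exc
            gene_id = _first_attr(feature, "gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {line_no}: feature lacks gene_id attribute")
            biotype = (
                _first_attr(feature, "gene_biotype")
                or _first_attr(feature, "gene_type")
                or _first_attr(feature, "biotype")
            )
            if feature.featuretype != "exon":
                if biotype and gene_id in annotation.genes:
                    annotation.genes[gene_id].biotype = _BIOTYPE_MAP.get(biotype, "other")
                continue
            transcript_id = _first_attr(feature, "transcript_id")
            if transcript_id is None:
                raise GtfParseError(f"line {line_no}: exon lacks transcript_id attribute")
            gene = annotation.genes.get(gene_id)
            if gene is None:
                gene = GeneRecord(
                    gene_id=gene_id,
                    chrom=feature.seqid,
                    strand=feature.strand if feature.strand in "+-" else ".",
                    biotype=_BIOTYPE_MAP.get(biotype or "", "other"),
                )
                annotation.genes[gene_id] = gene
            else:
                if gene.chrom != feature.seqid:
                    raise GtfParseError(
                        f"line {line_no}: exon of {gene_id} on {feature.seqid}, "
                        f"gene previously seen on {gene.chrom}"
                    )
            # GTF is 1-based inclusive; internal convention is 0-based half-open
            start0, end0 = feature.start - 1, feature.end
            if start0 < 0 or start0 >= end0:
                raise GtfParseError(f"line {line_no}: invalid coordinates {feature.start}-{feature.end}")
            gene.transcripts.setdefault(transcript_id, []).append((start0, end0))
    logger.info("read %d genes from %s", len(annotation), gtf_path)
    return annotation


def write_annotation_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write exon lines (1-based inclusive) for every transcript, sorted."""
    lines = []
    for gene in sorted(annotation.genes.values(), key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id)):
        for transcript_id in sorted(gene.transcripts):
            for start, end in sorted(gene.transcripts[transcript_id]):
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{transcript_id}"; '
                    f'gene_biotype "{_inverse_biotype(gene.biotype)}";'
                )
                lines.append(
                    "\t".join(
                        [
                            gene.chrom,
                            "zga_ase",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _inverse_biotype(biotype: str) -> str:
    return {"mRNA": "protein_coding", "lincRNA": "lincRNA"}.get(biotype, "other")
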
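"""Diploid genotype tables backed by VCF.

Genotypes are stored as alt-allele dosage codes: 0 (hom ref), 1 (het),
2 (hom alt), -1 (missing / site absent in that sample's calls). Only
bi-allelic SNVs are kept; records still multi-allelic on input are skipped
with a tally, and indels are ignored. Positions are 0-based internally and
1-based in VCF, as usual.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
BASES = ("A", "C", "G", "T")

ROLES = ("maternal_parent", "paternal_parent", "offspring")


@dataclass(frozen=True, order=True)
class SnpSite:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"invalid SNP alleles {self.ref}>{self.alt}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    role: str
    stage: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "offspring" and self.stage is None:
            raise ValueError(f"offspring sample {self.sample_id} needs a stage label")


@dataclass
class GenotypeTable:
    """Calls for a set of samples at a set of bi-allelic SNP sites.

    ``calls`` is indexed by (chrom, pos, ref, alt) with one int8 column per
    sample; absent sites are MISSING (-1) for that sample.
    """

    calls: pd.DataFrame
    samples: dict[str, SampleInfo] = field(default_factory=dict)
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        for sample_id in self.calls.columns:
            if sample_id not in self.samples:
                raise ValueError(f"call column {sample_id} has no sample metadata")

    @property
    def sites(self) -> list[SnpSite]:
        return [SnpSite(*key) for key in self.calls.index]

    def call(self, site: SnpSite, sample_id: str) -> int:
        key = (site.chrom, site.pos, site.ref, site.alt)
        if key not in self.calls.index or sample_id not in self.calls.columns:
            return MISSING
        return int(self.calls.loc[key, sample_id])

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, info in self.samples.items() if info.role == role]


def _empty_calls(sample_ids: Iterable[str]) -> pd.DataFrame:
    index = pd.MultiIndex.from_tuples([], names=["chrom", "pos", "ref", "alt"])
    return pd.DataFrame(
        {s: pd.Series(dtype=np.int8) for s in sample_ids}, index=index
    )


def read_vcf(
    path: str | Path,
    sample_info: dict[str, SampleInfo] | None = None,
    default_role: str = "offspring",
    stage: str | None = None,
    replicate: int | None = None,
) -> GenotypeTable:
    """Load a (possibly multi-sample) VCF into a :class:`GenotypeTable`.

    ``sample_info`` maps sample names to roles; samples without an entry get
    ``default_role`` (with ``stage``/``replicate`` for offspring).
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    info = {}
    for sample_id in sample_ids:
        if sample_info and sample_id in sample_info:
            info[sample_id] = sample_info[sample_id]
        else:
            info[sample_id] = SampleInfo(sample_id, default_role, stage, replicate)

    rows: dict[tuple, np.ndarray] = {}
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        codes = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                codes[i] = sum(alleles)
        rows[(variant.CHROM, variant.start, ref, alt)] = codes
    vcf.close()
    if skipped:
        logger.info("skipped %d non-bi-allelic-SNV records in %s", skipped, path)

    if not rows:
        return GenotypeTable(_empty_calls(sample_ids), info, skipped)
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["chrom", "pos", "ref", "alt"])
    calls = pd.DataFrame(
        np.vstack(list(rows.values())), index=index, columns=sample_ids, dtype=np.int8
    )
    return GenotypeTable(calls, info, skipped)


def merge_tables(tables: Iterable[GenotypeTable]) -> GenotypeTable:
    """Outer-join several tables on site; absent calls become MISSING."""
    tables = list(tables)
    if not tables:
        return GenotypeTable(_empty_calls([]), {})
    samples: dict[str, SampleInfo] = {}
    frames = []
    for table in tables:
        for sample_id, info in table.samples.items():
            if sample_id in samples:
                raise ValueError(f"duplicate sample id {sample_id} across tables")
            samples[sample_id] = info
        frames.append(table.calls)
    merged = pd.concat(frames, axis=1, join="outer").fillna(MISSING).astype(np.int8)
    merged = merged.sort_index()
    return GenotypeTable(merged, samples, sum(t.n_skipped_multiallelic for t in tables))


def write_vcf(table: GenotypeTable, path: str | Path, source: str = "zga_ase") -> None:
    """Write a minimal VCF v4.2; MISSING codes become ./. genotypes.

    Sites where every sample is MISSING are dropped (a site nobody was
    called at carries no information and would not appear in real calls).
    """
    sample_ids = list(table.calls.columns)
    chroms = sorted({key[0] for key in table.calls.index})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        *[f"##contig=<ID={chrom}>" for chrom in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for key in sorted(table.calls.index):
        chrom, pos, ref, alt = key
        codes = table.calls.loc[key]
        if (codes == MISSING).all():
            continue
        gts = "\t".join(GT_STRINGS[int(c)] for c in codes)
        lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_sheet(path: str | Path) -> dict[str, SampleInfo]:
    """TSV with columns sample_id, role, stage, replicate, vcf (vcf optional)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role"}
    if not required.issubset(frame.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    info = {}
    for _, row in frame.iterrows():
        stage = row.get("stage")
        stage = None if pd.isna(stage) else str(stage)
        rep = row.get("replicate")
        rep = None if pd.isna(rep) else int(rep)
        info[row["sample_id"]] = SampleInfo(row["sample_id"], row["role"], stage, rep)
    return info
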
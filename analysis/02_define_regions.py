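"""Build merged-exon, intron and intergenic catalogs from the simulated GTF.

Overlapping exon annotations within each gene are collapsed before introns
are taken as the gaps, and gene spans are merged (strand-ignored) before
intergenic gaps are taken, so the catalogs tile cleanly. Writes the catalogs
as GTF under scratch/ and a per-class count table to results/.

Run:  python analysis/02_define_regions.py   (after 01)
"""
from pathlib import Path

import pandas as pd

from zga_ase.regions import build_catalogs, write_region_gtf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    gtf = ROOT / "scratch" / "simdata" / "annotation.gtf"
    if not gtf.exists():
        raise SystemExit("run analysis/01_simulate_cross.py first")
    catalogs = build_catalogs(gtf)
    out = ROOT / "scratch" / "regions"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, catalog in catalogs.items():
        write_region_gtf(catalog, out / f"{name}.gtf")
        total_bp = sum(len(r.interval) for r in catalog.regions)
        rows.append({"region_class": name, "n_regions": len(catalog), "total_bp": total_bp})
        print(f"  {name}: {len(catalog)} regions, {total_bp} bp -> {out / f'{name}.gtf'}")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "region_counts.tsv", sep="\t", index=False)
    print(f"wrote {results / 'region_counts.tsv'}")


if __name__ == "__main__":
    main()
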
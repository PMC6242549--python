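import numpy as np
import pytest

from zga_ase.annotation import AnnotationSet, GeneRecord
from zga_ase.simulate import SimConfig, simulate_dataset


def make_gene(gene_id, chrom, strand, transcripts, biotype="mRNA"):
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, strand=strand, biotype=biotype,
        transcripts=transcripts,
    )


@pytest.fixture
def two_gene_annotation():
    """chr1: gene A (two exons, one intron), gene B downstream (single exon)."""
    annotation = AnnotationSet(source_build="test")
    annotation.genes["geneA"] = make_gene(
        "geneA", "chr1", "+", {"geneA.t1": [(99, 200), (299, 400)]}
    )
    annotation.genes["geneB"] = make_gene(
        "geneB", "chr1", "-", {"geneB.t1": [(599, 900)]}, biotype="lincRNA"
    )
    return annotation


def random_annotation(rng, max_genes=20, n_chromosomes=2):
    """Small random annotation with overlapping transcripts and genes."""
    annotation = AnnotationSet(source_build="random")
    n_genes = int(rng.integers(1, max_genes + 1))
    cursors = {f"chr{i + 1}": 100 for i in range(n_chromosomes)}
    for g in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chromosomes + 1))}"
        # sometimes rewind the cursor so genes overlap or nest
        if rng.random() < 0.25 and cursors[chrom] > 300:
            cursors[chrom] -= int(rng.integers(50, 250))
        pos = cursors[chrom]
        n_exons = int(rng.integers(1, 5))
        exons = []
        for i in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append((pos, pos + length))
            pos += length + (int(rng.integers(0, 80)) if i < n_exons - 1 else 0)
        transcripts = {f"g{g}.t1": exons}
        if n_exons > 1 and rng.random() < 0.5:
            # overlapping second transcript: shifted / extended exons
            shift = int(rng.integers(0, 30))
            transcripts[f"g{g}.t2"] = [
                (max(0, s - shift), e + int(rng.integers(0, 30))) for s, e in exons
            ]
        annotation.genes[f"g{g}"] = make_gene(
            f"g{g}", chrom, "+" if rng.random() < 0.5 else "-", transcripts
        )
        gene_end = max(e for t in transcripts.values() for _, e in t)
        cursors[chrom] = max(cursors[chrom], gene_end) + int(rng.integers(0, 200))
    return annotation


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Default synthetic cross, no error/dropout, written to disk once."""
    out = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(SimConfig(seed=7), out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
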
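"""Region arithmetic: GTF parsing, exon merging, intron/intergenic catalogs."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zga_ase.annotation import GtfParseError, read_annotation, write_annotation_gtf
from zga_ase.intervals import GenomicInterval, merge_intervals, subtract_intervals
from zga_ase.oracles import (
    intergenic_bruteforce,
    introns_bruteforce,
    merged_exons_bruteforce,
)
from zga_ase.regions import (
    define_intergenic,
    define_introns,
    define_merged_exons,
    merge_gene_exons,
    read_region_gtf,
    write_region_gtf,
)

from conftest import make_gene, random_annotation


class TestGtfIO:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t300\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        annotation = read_annotation(gtf)
        assert annotation.genes["g"].transcripts["t"] == [(99, 200), (299, 400)]

    def test_empty_file_gives_empty_annotation(self, tmp_path):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        assert len(read_annotation(gtf)) == 0

    def test_exon_without_transcript_id_is_parse_error(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(GtfParseError, match="line 1"):
            read_annotation(gtf)

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            "not a gtf line\n"
        )
        with pytest.raises(GtfParseError, match="line 2"):
            read_annotation(gtf)

    def test_unknown_feature_types_ignored(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\tstart_codon\t100\t102\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        annotation = read_annotation(gtf)
        assert annotation.genes["g"].exons == [(99, 200)]

    def test_annotation_round_trips(self, two_gene_annotation, tmp_path):
        path = tmp_path / "out.gtf"
        write_annotation_gtf(two_gene_annotation, path)
        back = read_annotation(path)
        for gene_id, gene in two_gene_annotation.genes.items():
            assert back.genes[gene_id].merged_exons() == gene.merged_exons()
            assert back.genes[gene_id].strand == gene.strand


class TestMergeExons:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(99, 200), (149, 250)], [(99, 250)]),
            ([(99, 200), (299, 400)], [(99, 200), (299, 400)]),
            ([(99, 200), (200, 300)], [(99, 300)]),  # abutting merge
        ],
    )
    def test_merge_examples(self, exons, expected):
        assert merge_intervals(exons) == expected

    def test_two_transcript_union(self):
        # t1: (99,200),(299,400); t2: (149,350) bridges the gap
        from zga_ase.annotation import AnnotationSet

        annotation = AnnotationSet()
        annotation.genes["g"] = make_gene(
            "g", "chr1", "+",
            {"t1": [(99, 200), (299, 400)], "t2": [(149, 350)]},
        )
        assert merge_gene_exons(annotation, "g") == [(99, 400)]
        assert merge_gene_exons(annotation, "g") == merged_exons_bruteforce(annotation, "g")

    def test_unknown_gene_raises(self, two_gene_annotation):
        with pytest.raises(KeyError):
            merge_gene_exons(two_gene_annotation, "nope")


class TestIntrons:
    def test_gap_between_exons(self, two_gene_annotation):
        catalog = define_introns(two_gene_annotation)
        introns = catalog.by_gene("geneA")
        assert len(introns) == 1
        assert (introns[0].interval.start, introns[0].interval.end) == (200, 299)
        assert introns[0].interval.strand == "+"
        assert introns[0].region_id == "geneA:intron:1"

    def test_single_exon_gene_has_no_introns(self, two_gene_annotation):
        assert define_introns(two_gene_annotation).by_gene("geneB") == []

    def test_bridging_transcript_removes_intron(self):
        from zga_ase.annotation import AnnotationSet

        annotation = AnnotationSet()
        annotation.genes["g"] = make_gene(
            "g", "chr1", "+",
            {"t1": [(99, 200), (299, 400)], "t2": [(149, 350)]},
        )
        assert define_introns(annotation).regions == []
        assert introns_bruteforce(annotation, "g") == []

    def test_mask_foreign_exons_subtracts_nested_gene(self):
        from zga_ase.annotation import AnnotationSet

        annotation = AnnotationSet()
        annotation.genes["outer"] = make_gene(
            "outer", "chr1", "+", {"t1": [(0, 100), (500, 600)]}
        )
        annotation.genes["inner"] = make_gene(
            "inner", "chr1", "-", {"t1": [(200, 300)]}
        )
        plain = define_introns(annotation).by_gene("outer")
        assert [(r.interval.start, r.interval.end) for r in plain] == [(100, 500)]
        masked = define_introns(annotation, mask_foreign_exons=True).by_gene("outer")
        assert [(r.interval.start, r.interval.end) for r in masked] == [
            (100, 200), (300, 500)
        ]


class TestIntergenic:
    def test_gap_between_genes(self, two_gene_annotation):
        catalog = define_intergenic(two_gene_annotation)
        assert len(catalog) == 1
        region = catalog.regions[0]
        assert (region.interval.start, region.interval.end) == (400, 599)
        assert region.interval.strand == "."
        assert region.gene_id is None

    def test_overlapping_genes_leave_no_gap(self):
        from zga_ase.annotation import AnnotationSet

        annotation = AnnotationSet()
        annotation.genes["a"] = make_gene("a", "chr1", "+", {"t": [(99, 500)]})
        annotation.genes["b"] = make_gene("b", "chr1", "-", {"t": [(399, 900)]})
        assert define_intergenic(annotation).regions == []
        assert intergenic_bruteforce(annotation, "chr1") == []

    def test_single_gene_chromosome_yields_nothing(self):
        from zga_ase.annotation import AnnotationSet

        annotation = AnnotationSet()
        annotation.genes["a"] = make_gene("a", "chr9", "+", {"t": [(99, 500)]})
        assert define_intergenic(annotation).regions == []


class TestRegionGtfRoundTrip:
    def test_write_read_identity(self, two_gene_annotation, tmp_path):
        catalog = define_introns(two_gene_annotation)
        path = tmp_path / "introns.gtf"
        write_region_gtf(catalog, path)
        line = path.read_text().splitlines()[0].split("\t")
        assert (line[2], line[3], line[4]) == ("intron", "201", "299")
        back = read_region_gtf(path)
        assert [(r.region_id, r.interval, r.gene_id) for r in back.regions] == [
            (r.region_id, r.interval, r.gene_id) for r in catalog.regions
        ]

    def test_second_write_is_byte_identical(self, two_gene_annotation, tmp_path):
        catalog = define_intergenic(two_gene_annotation)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_region_gtf(catalog, p1)
        write_region_gtf(read_region_gtf(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_catalog_writes_empty_file(self, tmp_path):
        from zga_ase.regions import RegionCatalog

        path = tmp_path / "empty.gtf"
        write_region_gtf(RegionCatalog("intron"), path)
        assert path.read_text() == ""


class TestRandomizedOracle:
    """Catalogs must equal exhaustive integer base-set recomputation."""

    def test_catalogs_match_bruteforce(self, rng):
        for _ in range(60):
            annotation = random_annotation(rng)
            introns = define_introns(annotation)
            for gene_id, gene in annotation.genes.items():
                assert gene.merged_exons() == merged_exons_bruteforce(annotation, gene_id)
                got = [
                    (r.interval.start, r.interval.end)
                    for r in introns.by_gene(gene_id)
                ]
                assert got == introns_bruteforce(annotation, gene_id)
            intergenic = define_intergenic(annotation)
            for chrom in annotation.chromosomes():
                got = [
                    (r.interval.start, r.interval.end)
                    for r in intergenic.regions
                    if r.interval.chrom == chrom
                ]
                assert got == intergenic_bruteforce(annotation, chrom)

    def test_gene_tiling_invariant(self, rng):
        """merged exons + introns tile the gene span exactly, disjointly."""
        for _ in range(20):
            annotation = random_annotation(rng, max_genes=10)
            introns = define_introns(annotation)
            for gene_id, gene in annotation.genes.items():
                pieces = gene.merged_exons() + [
                    (r.interval.start, r.interval.end)
                    for r in introns.by_gene(gene_id)
                ]
                pieces.sort()
                # pairwise disjoint and contiguous over the span
                for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
                    assert e1 == s2
                span = gene.span
                assert pieces[0][0] == span.start and pieces[-1][1] == span.end

    def test_input_order_invariance(self, rng):
        from zga_ase.annotation import AnnotationSet

        annotation = random_annotation(rng, max_genes=8)
        shuffled = AnnotationSet(source_build=annotation.source_build)
        for gene_id in sorted(annotation.genes, reverse=True):
            gene = annotation.genes[gene_id]
            shuffled.genes[gene_id] = make_gene(
                gene.gene_id, gene.chrom, gene.strand,
                {t: list(reversed(exons)) for t, exons in reversed(list(gene.transcripts.items()))},
            )
        for catalog_fn in (define_introns, define_intergenic, define_merged_exons):
            a = [(r.region_id, r.interval) for r in catalog_fn(annotation).regions]
            b = [(r.region_id, r.interval) for r in catalog_fn(shuffled).regions]
            assert a == b


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 100)).map(lambda t: (t[0], t[0] + t[1])),
    min_size=1,
    max_size=12,
)


class TestIntervalProperties:
    @given(intervals_strategy)
    @settings(derandomize=True, max_examples=80)
    def test_merge_covers_exactly_the_input_bases(self, intervals):
        merged = merge_intervals(intervals)
        base_union = {b for s, e in intervals for b in range(s, e)}
        merged_bases = {b for s, e in merged for b in range(s, e)}
        assert merged_bases == base_union
        for (s1, e1), (s2, _) in zip(merged, merged[1:]):
            assert s1 < e1 < s2  # sorted, disjoint, non-abutting

    @given(intervals_strategy)
    @settings(derandomize=True, max_examples=80)
    def test_gaps_complement_merged_within_hull(self, intervals):
        from zga_ase.intervals import interval_gaps

        merged = merge_intervals(intervals)
        gaps = interval_gaps(merged)
        hull = set(range(merged[0][0], merged[-1][1]))
        merged_bases = {b for s, e in merged for b in range(s, e)}
        gap_bases = {b for s, e in gaps for b in range(s, e)}
        assert merged_bases | gap_bases == hull
        assert not merged_bases & gap_bases

    @given(intervals_strategy, intervals_strategy)
    @settings(derandomize=True, max_examples=80)
    def test_subtract_is_base_set_difference(self, keep, remove):
        result = subtract_intervals(keep, remove)
        keep_bases = {b for s, e in keep for b in range(s, e)}
        remove_bases = {b for s, e in remove for b in range(s, e)}
        result_bases = {b for s, e in result for b in range(s, e)}
        assert result_bases == keep_bases - remove_bases


class TestIntervalPrimitives:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_subtract_intervals(self):
        assert subtract_intervals([(0, 100)], [(20, 30), (50, 60)]) == [
            (0, 20), (30, 50), (60, 100)
        ]
        assert subtract_intervals([(0, 10)], [(0, 10)]) == []
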
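import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitescout.regulon import (
    DERecord,
    DomainScoreRecord,
    GeneRecord,
    Operon,
    call_operons,
    classify_domains,
    extract_promoters,
    filter_de,
    read_annotation_tsv,
    read_de_table,
    read_domain_scores,
    read_gff3,
    subtract_regulon,
    write_annotation_tsv,
    write_de_table,
)
from sitescout.seq import NucSequence, revcomp
from sitescout.simulate import random_sequence


def _gene(gid, start, end, strand="+", contig="c1"):
    return GeneRecord(gid, contig, start, end, strand)


class TestFilterDE:
    def test_strong_up_kept(self):
        assert filter_de([DERecord("g1", 2.8, 0.001)]) == ["g1"]

    def test_below_cutoff_excluded(self):
        assert filter_de([DERecord("g1", -1.58, 0.001)]) == []

    def test_boundaries_inclusive(self):
        assert filter_de([DERecord("g1", 2.0, 0.01)]) == ["g1"]
        assert filter_de([DERecord("g2", -2.0, 0.01)]) == ["g2"]

    def test_missing_padj_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            out = filter_de([DERecord("g1", 5.0, None), DERecord("g2", 3.0, 0.001)])
        assert out == ["g2"]

    def test_padj_above_cutoff_excluded(self):
        assert filter_de([DERecord("g1", 5.0, 0.011)]) == []


class TestSubtractRegulon:
    def test_removes_exact_intersection(self):
        genes = [f"g{i}" for i in range(381)]
        regulon = set(genes[:200]) | {"other1", "other2"}
        remaining, removed = subtract_regulon(genes, regulon)
        assert len(remaining) == 181
        assert removed == 200

    def test_empty_regulon_is_identity(self):
        genes = ["a", "b", "c"]
        remaining, removed = subtract_regulon(genes, set())
        assert remaining == genes and removed == 0

    def test_disjoint(self):
        remaining, removed = subtract_regulon(["a", "b"], {"x", "y"})
        assert remaining == ["a", "b"] and removed == 0

    def test_preserves_order(self):
        remaining, _ = subtract_regulon(["c", "a", "b"], {"a"})
        assert remaining == ["c", "b"]


class TestCallOperons:
    def test_gap_below_threshold_chains(self):
        ops = call_operons([_gene("G1", 100, 400), _gene("G2", 430, 700)])
        assert len(ops) == 1
        assert ops[0].gene_ids == ("G1", "G2")
        assert ops[0].leader_gene == "G1"

    def test_gap_exactly_50_splits(self):
        ops = call_operons([_gene("G1", 100, 400), _gene("G2", 450, 700)])
        assert len(ops) == 2

    def test_opposite_strands_split(self):
        ops = call_operons([_gene("G1", 100, 400, "+"), _gene("G2", 410, 700, "-")])
        assert len(ops) == 2

    def test_minus_strand_leader_is_last_gene(self):
        ops = call_operons([_gene("G1", 100, 400, "-"), _gene("G2", 430, 700, "-")])
        assert len(ops) == 1
        assert ops[0].leader_gene == "G2"

    def test_overlapping_genes_chain_and_flag(self):
        ops = call_operons([_gene("G1", 100, 400), _gene("G2", 380, 700)])
        assert len(ops) == 1 and ops[0].overlap_flagged

    def test_different_contigs_never_merge(self):
        ops = call_operons(
            [_gene("G1", 100, 400, contig="c1"), _gene("G2", 410, 700, contig="c2")]
        )
        assert len(ops) == 2

    def test_unsorted_input(self):
        ops = call_operons([_gene("G2", 430, 700), _gene("G1", 100, 400)])
        assert len(ops) == 1 and ops[0].gene_ids == ("G1", "G2")

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5000),
                st.integers(50, 800),
                st.sampled_from("+-"),
                st.sampled_from(["c1", "c2"]),
            ),
            min_size=1,
            max_size=25,
        ),
        st.integers(0, 120),
    )
    def test_output_partitions_input(self, raw, max_gap):
        genes = [
            _gene(f"g{i}", s, s + ln, strand, contig)
            for i, (s, ln, strand, contig) in enumerate(raw)
        ]
        ops = call_operons(genes, max_gap=max_gap)
        covered = [g for op in ops for g in op.gene_ids]
        assert sorted(covered) == sorted(g.gene_id for g in genes)
        for op in ops:
            members = [g for g in genes if g.gene_id in op.gene_ids]
            assert len({m.strand for m in members}) == 1
            assert len({m.contig for m in members}) == 1

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 300), min_size=1, max_size=15),
        st.integers(0, 80),
        st.integers(0, 80),
    )
    def test_raising_max_gap_never_shrinks_operons(self, gaps, g1, g2):
        lo, hi = sorted((g1, g2))
        pos = 0
        genes = []
        for i, gap in enumerate(gaps):
            genes.append(_gene(f"g{i}", pos, pos + 100))
            pos += 100 + gap
        small = call_operons(genes, max_gap=lo)
        large = call_operons(genes, max_gap=hi)
        assert len(large) <= len(small)

    def test_max_gap_zero_yields_singletons(self):
        genes = [_gene(f"g{i}", i * 200, i * 200 + 100) for i in range(5)]
        assert len(call_operons(genes, max_gap=0)) == 5


class TestExtractPromoters:
    def _genome(self, seq):
        return [NucSequence("c1", seq)]

    def test_plus_strand_window(self):
        rng = np.random.default_rng(0)
        genome = self._genome(random_sequence(5000, 0.5, rng))
        gene = _gene("G1", 1000, 2000, "+")
        op = Operon("op0", ("G1",), "+", "G1", "c1")
        (region,) = extract_promoters(genome, [op], [gene])
        assert (region.start, region.end) == (700, 1010)
        assert len(region.seq) == 310
        assert not region.clipped
        assert region.seq.seq == genome[0].seq[700:1010]

    def test_minus_strand_marker_recovered(self):
        # marker planted 50 bp upstream of a minus-strand start codon must
        # appear at oriented offset up - 50 - len(marker)
        rng = np.random.default_rng(1)
        raw = list(random_sequence(5000, 0.5, rng))
        e = 1000
        marker = "ACGTACGT"
        raw[e + 50 : e + 58] = list(revcomp(marker))
        genome = self._genome("".join(raw))
        gene = _gene("G1", 500, e, "-")
        op = Operon("op0", ("G1",), "-", "G1", "c1")
        (region,) = extract_promoters(genome, [op], [gene])
        assert (region.start, region.end) == (990, 1300)
        off = 300 - 50 - len(marker)
        assert region.seq.seq[off : off + len(marker)] == marker

    def test_minus_strand_downstream_overlaps_coding_start(self):
        rng = np.random.default_rng(2)
        genome = self._genome(random_sequence(3000, 0.5, rng))
        gene = _gene("G1", 500, 1000, "-")
        op = Operon("op0", ("G1",), "-", "G1", "c1")
        (region,) = extract_promoters(genome, [op], [gene])
        # last 10 oriented bases = revcomp of genome[990:1000] ... check first codon base
        assert region.seq.seq[300] == revcomp(genome[0].seq[999])

    def test_clipping_flagged_at_contig_edge(self):
        rng = np.random.default_rng(3)
        genome = self._genome(random_sequence(600, 0.5, rng))
        gene = _gene("G1", 100, 400, "+")
        op = Operon("op0", ("G1",), "+", "G1", "c1")
        (region,) = extract_promoters(genome, [op], [gene])
        assert region.clipped
        assert (region.start, region.end) == (0, 110)

    def test_missing_leader_is_error_naming_operon(self):
        genome = self._genome("ACGT" * 300)
        op = Operon("opX", ("GHOST",), "+", "GHOST", "c1")
        with pytest.raises(KeyError, match="opX"):
            extract_promoters(genome, [op], [])

    def test_circular_wraparound_behind_flag(self):
        rng = np.random.default_rng(4)
        raw = random_sequence(1000, 0.5, rng)
        genome = [NucSequence("c1", raw, circular=True)]
        gene = _gene("G1", 100, 400, "+")
        op = Operon("op0", ("G1",), "+", "G1", "c1")
        (region,) = extract_promoters(genome, [op], [gene], circular_wrap=True)
        assert len(region.seq) == 310
        assert not region.clipped
        assert region.seq.seq[:200] == raw[800:]


TABLE_ROWS = [
    ("cerR", 128.1, 63.4, None),
    ("rs15160", 77.1, 68.2, None),
    ("gtaR", 51.6, 24.6, None),
    ("cerM", 47.5, 42.9, None),
    ("p15394", 38.7, 37.7, None),
    ("cerN", 66.1, None, None),
    ("cerI", None, None, 281.5),
]


class TestClassifyDomains:
    @staticmethod
    def _records():
        return [
            DomainScoreRecord(pid, bind, hth, synth)
            for pid, bind, hth, synth in TABLE_ROWS
        ]

    def test_full_regulator(self):
        (rec,) = classify_domains([DomainScoreRecord("cerR", 128.1, 63.4, None)])
        assert rec.label == "LuxR_full"

    def test_truncated_regulator_lacking_hth(self):
        (rec,) = classify_domains([DomainScoreRecord("cerN", 66.1, None, None)])
        assert rec.label == "LuxR_truncated"

    def test_below_binding_cutoff_unclassified(self):
        (rec,) = classify_domains([DomainScoreRecord("x", 34.9, 25.0, None)])
        assert rec.label == "unclassified"

    def test_synthase(self):
        (rec,) = classify_domains([DomainScoreRecord("cerI", None, None, 281.5)])
        assert rec.label == "LuxI"

    def test_reference_rows_give_six_regulators_and_one_synthase(self):
        labels = [r.label for r in classify_domains(self._records())]
        assert labels.count("LuxR_full") == 5
        assert labels.count("LuxR_truncated") == 1
        assert labels.count("LuxI") == 1

    def test_dual_qualifier_flagged_as_conflict(self):
        (rec,) = classify_domains([DomainScoreRecord("both", 50.0, 30.0, 90.0)])
        assert rec.label == "LuxR_full" and rec.conflict


class TestIO:
    def test_annotation_tsv_round_trip(self, tmp_path):
        genes = [_gene("G1", 0, 100, "+"), _gene("G2", 150, 400, "-")]
        p = tmp_path / "ann.tsv"
        write_annotation_tsv(genes, p)
        back = read_annotation_tsv(p)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in back] == [
            ("G1", 0, 100, "+"),
            ("G2", 150, 400, "-"),
        ]

    def test_de_table_round_trip_with_na(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text("gene_id\tlog2fc\tpadj\ng1\t2.5\t0.001\ng2\t1.0\t\n")
        recs = read_de_table(p)
        assert recs[0].padj == 0.001
        assert recs[1].padj is None

    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tgene\t101\t400\t.\t+\t.\tID=G1;locus_tag=LT1\n"
            "c1\tsrc\tgene\t501\t900\t.\t-\t.\tID=G2\n"
        )
        genes = read_gff3(gff)
        assert (genes[0].start, genes[0].end) == (100, 400)
        assert genes[1].strand == "-"

    def test_domain_scores_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "protein_id\tscore_autoind_bind\tscore_gere_hth\tscore_autoind_synth\n"
            "p1\t66.1\t\t\n"
        )
        (rec,) = read_domain_scores(p)
        assert rec.score_autoind_bind == 66.1
        assert rec.score_gere_hth is None
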
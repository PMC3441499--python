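import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netlab import network_io as nio

SYMBOLS = st.text(alphabet="ABCDEFGHIJ", min_size=1, max_size=4)


def make_records(pairs, conf=0.5):
    return [nio.InteractionRecord(a, b, conf) for a, b in pairs]


class TestParseEdgeTable:
    def test_empty_stream(self):
        assert nio.parse_edge_table("") == []

    def test_case_folding_makes_duplicates_identical(self):
        text = ("RAC1\tCDC42\t0.9\texp\n"
                "RAC1\tPAK1\t0.5\texp\n"
                "rac1\tpak1\t0.5\texp\n")
        records = nio.parse_edge_table(text)
        assert len(records) == 3
        assert records[2] == records[1]

    def test_header_autodetected(self):
        text = "protein_a\tprotein_b\tscore\tevidence\nRAC1\tPAK1\t0.5\texp\n"
        assert len(nio.parse_edge_table(text)) == 1

    def test_sif_fanout(self):
        records = nio.parse_edge_table("RAC1 pp PAK1 CDC42\n", dialect="sif")
        assert [(r.source_symbol, r.target_symbol) for r in records] == \
            [("RAC1", "PAK1"), ("RAC1", "CDC42")]
        assert all(r.confidence == 1.0 and r.evidence_tag == "pp" for r in records)

    def test_malformed_row_names_line(self):
        with pytest.raises(nio.EdgeTableError, match="line 2"):
            nio.parse_edge_table("A\tB\t0.5\nonlyonefield\n")

    def test_confidence_out_of_range_rejected(self):
        with pytest.raises(nio.EdgeTableError, match="line 1"):
            nio.parse_edge_table("A\tB\t1.5\n")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(SYMBOLS, SYMBOLS,
                              st.floats(0.0, 1.0, allow_nan=False)),
                    min_size=1, max_size=50))
    def test_tsv_round_trip(self, rows):
        records = [nio.InteractionRecord(a, b, c, "exp") for a, b, c in rows]
        buf = io.StringIO()
        nio.write_edge_table(records, buf)
        assert nio.parse_edge_table(buf.getvalue()) == records

    def test_sif_round_trip_preserves_edges(self):
        records = make_records([("A", "B"), ("C", "D"), ("B", "C")], 1.0)
        buf = io.StringIO()
        nio.write_edge_table(records, buf, dialect="sif")
        reparsed = nio.parse_edge_table(buf.getvalue(), dialect="sif")
        assert [r.pair for r in reparsed] == [r.pair for r in records]


class TestFilterByConfidence:
    def test_zero_threshold_keeps_all(self):
        records = make_records([("A", "B")] * 5, 0.01)
        assert nio.filter_by_confidence(records, 0.0) == records

    def test_threshold_is_inclusive(self):
        records = [nio.InteractionRecord("A", "B", c) for c in (0.39, 0.40, 0.41)]
        kept = nio.filter_by_confidence(records, 0.4)
        assert [r.confidence for r in kept] == [0.40, 0.41]

    def test_medium_high_confidence_split_retained(self):
        # two thirds medium [0.4, 0.7), one third high [0.7, 1.0]
        records = ([nio.InteractionRecord("A", f"M{i}", 0.55) for i in range(200)]
                   + [nio.InteractionRecord("A", f"H{i}", 0.85) for i in range(100)])
        kept = nio.filter_by_confidence(records, 0.4)
        assert len(kept) == 300
        medium = sum(1 for r in kept if 0.4 <= r.confidence < 0.7)
        assert medium / len(kept) == pytest.approx(2 / 3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), max_size=40))
    def test_filter_idempotent(self, confs):
        records = [nio.InteractionRecord("A", "B", c) for c in confs]
        once = nio.filter_by_confidence(records, 0.4)
        assert nio.filter_by_confidence(once, 0.4) == once


class TestBuildNetwork:
    def test_dedup_and_self_loop_rule(self):
        records = make_records([("A", "B"), ("B", "A"), ("C", "C")])
        net = nio.build_network(records)
        assert sorted(net.edges()) == [("A", "B")]
        assert "C" not in net  # self-loop-only symbol dropped without annotation

    def test_self_loop_symbol_kept_when_annotated(self):
        ann = {"C": nio.ProteinNode("C", "RAB", is_gtpase=True)}
        net = nio.build_network(make_records([("C", "C")]), ann)
        assert net.degree("C") == 0

    def test_duplicated_triangle_collapses(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        net = nio.build_network(make_records(tri + tri))
        assert net.number_of_edges() == 3

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.tuples(SYMBOLS, SYMBOLS), min_size=1, max_size=100))
    def test_edge_count_equals_distinct_pairs(self, pairs):
        distinct = {frozenset(p) for a, b in pairs
                    if (p := (a.upper(), b.upper()))[0] != p[1]}
        net = nio.build_network(make_records(pairs))
        assert net.number_of_edges() == len(distinct)
        assert sum(d for _, d in net.degree()) == 2 * net.number_of_edges()


class TestUnion:
    def test_idempotent(self, triangle):
        merged = nio.union([triangle, triangle])
        assert merged.number_of_nodes() == 3
        assert merged.number_of_edges() == 3

    def test_disjoint_additivity(self):
        g1 = nio.build_network(make_records([("A", "B"), ("B", "C"), ("A", "C")]))
        g2 = nio.build_network(make_records([("X", "Y"), ("Y", "Z"), ("X", "Z")]))
        merged = nio.union([g1, g2])
        assert merged.number_of_nodes() == 6
        assert merged.number_of_edges() == 6

    def test_overlap_set_union(self):
        e1 = [("A", "B"), ("B", "C"), ("C", "D")]
        e2 = [("B", "C"), ("C", "D"), ("D", "E")]
        merged = nio.union([nio.build_network(make_records(e1)),
                            nio.build_network(make_records(e2))])
        assert merged.number_of_edges() == len({frozenset(e) for e in e1 + e2})

    def test_subfamily_conflict_errors(self):
        g1 = nio.build_network(make_records([("A", "B")]),
                               {"A": nio.ProteinNode("A", "RHO", True)})
        g2 = nio.build_network(make_records([("A", "C")]),
                               {"A": nio.ProteinNode("A", "RAS", True)})
        with pytest.raises(ValueError, match="conflicting subfamily"):
            nio.union([g1, g2])


UNSUPPORTED_SEVEN = [("RAC1", "CDC42"), ("HRAS", "RHEB"), ("HRAS", "RAP1B"),
                     ("HRAS", "ARHGEF1"), ("RHOA", "PLEKHG2"),
                     ("RAB5A", "RAB7A"), ("RAB5A", "RIT2")]


class TestExcludeEdges:
    def test_unvalidated_pairs_removed(self):
        extra = [("RAC1", "PAK1"), ("HRAS", "RAF1")]
        net = nio.build_network(make_records(UNSUPPORTED_SEVEN + extra))
        pruned = nio.exclude_edges(net, UNSUPPORTED_SEVEN)
        assert net.number_of_edges() - pruned.number_of_edges() == 7

    def test_empty_blacklist_identity(self, triangle):
        pruned = nio.exclude_edges(triangle, [])
        assert set(pruned.edges()) == set(triangle.edges())

    def test_missing_pair_noop(self, triangle):
        pruned = nio.exclude_edges(triangle, [("X", "Y")])
        assert pruned.number_of_edges() == 3


class TestConfidenceSummary:
    def test_degenerate_spread(self):
        s = nio.confidence_summary(make_records([("A", "B")] * 4, 0.5))
        assert s.mean == 0.5 and s.sd == 0.0

    def test_population_sd(self):
        records = [nio.InteractionRecord("A", "B", c) for c in (0.4, 0.6, 0.8)]
        s = nio.confidence_summary(records)
        assert s.mean == pytest.approx(0.6)
        assert s.sd == pytest.approx(math.sqrt(0.08 / 3))

    def test_bins_sum_to_n(self, default_fixture):
        _, records, _ = default_fixture
        s = nio.confidence_summary(records)
        assert sum(s.bin_counts.values()) == s.n == len(records)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            nio.confidence_summary([])


class TestCurationReport:
    @pytest.mark.parametrize("considered,unsupported,pct",
                             [(429, 7, 98.4), (100, 0, 100.0), (429, 12, 97.2)])
    def test_confirmed_percent(self, considered, unsupported, pct):
        stats = nio.curation_report(considered, unsupported)
        assert round(stats.pct_confirmed, 1) == pct

    def test_zero_considered_errors(self):
        with pytest.raises(ValueError):
            nio.curation_report(0, 0)
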
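"""Candidate structure enumeration: canonical forms, oracle agreement, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_cycles, oracle_canonical, random_small_graph
from ecdna_catch.camper import (
    AmpliconPath,
    EnumerationOptions,
    NonCircularPathError,
    canonicalize_cycle,
    canonical_key_str,
    cycle_length,
    enumerate_candidates,
    parse_cycles,
    score_candidate,
    write_bed,
    write_cycles,
)
from ecdna_catch.graph_model import CutSite, GelBand, estimate_multiplicities

steps_strategy = st.lists(
    st.tuples(st.integers(min_value=1, max_value=8), st.sampled_from(["+", "-"])),
    min_size=1, max_size=6,
).map(tuple)


class TestCanonicalization:
    def test_rotations_share_a_key(self):
        a = AmpliconPath(steps=((1, "+"), (2, "+"), (3, "+")))
        b = AmpliconPath(steps=((2, "+"), (3, "+"), (1, "+")))
        assert canonicalize_cycle(a) == canonicalize_cycle(b)

    def test_reflection_shares_a_key(self):
        a = AmpliconPath(steps=((1, "+"), (2, "+")))
        b = AmpliconPath(steps=((2, "-"), (1, "-")))
        assert canonicalize_cycle(a) == canonicalize_cycle(b)

    def test_distinct_orientation_patterns_differ(self):
        a = AmpliconPath(steps=((1, "+"), (2, "+")))
        b = AmpliconPath(steps=((1, "+"), (2, "-")))
        assert canonicalize_cycle(a) != canonicalize_cycle(b)

    def test_linear_path_rejected(self):
        with pytest.raises(NonCircularPathError):
            canonicalize_cycle(AmpliconPath(steps=((1, "+"),), circular=False))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(steps=steps_strategy, rotation=st.integers(min_value=0, max_value=5))
    def test_rotation_and_reversal_invariance(self, steps, rotation):
        r = rotation % len(steps)
        rotated = steps[r:] + steps[:r]
        reversed_flipped = tuple(
            (s, "-" if o == "+" else "+") for s, o in reversed(steps)
        )
        key = canonicalize_cycle(AmpliconPath(steps=steps))
        assert canonicalize_cycle(AmpliconPath(steps=rotated)) == key
        assert canonicalize_cycle(AmpliconPath(steps=reversed_flipped)) == key
        assert key == oracle_canonical(steps)  # agrees with the test-side form


class TestCycleLength:
    def test_single_traversal(self, self_circle_graph):
        # an 890,900-bp segment traversed once measures 890.9 kb
        from ecdna_catch.graph_model import BreakpointGraph, GenomeSegment
        g = BreakpointGraph(
            segments=[GenomeSegment(id=1, chrom="chr1", start=0, end=890_900, cn=30)],
            edges=[],
        )
        assert cycle_length(AmpliconPath(steps=((1, "+"),)), g) == 890_900

    def test_repeated_traversal_counts_twice(self, three_cycle_graph):
        path = AmpliconPath(steps=((1, "+"), (1, "-")))
        assert cycle_length(path, three_cycle_graph) == 2 * 200_000

    def test_empty_path_is_zero(self, three_cycle_graph):
        assert cycle_length(AmpliconPath(steps=()), three_cycle_graph) == 0

    def test_unknown_segment_raises(self, three_cycle_graph):
        with pytest.raises(KeyError, match="99"):
            cycle_length(AmpliconPath(steps=((99, "+"),)), three_cycle_graph)


class TestEnumeration:
    def test_single_segment_circle_in_band(self, self_circle_graph):
        """A 1.258-Mb self-circle with one interior cut and a 1200-1370 kb band."""
        mult = estimate_multiplicities(self_circle_graph)
        options = EnumerationOptions(
            band=GelBand(size_min_kb=1200, size_max_kb=1370),
            cuts=[CutSite(chrom="chr7", position=54_500_000, guide="A")],
        )
        result = enumerate_candidates(self_circle_graph, mult, options)
        assert len(result) == 1
        assert result.candidates[0].length_bp == 1_258_000
        assert not result.truncated

    def test_band_excluding_the_cycle_gives_nothing(self, self_circle_graph):
        mult = estimate_multiplicities(self_circle_graph)
        options = EnumerationOptions(band=GelBand(size_min_kb=200, size_max_kb=400))
        assert len(enumerate_candidates(self_circle_graph, mult, options)) == 0

    def test_compression_zone_band_flagged_and_skipped(self, self_circle_graph):
        mult = estimate_multiplicities(self_circle_graph)
        options = EnumerationOptions(band=GelBand(size_min_kb=1000, size_max_kb=2500))
        result = enumerate_candidates(self_circle_graph, mult, options)
        assert result.compression_zone
        assert len(result) == 0

    def test_alternative_bridging_edges_both_found(self):
        """Two alternative junctions admit two cycles; both are enumerated."""
        from ecdna_catch.graph_model import (
            HEAD, TAIL, BreakpointEdge, BreakpointGraph, GenomeSegment,
        )
        segs = [
            GenomeSegment(id=1, chrom="c", start=0, end=100_000, cn=40),
            GenomeSegment(id=2, chrom="c", start=200_000, end=320_000, cn=40),
            GenomeSegment(id=3, chrom="c", start=400_000, end=480_000, cn=40),
            GenomeSegment(id=4, chrom="c", start=600_000, end=750_000, cn=40),
        ]
        edges = [
            BreakpointEdge(left=(1, TAIL), right=(2, HEAD)),
            BreakpointEdge(left=(2, TAIL), right=(1, HEAD)),   # short circle 1-2
            BreakpointEdge(left=(2, TAIL), right=(3, HEAD)),   # detour via 3,4
            BreakpointEdge(left=(3, TAIL), right=(4, HEAD)),
            BreakpointEdge(left=(4, TAIL), right=(1, HEAD)),
        ]
        g = BreakpointGraph(segments=segs, edges=edges)
        mult = {i: 1 for i in range(1, 5)}
        band = GelBand(size_min_kb=100, size_max_kb=600)
        result = enumerate_candidates(g, mult, EnumerationOptions(band=band))
        got = {c.canonical for c in result}
        expected = brute_force_cycles(g, mult, band)
        assert got == expected
        assert len(got) == 2

    def test_oracle_equivalence_on_random_graphs(self):
        """DFS enumeration equals exhaustive closed-walk enumeration."""
        rng = np.random.default_rng(20_240_101)
        for _ in range(40):
            graph, mult, band = random_small_graph(rng)
            result = enumerate_candidates(
                graph, mult, EnumerationOptions(band=band, max_candidates=100_000)
            )
            assert {c.canonical for c in result} == brute_force_cycles(graph, mult, band)

    def test_widening_the_band_never_removes_candidates(self):
        rng = np.random.default_rng(77)
        graph, mult, band = random_small_graph(rng)
        narrow = enumerate_candidates(graph, mult, EnumerationOptions(band=band))
        wide_band = GelBand(size_min_kb=band.size_min_kb / 2,
                            size_max_kb=min(band.size_max_kb * 1.5, 2199))
        wide = enumerate_candidates(graph, mult, EnumerationOptions(band=wide_band))
        assert {c.canonical for c in narrow} <= {c.canonical for c in wide}

    def test_single_guide_cut_traversal_is_exactly_once(self, three_cycle_graph):
        """With multiplicity 2 everywhere, circles using the cut segment twice drop."""
        mult = {1: 2, 2: 2, 3: 2}
        cut = CutSite(chrom="chr8", position=1_100_000, guide="A")  # inside segment 1
        band = GelBand(size_min_kb=100, size_max_kb=2000)
        result = enumerate_candidates(
            three_cycle_graph, mult, EnumerationOptions(band=band, cuts=[cut])
        )
        assert len(result) > 0
        for cand in result:
            assert cand.multiplicity_used.get(1, 0) == 1

    def test_truncation_is_flagged(self, three_cycle_graph):
        mult = {1: 2, 2: 2, 3: 2}
        band = GelBand(size_min_kb=100, size_max_kb=2000)
        result = enumerate_candidates(
            three_cycle_graph, mult, EnumerationOptions(band=band, max_candidates=1)
        )
        assert result.truncated

    def test_determinism_of_ordering(self):
        rng = np.random.default_rng(123)
        graph, mult, band = random_small_graph(rng)
        opts = EnumerationOptions(band=band)
        first = [c.canonical for c in enumerate_candidates(graph, mult, opts)]
        second = [c.canonical for c in enumerate_candidates(graph, mult, opts)]
        assert first == second


class TestScoring:
    def test_perfect_candidate(self, self_circle_graph):
        mult = estimate_multiplicities(self_circle_graph)
        band = GelBand(size_min_kb=1158, size_max_kb=1358)  # midpoint = 1258
        result = enumerate_candidates(
            self_circle_graph, mult, EnumerationOptions(band=band)
        )
        scores = result.candidates[0].scores
        assert scores.length_score == pytest.approx(1.0)
        assert scores.edge_utilization == 1.0
        assert result.candidates[0].pass_filter

    def test_length_at_band_edge_scores_zero(self, self_circle_graph):
        mult = estimate_multiplicities(self_circle_graph)
        band = GelBand(size_min_kb=1258, size_max_kb=1458)  # cycle sits on the edge
        result = enumerate_candidates(
            self_circle_graph, mult, EnumerationOptions(band=band)
        )
        cand = result.candidates[0]
        assert cand.scores.length_score == pytest.approx(0.0)
        assert not cand.pass_filter

    def test_partial_edge_utilization(self, three_cycle_graph):
        """A 2-of-3 discordant-edge walk scores utilization 2/3."""
        from ecdna_catch.graph_model import BreakpointEdge, BreakpointGraph, HEAD, TAIL
        extra = BreakpointEdge(left=(2, TAIL), right=(1, HEAD), support=5)
        g = BreakpointGraph(
            segments=list(three_cycle_graph.segments),
            edges=list(three_cycle_graph.edges) + [extra],
        )
        from ecdna_catch.camper import CandidateStructure
        path = AmpliconPath(steps=((1, "+"), (2, "+")))  # uses edges 1->2 and extra
        cand = CandidateStructure(path=path, length_bp=cycle_length(path, g),
                                  multiplicity_used={1: 1, 2: 1})
        scores = score_candidate(cand, g, GelBand(size_min_kb=100, size_max_kb=900))
        assert scores.edge_utilization == pytest.approx(2 / 4)


class TestOutputs:
    def test_cycles_round_trip(self, three_cycle_graph, tmp_path):
        mult = {1: 1, 2: 1, 3: 1}
        band = GelBand(size_min_kb=100, size_max_kb=1000)
        result = enumerate_candidates(three_cycle_graph, mult, EnumerationOptions(band=band))
        out = tmp_path / "c.cycles"
        write_cycles(result.candidates, three_cycle_graph, out)
        text = out.read_text()
        assert text.count("Cycle=") == len(result)
        assert text.count("Segment\t") == 3
        paths = parse_cycles(out)
        assert [canonicalize_cycle(p) for p in paths] == [c.canonical for c in result]

    def test_bed_rows_one_per_traversal(self, three_cycle_graph, tmp_path):
        mult = {1: 1, 2: 1, 3: 1}
        band = GelBand(size_min_kb=100, size_max_kb=1000)
        result = enumerate_candidates(three_cycle_graph, mult, EnumerationOptions(band=band))
        out = tmp_path / "c.bed"
        write_bed(result.candidates, three_cycle_graph, out)
        rows = [l.split("\t") for l in out.read_text().splitlines()]
        assert len(rows) == 3
        assert all(r[3].startswith("cycle1_") for r in rows)
        assert int(rows[0][1]) < int(rows[0][2])

    def test_writing_no_candidates_is_an_error(self, three_cycle_graph, tmp_path):
        with pytest.raises(ValueError, match="no candidates"):
            write_cycles([], three_cycle_graph, tmp_path / "c.cycles")
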
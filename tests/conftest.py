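"""Shared fixtures and the independent brute-force cycle oracle.

The oracle enumerates *every* bounded closed walk by exhaustive recursion
from every oriented starting segment, with its own edge-existence check and
its own canonicalization — it shares no code path with the DFS enumerator
it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecdna_catch.graph_model import (
    HEAD,
    TAIL,
    BreakpointEdge,
    BreakpointGraph,
    GelBand,
    GenomeSegment,
)


# ---------------------------------------------------------------------------
# Small reference graphs
# ---------------------------------------------------------------------------

@pytest.fixture
def self_circle_graph() -> BreakpointGraph:
    """Single 1,258,000-bp segment circularized head-to-tail (GBM39-like)."""
    seg = GenomeSegment(id=1, chrom="chr7", start=54_000_000, end=55_258_000, cn=92.0)
    edge = BreakpointEdge(left=(1, TAIL), right=(1, HEAD), support=120, kind="discordant")
    return BreakpointGraph(segments=[seg], edges=[edge])


@pytest.fixture
def three_cycle_graph() -> BreakpointGraph:
    """Three segments joined tail-to-head into one circle."""
    segs = [
        GenomeSegment(id=1, chrom="chr8", start=1_000_000, end=1_200_000, cn=40.0),
        GenomeSegment(id=2, chrom="chr8", start=2_000_000, end=2_300_000, cn=40.0),
        GenomeSegment(id=3, chrom="chr11", start=5_000_000, end=5_150_000, cn=40.0),
    ]
    edges = [
        BreakpointEdge(left=(1, TAIL), right=(2, HEAD), support=50),
        BreakpointEdge(left=(2, TAIL), right=(3, HEAD), support=50),
        BreakpointEdge(left=(3, TAIL), right=(1, HEAD), support=50),
    ]
    return BreakpointGraph(segments=segs, edges=edges)


# ---------------------------------------------------------------------------
# Brute-force closed-walk oracle
# ---------------------------------------------------------------------------

def _edge_keys(graph: BreakpointGraph) -> set[frozenset]:
    keys = set()
    for e in graph.edges:
        keys.add(frozenset((e.left, e.right)) if e.left != e.right else frozenset((e.left,)))
    return keys


def _junction(step_a, step_b) -> frozenset:
    a_exit = (step_a[0], TAIL if step_a[1] == "+" else HEAD)
    b_entry = (step_b[0], HEAD if step_b[1] == "+" else TAIL)
    return frozenset((a_exit, b_entry)) if a_exit != b_entry else frozenset((a_exit,))


def oracle_canonical(steps: tuple) -> tuple:
    """Independent rotation/reflection-invariant key (lexicographic minimum)."""
    rev = tuple((s, "-" if o == "+" else "+") for s, o in reversed(steps))
    forms = []
    for seq in (tuple(steps), rev):
        for r in range(len(seq)):
            forms.append(seq[r:] + seq[:r])
    return min(forms)


def brute_force_cycles(
    graph: BreakpointGraph,
    multiplicities: dict[int, int],
    band: GelBand,
    cut_segments: tuple[int, ...] = (),
    single_guide: bool = True,
) -> set[tuple]:
    """All canonical circular walks satisfying the constraints, by exhaustion."""
    edges = _edge_keys(graph)
    lengths = {s.id: s.length for s in graph.segments}
    max_bp = band.size_max_kb * 1000.0
    min_bp = band.size_min_kb * 1000.0
    total_budget = sum(m for m in multiplicities.values() if m > 0)
    results: set[tuple] = set()

    def ok_cuts(steps) -> bool:
        if not cut_segments:
            return True
        counts = {sid: 0 for sid in cut_segments}
        for sid, _o in steps:
            if sid in counts:
                counts[sid] += 1
        if single_guide:
            return all(c == 1 for c in counts.values())
        return any(c >= 1 for c in counts.values())

    def extend(steps, used, length):
        if len(steps) > total_budget:
            return
        if length > max_bp:
            return
        # try closing
        if steps and _junction(steps[-1], steps[0]) in edges and length >= min_bp:
            if ok_cuts(steps):
                results.add(oracle_canonical(tuple(steps)))
        for sid, mult in multiplicities.items():
            if used.get(sid, 0) >= mult or sid not in lengths:
                continue
            for orient in ("+", "-"):
                nxt = (sid, orient)
                if steps and _junction(steps[-1], nxt) not in edges:
                    continue
                used[sid] = used.get(sid, 0) + 1
                steps.append(nxt)
                extend(steps, used, length + lengths[sid])
                steps.pop()
                used[sid] -= 1

    extend([], {}, 0.0)
    return results


def random_small_graph(rng: np.random.Generator):
    """A random graph with <= 6 segments, multiplicities <= 2, sparse edges."""
    n = int(rng.integers(2, 7))
    segs = []
    pos = 1_000_000
    for i in range(1, n + 1):
        length = int(rng.integers(50_000, 300_000))
        gap = int(rng.integers(10_000, 50_000))
        segs.append(GenomeSegment(id=i, chrom="chrS", start=pos + gap,
                                  end=pos + gap + length, cn=40.0))
        pos = pos + gap + length
    mult = {i: int(rng.integers(1, 3)) for i in range(1, n + 1)}
    # a guaranteed cycle through all segments plus a couple of random chords
    ends = []
    order = rng.permutation(n) + 1
    orients = rng.choice(["+", "-"], size=n)
    edges = []
    seen = set()
    for j in range(n):
        a, oa = int(order[j]), orients[j]
        b, ob = int(order[(j + 1) % n]), orients[(j + 1) % n]
        left = (a, TAIL if oa == "+" else HEAD)
        right = (b, HEAD if ob == "+" else TAIL)
        key = frozenset((left, right)) if left != right else frozenset((left,))
        if key not in seen:
            seen.add(key)
            edges.append(BreakpointEdge(left=left, right=right, support=10))
    for _ in range(int(rng.integers(0, 3))):
        a = int(rng.integers(1, n + 1))
        b = int(rng.integers(1, n + 1))
        left = (a, rng.choice([HEAD, TAIL]))
        right = (b, rng.choice([HEAD, TAIL]))
        key = frozenset((left, right)) if left != right else frozenset((left,))
        if key not in seen:
            seen.add(key)
            edges.append(BreakpointEdge(left=tuple(left), right=tuple(right), support=5))
    graph = BreakpointGraph(segments=segs, edges=edges)
    total_len = sum(s.length for s in segs)
    # stay below the compression-zone cutoff so enumeration actually runs
    band = GelBand(size_min_kb=1.0,
                   size_max_kb=min(2199.0, max(2.0, 2.0 * total_len / 1000.0)))
    return graph, mult, band
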
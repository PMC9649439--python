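"""Copy-number-aware breakpoint graphs, cut sites and gel bands.

The substrate for ecDNA amplicon reconstruction is a breakpoint graph: a set
of amplified genomic segments, each carrying an estimated copy number (CN),
connected by *concordant* edges (reference-adjacent segment ends) and
*discordant* edges (rearrangement junctions supported by read pairs or split
reads).  Pulsed-field gel electrophoresis (PFGE) contributes an independent
molecule-size window per isolated band, and CRISPR sgRNA cut sites constrain
which circles could have been linearized into that band.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  The graph file dialect
stores 1-based segment boundary positions: a ``sequence`` record
``chrom:S-  chrom:E+`` covers the bases ``[S-1, E-1)`` internally, so its
length is ``E - S``.  Parsing and writing are exact inverses.

Orientation is encoded per segment end: the ``head`` is the low-coordinate
(start) boundary and the ``tail`` the high-coordinate (end) boundary.  A
``+`` traversal of a segment enters at the head and exits at the tail; a
``-`` traversal enters at the tail and exits at the head.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

HEAD = "head"
TAIL = "tail"

#: Default background (diploid) copy number used for multiplicity estimates.
DEFAULT_BACKGROUND_CN = 2.0


class GraphParseError(ValueError):
    """Raised when a graph file line cannot be interpreted."""


class GraphValidationError(ValueError):
    """Raised when a structurally invalid graph is constructed."""


@dataclass(frozen=True)
class GenomeSegment:
    """An amplified genomic interval with an estimated copy number."""

    id: int
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    cn: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GraphValidationError(
                f"segment {self.id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.cn < 0:
            raise GraphValidationError(f"segment {self.id}: negative copy number {self.cn}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        return self.chrom == chrom and self.start <= position < self.end


@dataclass(frozen=True)
class BreakpointEdge:
    """An adjacency between two oriented segment ends.

    ``kind`` distinguishes reference-adjacent (``concordant``) joins from
    rearrangement (``discordant``) junctions; both are traversable during
    cycle enumeration.
    """

    left: tuple[int, str]   # (segment id, HEAD|TAIL)
    right: tuple[int, str]
    support: int = 0
    kind: str = "discordant"

    def __post_init__(self) -> None:
        for seg_id, side in (self.left, self.right):
            if side not in (HEAD, TAIL):
                raise GraphValidationError(f"unknown segment side {side!r}")
        if self.support < 0:
            raise GraphValidationError("edge support must be non-negative")
        if self.kind not in ("concordant", "discordant"):
            raise GraphValidationError(f"unknown edge kind {self.kind!r}")

    @property
    def key(self) -> frozenset:
        """Unordered endpoint identity (an edge is undirected)."""
        return frozenset((self.left, self.right)) if self.left != self.right else frozenset((self.left,))

    def other_end(self, end: tuple[int, str]) -> tuple[int, str]:
        if end == self.left:
            return self.right
        if end == self.right:
            return self.left
        raise KeyError(f"{end} is not an endpoint of this edge")


@dataclass(frozen=True)
class CutSite:
    """A CRISPR sgRNA cut position (0-based)."""

    chrom: str
    position: int
    guide: str = ""


@dataclass(frozen=True)
class GelBand:
    """A PFGE molecule-size window in kilobases."""

    size_min_kb: float
    size_max_kb: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.size_min_kb < self.size_max_kb):
            raise GraphValidationError(
                f"band {self.label!r}: require 0 < min ({self.size_min_kb}) < max ({self.size_max_kb})"
            )

    @property
    def midpoint_kb(self) -> float:
        return 0.5 * (self.size_min_kb + self.size_max_kb)

    @property
    def halfwidth_kb(self) -> float:
        return 0.5 * (self.size_max_kb - self.size_min_kb)

    def contains_kb(self, size_kb: float) -> bool:
        return self.size_min_kb <= size_kb <= self.size_max_kb


@dataclass
class BreakpointGraph:
    """A validated collection of segments and edges."""

    segments: list[GenomeSegment]
    edges: list[BreakpointEdge]
    source: str = ""
    _by_id: dict[int, GenomeSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise GraphValidationError("duplicate segment ids")
        self._check_overlaps()
        for e in self.edges:
            for seg_id, _side in (e.left, e.right):
                if seg_id not in self._by_id:
                    raise GraphValidationError(f"edge references unknown segment id {seg_id}")

    def _check_overlaps(self) -> None:
        by_chrom: dict[str, list[GenomeSegment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise GraphValidationError(
                        f"overlapping segments on {chrom}: {a.id} [{a.start},{a.end}) "
                        f"and {b.id} [{b.start},{b.end})"
                    )

    def segment(self, seg_id: int) -> GenomeSegment:
        return self._by_id[seg_id]

    @property
    def discordant_edges(self) -> list[BreakpointEdge]:
        return [e for e in self.edges if e.kind == "discordant"]

    def edges_at(self, end: tuple[int, str]) -> list[BreakpointEdge]:
        return [e for e in self.edges if end in (e.left, e.right)]


# ---------------------------------------------------------------------------
# Graph file I/O
# ---------------------------------------------------------------------------

_SEQ_COORD = re.compile(r"^(?P<chrom>[\w.]+):(?P<pos>[\d,]+)(?P<sign>[+-])$")
_BP_COORD = re.compile(r"^(?P<chrom>[\w.]+):(?P<pos>[\d,]+)(?P<dir>[+-])$")


def _parse_pos(text: str) -> int:
    return int(text.replace(",", ""))


def parse_graph_file(path) -> BreakpointGraph:
    """Parse a tab-separated breakpoint-graph file.

    Records::

        sequence<TAB>chrom:START-<TAB>chrom:END+<TAB>CN
        discordant<TAB>chrom1:POS1<d1>-><chrom2:POS2<d2>><TAB>SUPPORT
        concordant<TAB>... (same shape as discordant)

    ``#`` lines are comments.  Breakpoint directions follow the usual
    convention: ``pos+`` attaches to the tail of the segment whose file end
    equals ``pos``; ``pos-`` attaches to the head of the segment whose file
    start equals ``pos``.
    """
    segments: list[GenomeSegment] = []
    raw_edges: list[tuple[int, str, str, int]] = []  # (lineno, edge_text, kind, support)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            rectype = fields[0]
            if rectype == "sequence":
                if len(fields) != 4:
                    raise GraphParseError(
                        f"{path}:{lineno}: sequence record needs 4 fields, got {len(fields)}"
                    )
                m1 = _SEQ_COORD.match(fields[1])
                m2 = _SEQ_COORD.match(fields[2])
                if not m1 or not m2 or m1["sign"] != "-" or m2["sign"] != "+":
                    raise GraphParseError(
                        f"{path}:{lineno}: malformed sequence coordinates {fields[1]!r} {fields[2]!r}"
                    )
                if m1["chrom"] != m2["chrom"]:
                    raise GraphParseError(
                        f"{path}:{lineno}: sequence record spans two chromosomes"
                    )
                try:
                    cn = float(fields[3])
                except ValueError as err:
                    raise GraphParseError(f"{path}:{lineno}: bad copy number {fields[3]!r}") from err
                start_file = _parse_pos(m1["pos"])
                end_file = _parse_pos(m2["pos"])
                try:
                    segments.append(
                        GenomeSegment(
                            id=len(segments) + 1,
                            chrom=m1["chrom"],
                            start=start_file - 1,
                            end=end_file - 1,
                            cn=cn,
                        )
                    )
                except GraphValidationError as err:
                    raise GraphParseError(f"{path}:{lineno}: {err}") from err
            elif rectype in ("discordant", "concordant"):
                if len(fields) != 3:
                    raise GraphParseError(
                        f"{path}:{lineno}: {rectype} record needs 3 fields, got {len(fields)}"
                    )
                try:
                    support = int(fields[2])
                except ValueError as err:
                    raise GraphParseError(f"{path}:{lineno}: bad support {fields[2]!r}") from err
                raw_edges.append((lineno, fields[1], rectype, support))
            else:
                raise GraphParseError(f"{path}:{lineno}: unknown record type {rectype!r}")

    if not segments:
        raise GraphValidationError(f"{path}: no sequence records (empty graph)")

    edges = [_resolve_edge(path, lineno, edge_text, kind, support, segments)
             for lineno, edge_text, kind, support in raw_edges]
    return BreakpointGraph(segments=segments, edges=edges, source=str(path))


def _resolve_edge(path, lineno: int, edge_text: str, kind: str, support: int,
                  segments: list[GenomeSegment]) -> BreakpointEdge:
    if "->" not in edge_text:
        raise GraphParseError(f"{path}:{lineno}: malformed edge {edge_text!r}")
    left_s, right_s = edge_text.split("->", 1)
    ends = []
    for part in (left_s, right_s):
        m = _BP_COORD.match(part)
        if not m:
            raise GraphParseError(f"{path}:{lineno}: malformed breakpoint {part!r}")
        chrom, pos, direction = m["chrom"], _parse_pos(m["pos"]), m["dir"]
        ends.append(_match_boundary(path, lineno, chrom, pos, direction, segments))
    return BreakpointEdge(left=ends[0], right=ends[1], support=support, kind=kind)


def _match_boundary(path, lineno: int, chrom: str, file_pos: int, direction: str,
                    segments: list[GenomeSegment]) -> tuple[int, str]:
    for seg in segments:
        if seg.chrom != chrom:
            continue
        if direction == "+" and seg.end == file_pos - 1:
            return (seg.id, TAIL)
        if direction == "-" and seg.start == file_pos - 1:
            return (seg.id, HEAD)
    raise GraphParseError(
        f"{path}:{lineno}: breakpoint {chrom}:{file_pos}{direction} does not match any segment boundary"
    )


def write_graph_file(graph: BreakpointGraph, path) -> None:
    """Inverse of :func:`parse_graph_file` (exact coordinate round trip)."""
    with open(path, "w") as fh:
        fh.write("# breakpoint graph\n")
        for seg in graph.segments:
            fh.write(
                f"sequence\t{seg.chrom}:{seg.start + 1}-\t{seg.chrom}:{seg.end + 1}+\t{seg.cn:.4f}\n"
            )
        for edge in graph.edges:
            parts = []
            for seg_id, side in (edge.left, edge.right):
                seg = graph.segment(seg_id)
                if side == TAIL:
                    parts.append(f"{seg.chrom}:{seg.end + 1}+")
                else:
                    parts.append(f"{seg.chrom}:{seg.start + 1}-")
            fh.write(f"{edge.kind}\t{parts[0]}->{parts[1]}\t{edge.support}\n")


def write_segments_bed(graph: BreakpointGraph, path) -> None:
    """Write segment intervals as BED (0-based half-open, native convention)."""
    with open(path, "w") as fh:
        for seg in graph.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\tsegment_{seg.id}\t{seg.cn:.4f}\n")


# ---------------------------------------------------------------------------
# Multiplicity estimation
# ---------------------------------------------------------------------------

def estimate_multiplicities(
    graph: BreakpointGraph,
    background_cn: float = DEFAULT_BACKGROUND_CN,
    unit_cn: float | None = None,
) -> dict[int, int]:
    """Estimate how many times each segment appears per ecDNA circle.

    A segment is considered amplified when its CN exceeds twice the
    background.  The per-copy CN unit ``u`` defaults to the minimum amplified
    CN minus the background (the least-amplified segment is presumed to occur
    once per circle); ``unit_cn`` overrides it.  Multiplicity is
    ``max(0, round((cn - background) / u))``; zero-multiplicity segments are
    excluded from enumeration.
    """
    amplified = [s for s in graph.segments if s.cn > 2 * background_cn]
    if not amplified:
        raise GraphValidationError("no amplicon: no segment with cn above 2x background")
    if unit_cn is None:
        unit_cn = min(s.cn for s in amplified) - background_cn
    if unit_cn <= 0:
        raise GraphValidationError(f"non-positive multiplicity unit {unit_cn}")
    mult: dict[int, int] = {}
    for seg in graph.segments:
        m = round((seg.cn - background_cn) / unit_cn)
        mult[seg.id] = max(0, int(m))
    return mult


def locate_cut_sites(
    graph: BreakpointGraph, cuts: Iterable[CutSite]
) -> dict[CutSite, int | None]:
    """Map each cut site to its containing segment id, or None if off-amplicon.

    Containment uses the half-open convention: a cut exactly at a segment
    start belongs to that segment; a cut at a segment end does not.
    """
    trees: dict[str, IntervalTree] = {}
    for seg in graph.segments:
        trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, seg.id)
    out: dict[CutSite, int | None] = {}
    for cut in cuts:
        hits = trees.get(cut.chrom, IntervalTree())[cut.position]
        out[cut] = next(iter(hits)).data if hits else None
    return out


@dataclass
class GraphReport:
    """Structural diagnostics for a parsed graph."""

    degree: dict[tuple[int, str], int]
    total_amplified_length: int
    unbalanced_ends: list[tuple[int, str]]

    @property
    def n_unbalanced(self) -> int:
        return len(self.unbalanced_ends)


def validate_graph(graph: BreakpointGraph) -> GraphReport:
    """Tabulate per-end edge degrees and flag ends lacking any edge.

    Dangling segment ends correspond to missing junctions that prevent
    unambiguous amplicon resolution downstream.
    """
    degree = {(s.id, side): 0 for s in graph.segments for side in (HEAD, TAIL)}
    for edge in graph.edges:
        degree[edge.left] += 1
        if edge.right != edge.left:
            degree[edge.right] += 1
    unbalanced = sorted(end for end, d in degree.items() if d == 0)
    total = sum(s.length for s in graph.segments)
    return GraphReport(degree=degree, total_amplified_length=total, unbalanced_ends=unbalanced)


def add_implied_concordant_edges(graph: BreakpointGraph) -> BreakpointGraph:
    """Return a graph with concordant edges added between reference-adjacent segments.

    Two segments on the same chromosome with ``a.end == b.start`` are joined
    tail-of-a to head-of-b unless an equivalent edge already exists.
    """
    existing = {e.key for e in graph.edges}
    new_edges = list(graph.edges)
    by_chrom: dict[str, list[GenomeSegment]] = {}
    for s in graph.segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end == b.start:
                edge = BreakpointEdge(left=(a.id, TAIL), right=(b.id, HEAD), kind="concordant")
                if edge.key not in existing:
                    new_edges.append(edge)
                    existing.add(edge.key)
    return BreakpointGraph(segments=list(graph.segments), edges=new_edges, source=graph.source)
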
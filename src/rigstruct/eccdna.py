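"""Reconstruction of circular extrachromosomal DNA candidates.

Highly amplified copy-number segments become graph nodes with two ends;
SV joins whose breakends land on segment boundaries (within a matching
tolerance) become edges. Reported structures are the simple cycles that
traverse each segment through (enter one end, leave the other),
deduplicated under rotation and reversal and ranked by amplified mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .model import BreakpointJoin, CNSegment, InputError

__all__ = [
    "EccDNAParams",
    "AmpliconGraph",
    "EccDNACycle",
    "EccDNAReport",
    "select_amplified_segments",
    "build_amplicon_graph",
    "find_cycles",
    "reconstruct_structures",
    "verify_cycle",
]

LEFT, RIGHT = "left", "right"


@dataclass(frozen=True)
class EccDNAParams:
    amp_threshold: float = 2.0
    tolerance_bp: int = 10_000
    max_segments: int = 20


@dataclass(frozen=True)
class GraphEdge:
    node_a: int
    end_a: str
    node_b: int
    end_b: str
    join: BreakpointJoin


@dataclass
class AmpliconGraph:
    nodes: List[CNSegment]
    edges: List[GraphEdge]
    unmatched_joins: List[BreakpointJoin]
    warnings: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class EccDNACycle:
    """Ordered, oriented traversal of amplified segments closed into a circle."""

    segments: Tuple[Tuple[CNSegment, str], ...]  # (segment, "+" | "-")
    supporting_joins: Tuple[BreakpointJoin, ...]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_length(self) -> int:
        return sum(seg.length for seg, _ in self.segments)

    @property
    def amplified_mass(self) -> float:
        return sum(seg.length * 2**seg.seg_mean for seg, _ in self.segments)


@dataclass
class EccDNAReport:
    cycles: List[EccDNACycle]
    unmatched_joins: List[BreakpointJoin]
    n_subthreshold_segments: int
    warnings: List[str] = field(default_factory=list)


def select_amplified_segments(
    segments: Sequence[CNSegment], amp_threshold: float = 2.0
) -> List[CNSegment]:
    """Segments at or above the amplification threshold, in coordinate order."""
    return sorted(
        (s for s in segments if s.seg_mean >= amp_threshold),
        key=lambda s: (s.chrom, s.start, s.end),
    )


def _attach(
    breakend: Tuple[str, int, str],
    nodes: Sequence[CNSegment],
    tolerance_bp: int,
    warnings_out: List[str],
) -> Optional[Tuple[int, str]]:
    """Map one breakend to a (node index, end) pair.

    '+' strand breakends attach to right boundaries (segment ends), '-'
    to left boundaries (segment starts). Nearest candidate within
    tolerance wins; an exact distance tie goes to the lower-coordinate
    boundary with a warning.
    """
    chrom, pos, strand = breakend
    end = RIGHT if strand == "+" else LEFT
    candidates = []
    for i, seg in enumerate(nodes):
        if seg.chrom != chrom:
            continue
        boundary = seg.end if end == RIGHT else seg.start
        dist = abs(pos - boundary)
        if dist <= tolerance_bp:
            candidates.append((dist, boundary, i))
    if not candidates:
        return None
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        warnings_out.append(
            f"breakend {chrom}:{pos}({strand}) equidistant to two boundaries; "
            "attached to lower coordinate"
        )
    return candidates[0][2], end


def build_amplicon_graph(
    nodes: Sequence[CNSegment],
    joins: Sequence[BreakpointJoin],
    tolerance_bp: int = 10_000,
) -> AmpliconGraph:
    if tolerance_bp < 0:
        raise InputError("tolerance_bp must be >= 0")
    nodes = list(nodes)
    edges: List[GraphEdge] = []
    unmatched: List[BreakpointJoin] = []
    warns: List[str] = []
    for j in joins:
        a = _attach((j.chrom_a, j.pos_a, j.strand_a), nodes, tolerance_bp, warns)
        b = _attach((j.chrom_b, j.pos_b, j.strand_b), nodes, tolerance_bp, warns)
        if a is None or b is None:
            unmatched.append(j)
            continue
        edges.append(GraphEdge(node_a=a[0], end_a=a[1], node_b=b[0], end_b=b[1], join=j))
    return AmpliconGraph(nodes=nodes, edges=edges, unmatched_joins=unmatched, warnings=warns)


def _canonical(path: Tuple[Tuple[int, str], ...]) -> Tuple[Tuple[int, str], ...]:
    """Canonical form of a cycle under rotation and reversal."""
    variants = []
    n = len(path)
    rev = tuple((i, "-" if o == "+" else "+") for i, o in reversed(path))
    for seq in (path, rev):
        for r in range(n):
            variants.append(seq[r:] + seq[:r])
    return min(variants)


def find_cycles(graph: AmpliconGraph, max_segments: int = 20) -> List[EccDNACycle]:
    """Exhaustive enumeration of simple traverse-through cycles.

    Each segment is entered at one end and left at the other; cycles are
    deduplicated under rotation/reversal and sorted by amplified mass
    descending (ties broken deterministically).
    """
    if max_segments > 20:
        raise InputError("max_segments capped at 20 (exhaustive search bound)")
    if len(graph.nodes) > max_segments:
        raise InputError(
            f"{len(graph.nodes)} amplified segments exceed max_segments="
            f"{max_segments}; raise the amplification threshold"
        )
    # adjacency over (node, end) pairs
    adj: Dict[Tuple[int, str], List[Tuple[Tuple[int, str], int]]] = {}
    for ei, e in enumerate(graph.edges):
        adj.setdefault((e.node_a, e.end_a), []).append(((e.node_b, e.end_b), ei))
        adj.setdefault((e.node_b, e.end_b), []).append(((e.node_a, e.end_a), ei))

    seen: Set[Tuple[Tuple[int, str], ...]] = set()
    results: List[EccDNACycle] = []

    def other(end: str) -> str:
        return LEFT if end == RIGHT else RIGHT

    def dfs(
        start: int,
        node: int,
        entry_end: str,
        path: List[Tuple[int, str]],
        edge_path: List[int],
        visited: Set[int],
    ) -> None:
        exit_end = other(entry_end)
        for (nxt, nxt_end), ei in adj.get((node, exit_end), []):
            if nxt == start and nxt_end == LEFT and len(path) >= 1:
                cycle_path = tuple(path)
                key = _canonical(cycle_path)
                if key not in seen:
                    seen.add(key)
                    segs = tuple((graph.nodes[i], o) for i, o in cycle_path)
                    joins = tuple(graph.edges[j].join for j in edge_path + [ei])
                    results.append(EccDNACycle(segments=segs, supporting_joins=joins))
                continue
            if nxt in visited:
                continue
            orient = "+" if nxt_end == LEFT else "-"
            dfs(
                start,
                nxt,
                nxt_end,
                path + [(nxt, orient)],
                edge_path + [ei],
                visited | {nxt},
            )

    for start in range(len(graph.nodes)):
        dfs(start, start, LEFT, [(start, "+")], [], {start})

    results.sort(
        key=lambda c: (
            -c.amplified_mass,
            c.n_segments,
            tuple((s.chrom, s.start, o) for s, o in c.segments),
        )
    )
    return results


def reconstruct_structures(
    segments: Sequence[CNSegment],
    joins: Sequence[BreakpointJoin],
    params: EccDNAParams = EccDNAParams(),
) -> EccDNAReport:
    """select -> build -> find, with diagnostics. Deterministic in its
    inputs; join order does not affect the reported cycles."""
    nodes = select_amplified_segments(segments, params.amp_threshold)
    ordered_joins = sorted(
        joins, key=lambda j: (j.chrom_a, j.pos_a, j.chrom_b, j.pos_b, j.strand_a, j.strand_b)
    )
    graph = build_amplicon_graph(nodes, ordered_joins, params.tolerance_bp)
    cycles = find_cycles(graph, params.max_segments)
    return EccDNAReport(
        cycles=cycles,
        unmatched_joins=graph.unmatched_joins,
        n_subthreshold_segments=len(segments) - len(nodes),
        warnings=graph.warnings,
    )


def verify_cycle(
    cycle: EccDNACycle,
    joins: Sequence[BreakpointJoin],
    tolerance_bp: int = 10_000,
) -> bool:
    """Independent validity check: walk the cycle and confirm that every
    consecutive pair of oriented segments (including the wrap-around) is
    connected by a distinct join whose breakends sit within tolerance of
    the exit and entry boundaries, and that total_length adds up.

    This walker consults only the raw join list, not the amplicon graph.
    """
    if cycle.total_length != sum(seg.length for seg, _ in cycle.segments):
        return False
    n = len(cycle.segments)
    used: Set[int] = set()
    for k in range(n):
        seg_a, o_a = cycle.segments[k]
        seg_b, o_b = cycle.segments[(k + 1) % n]
        # exit boundary of a: right end if traversed "+", else left end
        exit_pos = seg_a.end if o_a == "+" else seg_a.start
        exit_strand = "+" if o_a == "+" else "-"
        entry_pos = seg_b.start if o_b == "+" else seg_b.end
        entry_strand = "-" if o_b == "+" else "+"

        found = None
        for ji, j in enumerate(joins):
            if ji in used:
                continue
            ends = [
                (j.chrom_a, j.pos_a, j.strand_a),
                (j.chrom_b, j.pos_b, j.strand_b),
            ]
            for first, second in (ends, ends[::-1]):
                if (
                    first[0] == seg_a.chrom
                    and abs(first[1] - exit_pos) <= tolerance_bp
                    and first[2] == exit_strand
                    and second[0] == seg_b.chrom
                    and abs(second[1] - entry_pos) <= tolerance_bp
                    and second[2] == entry_strand
                ):
                    found = ji
                    break
            if found is not None:
                break
        if found is None:
            return False
        used.add(found)
    return True
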
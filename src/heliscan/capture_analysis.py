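"""Segment decomposition of related elements and inference of stepwise
capture / internal-loss / nested-insertion histories.

Elements are decomposed into shared homologous blocks (all-vs-all local
alignment, transitive clustering), each element becoming an ordered string
of block identifiers with unique-sequence gaps.  Events are then inferred as
single-edit relations between block strings.  Direction between an isolated
pair is inherently ambiguous (a capture read one way is a loss read the
other), so both orientations are emitted and flagged; multi-element
parsimony or user ancestry breaks ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .homology_engine import local_search
from .sequence_io import GenomeSequence

EVENT_TYPES = ("capture", "loss", "nested_insertion")


@dataclass(frozen=True)
class SegmentBlock:
    """One homologous segment occurrence inside one element."""

    element_id: str
    start: int
    end: int
    block_id: str  # shared across elements; "u<n>" ids are unique gaps
    identity: float  # percent, of the block's cross-element alignment

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_unique(self) -> bool:
        return self.block_id.startswith("u")


@dataclass(frozen=True)
class CaptureEvent:
    """One inferred transformation turning parent into child."""

    type: str
    parent_element: str
    child_element: str
    child_interval: tuple[int, int]  # affected run, child coords (parent for loss)
    inserted_sequence: str | None = None  # capture / nested_insertion payload
    support: tuple[str, ...] = ()  # block ids evidencing the shared backbone
    ambiguous: bool = True  # single-pair direction cannot be oriented

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class DerivationGraph:
    """Directed multigraph of elements connected by inferred events."""

    graph: nx.MultiDiGraph

    def events(self, parent: str | None = None, child: str | None = None) -> list[CaptureEvent]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            if parent is not None and u != parent:
                continue
            if child is not None and v != child:
                continue
            out.append(data["event"])
        return out

    def ranked_paths(self, src: str, dst: str, cutoff: int = 6) -> list[list[str]]:
        """Simple paths from src to dst, fewest events first."""
        paths = nx.all_simple_paths(self.graph, src, dst, cutoff=cutoff)
        return sorted(paths, key=len)

    def minimal_event_count(self, src: str, dst: str) -> int | None:
        try:
            return nx.shortest_path_length(self.graph, src, dst)
        except nx.NetworkXNoPath:
            return None


# ---------------------------------------------------------------------------
# Block decomposition


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _as_dict(elements) -> dict[str, str]:
    if isinstance(elements, Mapping):
        return {k: str(v).upper() for k, v in elements.items()}
    return {f"elem{i}": str(s).upper() for i, s in enumerate(elements)}


def decompose_segments(
    elements: Mapping[str, str] | Sequence[str],
    min_identity: float = 85.0,
    min_block_bp: int = 50,
    merge_gap: int = 20,
    breakpoint_tol: int = 5,
) -> list[SegmentBlock]:
    """Decompose related elements into shared homologous blocks.

    All-vs-all local alignments at >= ``min_identity`` percent and
    >= ``min_block_bp`` aligned length are clustered transitively into
    block ids; breakpoints are projected across alignments so that shared
    content is cut consistently in every element.  Unaligned stretches
    become per-element unique gaps (ids ``u0``, ``u1``, ...); unique gaps
    shorter than ``merge_gap`` between two blocks are treated as indel noise
    and absorbed into the preceding block.
    """
    seqs = _as_dict(elements)
    if len(seqs) < 2:
        raise ValueError("need at least two elements to decompose")
    names = list(seqs)

    # 1. pairwise local alignments (forward strand; orientation-flips are out
    #    of scope for block strings)
    pair_alignments: list[tuple[str, int, int, str, int, int, float]] = []
    for a, b in itertools.combinations(names, 2):
        genome_b = GenomeSequence(seq_id=b, residues=seqs[b])
        for hit in local_search(
            seqs[a], genome_b, min_len_bp=min_block_bp, min_identity=min_identity,
            strand_mode="both",
        ):
            if hit.strand != "+":
                continue
            qa, qb = hit.query_interval
            s = hit.subject_interval
            pair_alignments.append((a, qa, qb, b, s.start, s.end, hit.identity))

    # 2. breakpoint projection to a fixpoint
    bps: dict[str, set[int]] = {n: {0, len(seqs[n])} for n in names}
    for a, qa, qb, b, sa, sb, _ in pair_alignments:
        bps[a].update((qa, qb))
        bps[b].update((sa, sb))

    def _near(pos: int, positions: set[int]) -> bool:
        return any(abs(pos - p) <= breakpoint_tol for p in positions)

    def _project(p: int, qa: int, qb: int, sa: int, sb: int) -> int:
        # linear interpolation through the alignment (near-gapless in use)
        frac = (p - qa) / (qb - qa)
        return round(sa + frac * (sb - sa))

    for _ in range(8):
        changed = False
        for a, qa, qb, b, sa, sb, _ in pair_alignments:
            for p in list(bps[a]):
                if qa < p < qb:
                    q = _project(p, qa, qb, sa, sb)
                    if sa < q < sb and not _near(q, bps[b]):
                        bps[b].add(q)
                        changed = True
            for p in list(bps[b]):
                if sa < p < sb:
                    q = _project(p, sa, sb, qa, qb)
                    if qa < q < qb and not _near(q, bps[a]):
                        bps[a].add(q)
                        changed = True
        if not changed:
            break

    # 3. atomic segments and transitive clustering
    segments: dict[str, list[tuple[int, int]]] = {}
    for n in names:
        cuts = sorted(bps[n])
        segments[n] = [
            (s, e) for s, e in zip(cuts, cuts[1:]) if e - s > breakpoint_tol
        ]

    def _covering(n: str, lo: int, hi: int) -> tuple[int, int] | None:
        mid = (lo + hi) / 2
        for seg in segments[n]:
            if seg[0] - breakpoint_tol <= lo and hi <= seg[1] + breakpoint_tol:
                return seg
            if seg[0] <= mid < seg[1]:
                return seg
        return None

    uf = _UnionFind()
    identity_of: dict[tuple, float] = {}
    for a, qa, qb, b, sa, sb, ident in pair_alignments:
        for seg in segments[a]:
            if seg[0] < qa - breakpoint_tol or seg[1] > qb + breakpoint_tol:
                continue
            lo = _project(max(seg[0], qa), qa, qb, sa, sb)
            hi = _project(min(seg[1], qb), qa, qb, sa, sb)
            target = _covering(b, lo, hi)
            if target is None:
                continue
            uf.union((a, seg), (b, target))
            for node in ((a, seg), (b, target)):
                identity_of[node] = min(identity_of.get(node, 100.0), ident)

    components: dict = {}
    for n in names:
        for seg in segments[n]:
            root = uf.find((n, seg))
            components.setdefault(root, []).append((n, seg))

    # 4. assign ids: shared components -> b<k>, singletons -> unique gaps
    blocks: list[SegmentBlock] = []
    shared_counter = itertools.count()
    unique_counter = itertools.count()
    root_id: dict = {}
    for root, members in sorted(
        components.items(), key=lambda kv: min((m[0], m[1][0]) for m in kv[1])
    ):
        elems = {m[0] for m in members}
        if len(elems) >= 2:
            root_id[root] = f"b{next(shared_counter)}"
    for n in names:
        for seg in segments[n]:
            root = uf.find((n, seg))
            bid = root_id.get(root)
            if bid is None:
                bid = f"u{next(unique_counter)}"
            blocks.append(
                SegmentBlock(
                    element_id=n,
                    start=seg[0],
                    end=seg[1],
                    block_id=bid,
                    identity=identity_of.get((n, seg), 100.0),
                )
            )

    # 5. absorb short unique gaps (indel noise) between shared blocks
    out: list[SegmentBlock] = []
    by_elem: dict[str, list[SegmentBlock]] = {}
    for blk in blocks:
        by_elem.setdefault(blk.element_id, []).append(blk)
    for n in names:
        row = sorted(by_elem.get(n, []), key=lambda b: b.start)
        for blk in row:
            if (
                blk.is_unique
                and blk.length < merge_gap
                and out
                and out[-1].element_id == n
                and not out[-1].is_unique
            ):
                prev = out.pop()
                out.append(
                    SegmentBlock(n, prev.start, blk.end, prev.block_id, prev.identity)
                )
            else:
                out.append(blk)
    return out


def block_strings(blocks: Sequence[SegmentBlock]) -> dict[str, list[SegmentBlock]]:
    """Ordered block decomposition per element."""
    out: dict[str, list[SegmentBlock]] = {}
    for blk in blocks:
        out.setdefault(blk.element_id, []).append(blk)
    for row in out.values():
        row.sort(key=lambda b: b.start)
    return out


# ---------------------------------------------------------------------------
# Event inference


def _single_insert_explanations(
    parent: list[str], child: list[str]
) -> list[tuple[int, int]]:
    """All (i, j) with child[:i] + child[j:] == parent and child[i:j] novel."""
    out = []
    np_, nc = len(parent), len(child)
    if nc <= np_:
        return out
    parent_set = set(parent)
    for i in range(nc):
        j = i + (nc - np_)
        if j <= i or j > nc:
            continue
        if child[:i] == parent[:i] and child[j:] == parent[i:]:
            # the run must bring novel content; junction slop may drag a
            # short shared block into it, so "any novel" rather than "all"
            if any(tok not in parent_set for tok in child[i:j]):
                out.append((i, j))
    return out


def _refine_single_edit(
    shorter: str, longer: str, pos_guess: int
) -> tuple[int, int] | None:
    """Exact interval such that ``longer == shorter[:pos] + run + shorter[pos:]``.

    Block boundaries carry a few bp of slop (chance-matching alignment
    overhangs), so when the raw residues are available the affected interval
    is re-anchored via longest common prefix/suffix.  Returns ``None`` when
    the pair is not an exact single-run edit (e.g. diverged copies).
    """
    run_len = len(longer) - len(shorter)
    if run_len <= 0:
        return None
    m = len(shorter)
    lcp = 0
    while lcp < m and shorter[lcp] == longer[lcp]:
        lcp += 1
    lcs = 0
    while lcs < m - lcp and shorter[m - 1 - lcs] == longer[len(longer) - 1 - lcs]:
        lcs += 1
    lo, hi = m - lcs, lcp
    if lo > hi:
        return None
    pos = min(max(pos_guess, lo), hi)
    return (pos, pos + run_len)


def infer_events(
    blocks: Sequence[SegmentBlock],
    elements: Mapping[str, str] | None = None,
) -> DerivationGraph:
    """Infer capture / loss / nested-insertion relations between elements.

    For every ordered element pair (P, C): a *capture* edge is emitted when
    C's block string equals P's with exactly one contiguous novel run
    inserted; a *loss* edge when C equals P with one contiguous internal run
    deleted; a *nested_insertion* edge when C's full block string appears as
    a contiguous run inside P.  All minimal single-edit explanations are
    kept; multi-step paths are ranked by event count via the returned graph.
    Passing ``elements`` (id -> sequence) attaches replayable payloads.
    """
    strings = block_strings(blocks)
    seqs = dict(elements) if elements else {}
    g = nx.MultiDiGraph()
    g.add_nodes_from(strings)

    def ids(row: list[SegmentBlock]) -> list[str]:
        return [b.block_id for b in row]

    for p_name, c_name in itertools.permutations(strings, 2):
        p_row, c_row = strings[p_name], strings[c_name]
        p_ids, c_ids = ids(p_row), ids(c_row)
        shared = tuple(sorted(set(p_ids) & set(c_ids)))

        # capture: child = parent with one novel contiguous run inserted.
        # Only internal runs qualify, so that every capture(P->C) has a valid
        # mirror loss(C->P); edge captures cannot be oriented at all.
        for i, j in _single_insert_explanations(p_ids, c_ids):
            if i == 0 or j == len(c_ids):
                continue
            start, end = c_row[i].start, c_row[j - 1].end
            if p_name in seqs and c_name in seqs:
                refined = _refine_single_edit(seqs[p_name], seqs[c_name], start)
                if refined is not None:
                    start, end = refined
            payload = seqs[c_name][start:end] if c_name in seqs else None
            g.add_edge(
                p_name,
                c_name,
                event=CaptureEvent(
                    "capture", p_name, c_name, (start, end),
                    inserted_sequence=payload, support=shared,
                ),
            )

        # loss: child = parent with one contiguous internal run deleted
        for i, j in _single_insert_explanations(c_ids, p_ids):
            if i == 0 or j == len(p_ids):
                continue  # losses are internal
            start, end = p_row[i].start, p_row[j - 1].end
            if p_name in seqs and c_name in seqs:
                refined = _refine_single_edit(seqs[c_name], seqs[p_name], start)
                if refined is not None:
                    start, end = refined
            g.add_edge(
                p_name,
                c_name,
                event=CaptureEvent(
                    "loss", p_name, c_name, (start, end), support=shared
                ),
            )

        # nested insertion: child appears whole and contiguous inside parent
        nc = len(c_ids)
        if 0 < nc < len(p_ids):
            for i in range(len(p_ids) - nc + 1):
                if p_ids[i : i + nc] == c_ids and not all(
                    b.is_unique for b in c_row
                ):
                    start, end = p_row[i].start, p_row[i + nc - 1].end
                    payload = seqs[c_name] if c_name in seqs else None
                    g.add_edge(
                        c_name,
                        p_name,
                        event=CaptureEvent(
                            "nested_insertion", c_name, p_name, (start, end),
                            inserted_sequence=payload, support=shared,
                        ),
                    )
                    break
    return DerivationGraph(g)


# ---------------------------------------------------------------------------
# Replay


class ReplayError(ValueError):
    pass


def replay_events(parent: str, events: Sequence[CaptureEvent]) -> str:
    """Apply events in order to a parent sequence, returning the child.

    Capture and nested-insertion events insert their payload at the start of
    the affected interval; loss events delete the interval.  An inapplicable
    event raises :class:`ReplayError` naming the step.
    """
    seq = parent
    for step, ev in enumerate(events):
        start, end = ev.child_interval
        if ev.type in ("capture", "nested_insertion"):
            if ev.inserted_sequence is None:
                raise ReplayError(f"step {step}: {ev.type} event has no payload")
            if not 0 <= start <= len(seq):
                raise ReplayError(
                    f"step {step}: insertion point {start} outside sequence"
                )
            seq = seq[:start] + ev.inserted_sequence + seq[start:]
        elif ev.type == "loss":
            if not 0 <= start < end <= len(seq):
                raise ReplayError(
                    f"step {step}: loss interval [{start}, {end}) outside sequence"
                )
            seq = seq[:start] + seq[end:]
        else:  # pragma: no cover - guarded by CaptureEvent
            raise ReplayError(f"step {step}: unknown event type {ev.type!r}")
    return seq
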
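"""Pair terminus hits into intact element calls and annotate structural hallmarks.

Pairing rule: a 5'-hit and a 3'-hit of the same family and strand whose span
(5'-hit start to 3'-hit end, strand-oriented) is strictly below the span
limit (default 20 kb) form a single element; the call extends to the
*farthest* in-range 3'-hit, with nearer 3'-hits kept as multiple-termini
candidates.  AT-flank, hairpin and putative-autonomous results are
annotations, not filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

from .motif_engine import TerminusHit, hit_sort_key
from .sequence_io import GenomeSequence, GenomicInterval, reverse_complement

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_MAX_SPAN = 20_000
AUTONOMOUS_MIN_LENGTH = 10_000


@dataclass(frozen=True)
class HairpinHit:
    """A reverse-complement palindrome near the element 3'-end."""

    interval: GenomicInterval
    stem_length: int
    loop_length: int
    mismatches: int
    distance_to_3prime: int

    @property
    def score(self) -> int:
        return self.stem_length - self.mismatches


@dataclass(frozen=True)
class HelitronCall:
    """A paired intact element: one 5'-hit plus one or more 3'-hits."""

    interval: GenomicInterval
    family: str
    five_hit: TerminusHit
    three_hits: tuple[TerminusHit, ...]  # ordered 5'->3'; last is the element end
    flank_upstream_base: str | None = None
    flank_downstream_base: str | None = None
    at_insertion: bool = False
    hairpin: HairpinHit | None = None
    putative_autonomous: bool = False
    multi_termini_5: int = 1
    multi_termini_3: int = 1

    def __post_init__(self):
        if any(t.family != self.family for t in self.three_hits):
            raise ValueError("call mixes families")
        if self.five_hit.family != self.family:
            raise ValueError("call mixes families")
        if self.interval.length >= DEFAULT_MAX_SPAN * 10:
            raise ValueError("implausible call span")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def gff_type(self) -> str:
        return "helitron"

    @property
    def name(self) -> str:
        iv = self.interval
        return f"{self.family}_{iv.seq_id}_{iv.start}_{iv.end}{iv.strand}"

    @property
    def pass_level(self) -> str:
        return self.five_hit.pass_level

    def to_row(self) -> dict:
        iv = self.interval
        return {
            "seq_id": iv.seq_id,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "name": self.name,
            "family": self.family,
            "length": self.length,
            "pass_level": self.pass_level,
            "at_insertion": self.at_insertion,
            "has_hairpin": self.hairpin is not None,
            "putative_autonomous": self.putative_autonomous,
            "multi_termini_5": self.multi_termini_5,
            "multi_termini_3": self.multi_termini_3,
        }


def _check_sorted(hits: Sequence[TerminusHit]) -> None:
    keys = [(h.interval.seq_id, h.interval.start) for h in hits]
    if keys != sorted(keys):
        raise ValueError("terminus hits must be sorted by (seq_id, start)")


def _mirror_hit(hit: TerminusHit, offset: int = 1 << 40) -> TerminusHit:
    """Map a minus-strand hit into a mirrored coordinate frame where the
    element 5'->3' direction runs left to right."""
    iv = hit.interval
    return replace(
        hit,
        interval=GenomicInterval(iv.seq_id, offset - iv.end, offset - iv.start, "+"),
    )


def _pair_forward(
    fives: list[TerminusHit],
    threes: list[TerminusHit],
    max_span_bp: int,
) -> list[tuple[TerminusHit, list[TerminusHit]]]:
    """Pair in a frame where coordinates increase 5'->3'."""
    pairs = []
    threes = sorted(threes, key=lambda h: (h.interval.end, h.interval.start))
    for f in fives:
        in_range: dict[int, TerminusHit] = {}
        for t in threes:
            if t.interval.start < f.interval.end:
                continue  # 3'-hit must lie downstream of the 5'-hit
            if t.interval.end - f.interval.start >= max_span_bp:
                continue
            # one terminus per distinct end; keep the longest match there
            prev = in_range.get(t.interval.end)
            if prev is None or t.interval.length > prev.interval.length:
                in_range[t.interval.end] = t
        if in_range:
            pairs.append((f, [in_range[e] for e in sorted(in_range)]))
        else:
            log.info(
                "orphan 5'-hit at %s:%d (no in-range 3'-hit)",
                f.interval.seq_id,
                f.interval.start,
            )
    return pairs


def pair_termini(
    hits: Sequence[TerminusHit],
    max_span_bp: int = DEFAULT_MAX_SPAN,
) -> list[HelitronCall]:
    """Pair sorted terminus hits into element calls.

    Every 5'-hit yields at most one call, extending to the farthest
    same-family, same-strand 3'-hit whose end is strictly less than
    ``max_span_bp`` downstream of the 5'-hit start.  Nearer in-range 3'-hits
    are recorded in ``three_hits``; intervening 5'-hits are counted in
    ``multi_termini_5``.  Orphan 5'-hits produce no call and are logged.
    """
    if max_span_bp <= 0:
        raise ValueError("max_span_bp must be positive")
    _check_sorted(hits)
    groups: dict[tuple, dict[str, list[TerminusHit]]] = {}
    for h in hits:
        if h.pass_level == "pseudo":
            continue  # pseudo termini never found elements
        key = (h.interval.seq_id, h.interval.strand, h.family)
        bucket = groups.setdefault(key, {"five": [], "three": []})
        bucket["five" if h.end_type == "five_prime" else "three"].append(h)

    calls: list[HelitronCall] = []
    for (seq_id, strand, family), bucket in groups.items():
        fives, threes = bucket["five"], bucket["three"]
        if strand == "-":
            mirror = {_mirror_hit(h): h for h in fives + threes}
            pairs = _pair_forward(
                sorted((m for m, h in mirror.items() if h.end_type == "five_prime"),
                       key=lambda h: h.interval.start),
                [m for m, h in mirror.items() if h.end_type == "three_prime"],
                max_span_bp,
            )
            # mirrored order is already 5'->3' (descending genome coordinate)
            pairs = [(mirror[f], [mirror[t] for t in ts]) for f, ts in pairs]
        else:
            pairs = _pair_forward(
                sorted(fives, key=lambda h: h.interval.start), threes, max_span_bp
            )

        five_starts = sorted(
            {h.interval.end if strand == "-" else h.interval.start for h in fives}
        )
        for f, ts in pairs:
            last = ts[-1]
            if strand == "+":
                iv = GenomicInterval(seq_id, f.interval.start, last.interval.end, "+")
                n5 = sum(1 for s in five_starts if iv.start <= s < iv.end)
            else:
                iv = GenomicInterval(seq_id, last.interval.start, f.interval.end, "-")
                n5 = sum(1 for s in five_starts if iv.start < s <= iv.end)
            calls.append(
                HelitronCall(
                    interval=iv,
                    family=family,
                    five_hit=f,
                    three_hits=tuple(ts),
                    multi_termini_5=n5,
                    multi_termini_3=len(ts),
                )
            )
    calls.sort(key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.end))
    return calls


def annotate_flanks(call: HelitronCall, genome: GenomeSequence) -> HelitronCall:
    """Record the strand-oriented host bases flanking the element.

    Sets ``at_insertion`` true iff the upstream base is A and the downstream
    base is T (the preferred insertion context).  Missing flanks at contig
    edges stay ``None`` and never satisfy the AT test.
    """
    iv = call.interval
    if iv.end > genome.length:
        raise ValueError("call interval outside genome")
    left = genome.residues[iv.start - 1] if iv.start > 0 else None
    right = genome.residues[iv.end] if iv.end < genome.length else None
    if iv.strand == "+":
        up, down = left, right
    else:
        up = _COMP.get(right) if right else None
        down = _COMP.get(left) if left else None
    return replace(
        call,
        flank_upstream_base=up,
        flank_downstream_base=down,
        at_insertion=(up == "A" and down == "T"),
    )


def detect_hairpin(
    call: HelitronCall,
    genome: GenomeSequence,
    stem_min: int = 8,
    stem_max: int = 10,
    loop_max: int = 4,
    window_bp: int = 50,
    max_mismatch: int = 1,
) -> HairpinHit | None:
    """Best reverse-complement palindrome in the window upstream of the 3'-end.

    Score is stem length minus mismatches; ties prefer the hairpin nearer the
    element 3'-end.  Returns ``None`` when no stem of at least ``stem_min``
    base pairs is found.
    """
    iv = call.interval
    if iv.strand == "+":
        w_start = max(iv.start, iv.end - window_bp)
        window = genome.residues[w_start:iv.end]
    else:
        w_end = min(iv.end, iv.start + window_bp)
        window = reverse_complement(genome.residues[iv.start:w_end])
    best: HairpinHit | None = None
    wlen = len(window)
    for stem in range(stem_max, stem_min - 1, -1):
        for loop in range(0, loop_max + 1):
            total = 2 * stem + loop
            for p in range(0, wlen - total + 1):
                left = window[p : p + stem]
                right = window[p + stem + loop : p + total]
                if "N" in left or "N" in right:
                    continue
                mism = sum(
                    1
                    for i in range(stem)
                    if _COMP.get(right[stem - 1 - i]) != left[i]
                )
                if mism > max_mismatch:
                    continue
                dist = wlen - (p + total)
                if iv.strand == "+":
                    g_start = iv.end - wlen + p
                    hp_iv = GenomicInterval(iv.seq_id, g_start, g_start + total, "+")
                else:
                    g_end = iv.start + wlen - p
                    hp_iv = GenomicInterval(iv.seq_id, g_end - total, g_end, "-")
                cand = HairpinHit(hp_iv, stem, loop, mism, dist)
                if (
                    best is None
                    or cand.score > best.score
                    or (cand.score == best.score and cand.distance_to_3prime < best.distance_to_3prime)
                ):
                    best = cand
    return best


def flag_putative_autonomous(
    call: HelitronCall,
    transposon_mask: Sequence[GenomicInterval] = (),
    min_length: int = AUTONOMOUS_MIN_LENGTH,
) -> bool:
    """True iff the call is long (> ``min_length``) and overlaps no masked
    long transposon."""
    if call.length <= min_length:
        return False
    return not any(call.interval.overlaps(m) for m in transposon_mask)


def annotate_calls(
    calls: Sequence[HelitronCall],
    genomes: dict[str, GenomeSequence],
    transposon_mask: Sequence[GenomicInterval] = (),
) -> list[HelitronCall]:
    """Apply flank, hairpin and autonomy annotation to every call."""
    out = []
    for call in calls:
        genome = genomes[call.interval.seq_id]
        call = annotate_flanks(call, genome)
        call = replace(
            call,
            hairpin=detect_hairpin(call, genome),
            putative_autonomous=flag_putative_autonomous(call, transposon_mask),
        )
        out.append(call)
    return out
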
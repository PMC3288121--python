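"""Pseudo-terminus detection, multiple-termini profiling, and nested-element
transposition product prediction.

A real 3'-terminus carries an intact ``CTAG`` motif (the match text ends
``CTAGT``); a pseudo 3'-terminus carries the decayed ``CTAT`` consensus.
Pseudo 5'-termini are not sequence-distinguishable from real ones, so 5'-hits
are classified pseudo by position (inside an element body) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .helitron_caller import HelitronCall
from .motif_engine import (
    TerminusHit,
    builtin_patterns,
    get_pattern,
    scan_termini,
)
from .sequence_io import GenomeSequence, GenomicInterval


def has_intact_ctag(matched_text: str) -> bool:
    """True iff the terminus text ends in CTAG followed by one base."""
    return len(matched_text) >= 5 and matched_text[-5:-1] == "CTAG"


@dataclass(frozen=True)
class PseudoTerminusHit:
    """A 3'-terminus-like locus classified by CTAG integrity."""

    interval: GenomicInterval
    family: str
    end_type: str
    ctag_intact: bool
    matched_text: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def gff_type(self) -> str:
        return "terminus_3" if self.ctag_intact else "pseudo_terminus"

    @property
    def name(self) -> str:
        iv = self.interval
        kind = "real3" if self.ctag_intact else "pseudo3"
        return f"{self.family}_{kind}_{iv.seq_id}_{iv.start}_{iv.end}{iv.strand}"


def scan_pseudo_3prime(
    genome: GenomeSequence | str,
    strand_mode: str = "both",
    exclusion: str = "overlap_real",
) -> list[PseudoTerminusHit]:
    """Scan for the decayed (CTAT) 3'-terminus consensus.

    Matches of the pseudo consensus are reported with ``ctag_intact=False``.
    Loci whose context instead completes a real CTAGT ending are excluded
    from the pseudo set and reported as real (``ctag_intact=True``).

    The published exclusion clause ("avoiding the 3'-termini of elements that
    ended in a guanine base") is ambiguous; two readings are implemented:

    - ``"overlap_real"`` (default): a pseudo match overlapping a strict real
      3'-terminus match on the same strand is reclassified as real.
    - ``"same_start"``: reclassify only when a strict real match starts at
      the same position as the pseudo match.
    """
    if exclusion not in ("overlap_real", "same_start"):
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    if isinstance(genome, str):
        genome = GenomeSequence(seq_id="seq", residues=genome.upper())
    pseudo_pat = get_pattern("helA", "three_prime", "pseudo")
    real_pat = get_pattern("helA", "three_prime", "strict")
    pseudo_hits = scan_termini(genome, [pseudo_pat], strand_mode)
    real_hits = scan_termini(genome, [real_pat], strand_mode)

    out: list[PseudoTerminusHit] = []
    for h in pseudo_hits:
        if exclusion == "same_start":
            is_real = any(
                r.interval.strand == h.interval.strand
                and (
                    r.interval.start == h.interval.start
                    if h.strand == "+"
                    else r.interval.end == h.interval.end
                )
                for r in real_hits
            )
        else:
            is_real = any(
                r.interval.strand == h.interval.strand
                and r.interval.overlaps(h.interval)
                for r in real_hits
            )
        out.append(
            PseudoTerminusHit(
                interval=h.interval,
                family=h.family,
                end_type=h.end_type,
                ctag_intact=is_real,
                matched_text=h.matched_text,
            )
        )
    for r in real_hits:
        # real termini are reported alongside so callers see the full picture
        out.append(
            PseudoTerminusHit(
                interval=r.interval,
                family=r.family,
                end_type=r.end_type,
                ctag_intact=True,
                matched_text=r.matched_text,
            )
        )
    out.sort(key=lambda h: (h.interval.seq_id, h.interval.start, -h.interval.end))
    return out


def pseudo_set(hits: Sequence[PseudoTerminusHit]) -> list[PseudoTerminusHit]:
    return [h for h in hits if not h.ctag_intact]


# ---------------------------------------------------------------------------
# Multiple-termini profiling


@dataclass(frozen=True)
class MultiTerminiRecord:
    call: HelitronCall
    n_termini_5: int
    n_termini_3: int
    internal_3_ctag_intact: tuple[bool, ...]

    @property
    def is_multi_5(self) -> bool:
        return self.n_termini_5 > 1

    @property
    def is_multi_3(self) -> bool:
        return self.n_termini_3 > 1


@dataclass(frozen=True)
class MultiTerminiReport:
    records: tuple[MultiTerminiRecord, ...]
    fraction_multi_5: float
    fraction_multi_3: float


def _strictly_inside(hit_iv: GenomicInterval, call_iv: GenomicInterval) -> bool:
    return (
        hit_iv.seq_id == call_iv.seq_id
        and hit_iv.start > call_iv.start
        and hit_iv.end < call_iv.end
    )


def profile_multi_termini(
    calls: Sequence[HelitronCall],
    hits: Sequence[TerminusHit],
) -> MultiTerminiReport:
    """Count internal termini per call and summarize multi-termini fractions.

    ``hits`` should be the full hit set from the same scan (any pass level,
    including pseudo-consensus hits).  Internal hits are those strictly
    inside the element body; distinct 5'-termini are counted by start and
    distinct 3'-termini by end, each including the element's own terminus.
    """
    records = []
    for call in calls:
        iv = call.interval
        internal_5: set[int] = set()
        internal_3: dict[int, TerminusHit] = {}
        for h in hits:
            if h.interval.strand != iv.strand or h.family != call.family:
                continue
            if not _strictly_inside(h.interval, iv):
                continue
            if h.end_type == "five_prime":
                internal_5.add(
                    h.interval.start if iv.strand == "+" else h.interval.end
                )
            else:
                key = h.interval.end if iv.strand == "+" else h.interval.start
                prev = internal_3.get(key)
                if prev is None or h.interval.length > prev.interval.length:
                    internal_3[key] = h
        records.append(
            MultiTerminiRecord(
                call=call,
                n_termini_5=1 + len(internal_5),
                n_termini_3=1 + len(internal_3),
                internal_3_ctag_intact=tuple(
                    has_intact_ctag(internal_3[k].matched_text)
                    for k in sorted(internal_3)
                ),
            )
        )
    n = len(records)
    return MultiTerminiReport(
        records=tuple(records),
        fraction_multi_5=(sum(r.is_multi_5 for r in records) / n) if n else 0.0,
        fraction_multi_3=(sum(r.is_multi_3 for r in records) / n) if n else 0.0,
    )


# ---------------------------------------------------------------------------
# Nested-transposition product prediction


@dataclass(frozen=True)
class NestedElement:
    """One element of a nested configuration, reduced to its terminus anchors.

    ``five_pos`` is the start of the 5'-terminus, ``three_pos`` the end of
    the 3'-terminus, in a shared coordinate frame increasing 5'->3'.
    """

    name: str
    five_pos: int
    three_pos: int
    family: str = "helA"

    def __post_init__(self):
        if self.five_pos >= self.three_pos:
            raise ValueError(f"{self.name}: 5' anchor must precede 3' anchor")


@dataclass(frozen=True)
class NestedConfiguration:
    """Outer-to-inner list of same-family elements, each strictly inside the
    body of the previous one."""

    elements: tuple[NestedElement, ...]

    def __post_init__(self):
        if not self.elements:
            raise ValueError("configuration needs at least one element")
        families = {e.family for e in self.elements}
        if len(families) > 1:
            raise ValueError("nested configuration mixes families")
        for parent, child in zip(self.elements, self.elements[1:]):
            if not (parent.five_pos < child.five_pos and child.three_pos < parent.three_pos):
                raise ValueError(
                    f"{child.name} is not strictly nested inside {parent.name}"
                )

    @property
    def outer(self) -> NestedElement:
        return self.elements[0]

    def totals(self) -> tuple[int, int]:
        n = len(self.elements)
        return n, n

    @classmethod
    def from_calls(cls, calls: Sequence[HelitronCall]) -> "NestedConfiguration":
        """Build a configuration from outer-to-inner element calls."""
        elems = tuple(
            NestedElement(
                name=c.name,
                five_pos=c.interval.start,
                three_pos=c.interval.end,
                family=c.family,
            )
            for c in calls
        )
        return cls(elems)


@dataclass(frozen=True)
class TranspositionProduct:
    """Termini bookkeeping for a partial read-out of a nested configuration."""

    product_interval: tuple[int, int]
    n_termini_5: int
    n_termini_3: int
    remnant_n_termini_5: int
    remnant_n_termini_3: int


def predict_nested_products(
    config: NestedConfiguration, launch_terminus: str
) -> TranspositionProduct:
    """Predict the product of transposition launched from one 5'-terminus.

    The product spans from the launch element's 5'-terminus through the
    outermost element's final 3'-terminus; it carries every 5'- and
    3'-terminus inside that span.  The remnant retains the complement, so
    product plus remnant termini counts always equal the configuration's
    totals.
    """
    by_name = {e.name: e for e in config.elements}
    if launch_terminus not in by_name:
        raise KeyError(
            f"launch terminus {launch_terminus!r} not in configuration "
            f"({sorted(by_name)})"
        )
    launch = by_name[launch_terminus]
    span = (launch.five_pos, config.outer.three_pos)
    n5 = sum(1 for e in config.elements if span[0] <= e.five_pos <= span[1])
    n3 = sum(1 for e in config.elements if span[0] <= e.three_pos <= span[1])
    total5, total3 = config.totals()
    return TranspositionProduct(
        product_interval=span,
        n_termini_5=n5,
        n_termini_3=n3,
        remnant_n_termini_5=total5 - n5,
        remnant_n_termini_3=total3 - n3,
    )
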
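"""BLASTN-like local similarity search: seed discovery, boundary validation,
and tiered copy-number counting.

The search is exact-seed-and-extend: 11-mer matches are clustered by
diagonal, and each cluster window is resolved with a local dynamic-
programming alignment (match +1, mismatch -2, gap -3 by default).  Identity
is computed over aligned columns (gaps included), coverage over query
length.  Both strands are searched; overlapping hits at a subject locus are
merged keeping the best score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from Bio import Align

from .sequence_io import GenomeSequence, GenomicInterval, reverse_complement

DEFAULT_SEED_SIZE = 11
DEFAULT_BAND = 15


@dataclass(frozen=True)
class LocalAlignment:
    """One local-similarity hit between a query and a subject genome."""

    query_interval: tuple[int, int]  # on the original query orientation
    subject_interval: GenomicInterval
    identity: float  # percent over aligned columns
    coverage: float  # percent of query length aligned
    score: float
    strand: str
    aligned_length: int
    n_identical: int

    def __post_init__(self):
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity/coverage out of [0, 100]")


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _cluster_seeds(
    matches: list[tuple[int, int]], band: int, max_gap: int
) -> list[list[tuple[int, int]]]:
    """Group (diagonal, subject_pos) seed matches into extension clusters."""
    matches.sort()
    clusters: list[list[tuple[int, int]]] = []
    for diag, spos in matches:
        placed = False
        for cluster in reversed(clusters):
            d0, s0 = cluster[-1]
            if abs(diag - d0) <= band and 0 <= spos - s0 <= max_gap:
                cluster.append((diag, spos))
                placed = True
                break
            if diag - d0 > band:
                break
        if not placed:
            clusters.append([(diag, spos)])
    return clusters


def _overlap_frac(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / min(a.length, b.length)


def local_search(
    query: str,
    genome: GenomeSequence | str,
    min_len_bp: int = 25,
    min_identity: float = 70.0,
    seed_size: int = DEFAULT_SEED_SIZE,
    band: int = DEFAULT_BAND,
    match_score: float = 1.0,
    mismatch_score: float = -2.0,
    gap_score: float = -3.0,
    strand_mode: str = "both",
) -> list[LocalAlignment]:
    """Find local alignments of ``query`` in ``genome``.

    Returns hits with aligned length >= ``min_len_bp`` and identity >=
    ``min_identity`` percent, sorted by descending score.
    """
    query = query.upper()
    if len(query) < seed_size:
        raise ValueError(
            f"query length {len(query)} is below the seed size {seed_size}"
        )
    if isinstance(genome, str):
        genome = GenomeSequence(seq_id="seq", residues=genome.upper())
    subject = genome.residues
    index = _seed_index(subject, seed_size)
    aligner = _make_aligner(match_score, mismatch_score, gap_score)
    qlen = len(query)
    max_gap = max(200, qlen)

    hits: list[LocalAlignment] = []
    strands = ("+", "-") if strand_mode == "both" else ("+",)
    for strand in strands:
        qseq = query if strand == "+" else reverse_complement(query)
        matches: list[tuple[int, int]] = []
        for qpos in range(0, qlen - seed_size + 1):
            kmer = qseq[qpos : qpos + seed_size]
            for spos in index.get(kmer, ()):
                matches.append((spos - qpos, spos))
        if not matches:
            continue
        for cluster in _cluster_seeds(matches, band, max_gap):
            sposs = [s for _, s in cluster]
            qposs = [s - d for d, s in cluster]
            # windows hug the seed cluster on both axes: wide enough for
            # extension past the outermost seeds, narrow enough that a
            # neighbouring repeat copy does not shadow this one in the DP
            pad = band + seed_size + min(qlen, 150)
            w_start = max(0, min(sposs) - pad)
            w_end = min(len(subject), max(sposs) + seed_size + pad)
            q_start = max(0, min(qposs) - pad)
            q_end = min(qlen, max(qposs) + seed_size + pad)
            window = subject[w_start:w_end]
            qslice = qseq[q_start:q_end]
            try:
                alignments = aligner.align(window, qslice)
            except (ValueError, OverflowError):  # degenerate window
                continue
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if aln.score <= 0:
                continue
            counts = aln.counts()
            aligned_len = counts.gaps + counts.identities + counts.mismatches
            if aligned_len == 0:
                continue
            identity = 100.0 * counts.identities / aligned_len
            t0, t1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
            q0, q1 = q_start + int(aln.coordinates[1][0]), q_start + int(aln.coordinates[1][-1])
            coverage = 100.0 * (q1 - q0) / qlen
            if strand == "+":
                q_iv = (q0, q1)
            else:
                q_iv = (qlen - q1, qlen - q0)
            s_iv = GenomicInterval(genome.seq_id, w_start + t0, w_start + t1, strand)
            hits.append(
                LocalAlignment(
                    query_interval=q_iv,
                    subject_interval=s_iv,
                    identity=identity,
                    coverage=min(coverage, 100.0),
                    score=float(aln.score),
                    strand=strand,
                    aligned_length=aligned_len,
                    n_identical=counts.identities,
                )
            )

    # merge overlapping hits per subject locus, best score wins
    hits.sort(key=lambda h: -h.score)
    merged: list[LocalAlignment] = []
    for h in hits:
        if any(
            _overlap_frac(h.subject_interval, m.subject_interval) > 0.5
            for m in merged
        ):
            continue
        merged.append(h)
    return [
        h
        for h in merged
        if h.aligned_length >= min_len_bp and h.identity >= min_identity
    ]


# ---------------------------------------------------------------------------
# Seed-based discovery


def seed_discovery(
    seed_elements: Sequence[str],
    genome: GenomeSequence | str,
    probe_bp: int = 50,
    five_min_len: int = 25,
    five_min_identity: float = 70.0,
    three_min_len: int = 25,
    three_min_identity: float = 80.0,
    max_span_bp: int = 20_000,
) -> list[GenomicInterval]:
    """Discover candidate element loci from known seed elements.

    Each seed contributes its first and last ``probe_bp`` residues as 5'-
    and 3'-terminus probes.  A candidate is a locus where a 5'-probe hit
    (> ``five_min_len`` aligned, identity > ``five_min_identity``) is
    followed within ``max_span_bp`` by a 3'-probe hit (> ``three_min_len``,
    identity > ``three_min_identity``) on the same strand; the farthest
    in-range 3'-hit sets the candidate end.
    """
    if isinstance(genome, str):
        genome = GenomeSequence(seq_id="seq", residues=genome.upper())
    candidates: set[GenomicInterval] = set()
    for seed in seed_elements:
        seed = seed.upper()
        p5, p3 = seed[:probe_bp], seed[-probe_bp:]
        h5s = [
            h
            for h in local_search(p5, genome, min_len_bp=0, min_identity=0)
            if h.aligned_length > five_min_len and h.identity > five_min_identity
        ]
        h3s = [
            h
            for h in local_search(p3, genome, min_len_bp=0, min_identity=0)
            if h.aligned_length > three_min_len and h.identity > three_min_identity
        ]
        for h5 in h5s:
            best: GenomicInterval | None = None
            for h3 in h3s:
                if h3.strand != h5.strand:
                    continue
                a, b = h5.subject_interval, h3.subject_interval
                if h5.strand == "+":
                    if b.start < a.end or b.end - a.start >= max_span_bp:
                        continue
                    iv = GenomicInterval(a.seq_id, a.start, b.end, "+")
                else:
                    if a.start < b.end or a.end - b.start >= max_span_bp:
                        continue
                    iv = GenomicInterval(a.seq_id, b.start, a.end, "-")
                if best is None or iv.length > best.length:
                    best = iv
            if best is not None:
                candidates.add(best)
    return sorted(candidates, key=lambda iv: (iv.seq_id, iv.start, iv.end))


# ---------------------------------------------------------------------------
# Boundary validation across copies


@dataclass(frozen=True)
class BoundaryResult:
    intervals: tuple[GenomicInterval, ...]
    left_extension: int
    right_extension: int
    resolved: bool
    note: str = ""


def _column_agreement(chars: Sequence[str]) -> float:
    counts: dict[str, int] = {}
    for ch in chars:
        counts[ch] = counts.get(ch, 0) + 1
    return max(counts.values()) / len(chars)


def validate_boundaries(
    copies: Sequence[LocalAlignment | GenomicInterval],
    genome: GenomeSequence,
    threshold: float = 0.60,
    window: int = 10,
    max_extend: int = 2_000,
) -> BoundaryResult:
    """Refine element boundaries by multi-copy flank comparison.

    Each locus is extended outward while the copies still agree; the
    boundary is placed where windowed column identity across copies drops
    below ``threshold``.  With a single copy the boundaries are returned
    unrefined and flagged; if no divergence appears within ``max_extend``
    (e.g. tandem duplications sharing flanks) the result is flagged
    unresolvable.
    """
    ivs = [
        c.subject_interval if isinstance(c, LocalAlignment) else c for c in copies
    ]
    if len(ivs) < 2:
        return BoundaryResult(tuple(ivs), 0, 0, resolved=False, note="single copy")
    seq = genome.residues

    def oriented(iv: GenomicInterval, offset: int) -> str | None:
        # offset < 0: upstream of the 5' edge; offset >= length: downstream
        if iv.strand == "+":
            pos = iv.start + offset
        else:
            pos = iv.end - 1 - offset
        if pos < 0 or pos >= len(seq):
            return None
        ch = seq[pos]
        return ch if iv.strand == "+" else {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}[ch]

    # change-point detection: columns inside the element score above the
    # cutoff, unrelated flank columns below it; the boundary is the offset
    # maximizing the cumulative score
    cutoff = (threshold + 1.0) / 2.0

    def extend(side: str) -> tuple[int, bool]:
        agreements: list[float] = []
        score = best_score = 0.0
        best_d = 0
        for d in range(1, max_extend + 1):
            cols = []
            for iv in ivs:
                off = -d if side == "left" else iv.length - 1 + d
                ch = oriented(iv, off)
                if ch is None:  # contig edge: settle on the best point so far
                    return best_d, True
                cols.append(ch)
            agreements.append(_column_agreement(cols))
            score += agreements[-1] - cutoff
            if score > best_score:
                best_score, best_d = score, d
            if (
                len(agreements) >= window
                and d - best_d >= window
                and sum(agreements[-window:]) / window < threshold
            ):
                return best_d, True
        return best_d, False

    left_ext, left_ok = extend("left")
    right_ext, right_ok = extend("right")
    resolved = left_ok and right_ok
    refined = tuple(
        GenomicInterval(
            iv.seq_id,
            iv.start - (left_ext if iv.strand == "+" else right_ext),
            iv.end + (right_ext if iv.strand == "+" else left_ext),
            iv.strand,
        )
        for iv in ivs
    )
    return BoundaryResult(
        refined,
        left_ext,
        right_ext,
        resolved=resolved,
        note="" if resolved else "flanks did not diverge within max_extend",
    )


# ---------------------------------------------------------------------------
# Copy-number tiers


@dataclass
class CopyTier:
    """One copy-counting stringency tier.

    Either ``min_coverage`` (percent of query) or ``min_length`` (aligned bp,
    the relaxed tier) gates the hit, together with ``min_identity``.
    Comparisons are strict (>), matching the published tier wording.
    """

    min_identity: float
    min_coverage: float | None = None
    min_length: int | None = None
    copy_count: int = 0

    def __post_init__(self):
        if (self.min_coverage is None) == (self.min_length is None):
            raise ValueError("exactly one of min_coverage/min_length required")

    def accepts(self, hit: LocalAlignment) -> bool:
        if hit.identity <= self.min_identity:
            return False
        if self.min_coverage is not None:
            return hit.coverage > self.min_coverage
        return hit.aligned_length > self.min_length

    @property
    def label(self) -> str:
        if self.min_coverage is not None:
            return f"coverage>{self.min_coverage:g}% and identities>{self.min_identity:g}%"
        return f"coverage>{self.min_length} bp and identities>{self.min_identity:g}%"


def default_tiers() -> list[CopyTier]:
    """The four published stringency tiers, strictest first."""
    return [
        CopyTier(min_coverage=95, min_identity=95),
        CopyTier(min_coverage=90, min_identity=90),
        CopyTier(min_coverage=85, min_identity=85),
        CopyTier(min_length=200, min_identity=80),
    ]


def count_copies(
    element: str,
    genome: GenomeSequence | str,
    tiers: Sequence[CopyTier] | None = None,
) -> list[CopyTier]:
    """Count distinct non-overlapping subject loci per stringency tier.

    Non-overlap is resolved greedily by score.  Counts are expected to be
    non-decreasing from the strictest to the most relaxed tier.
    """
    if tiers is None:
        tiers = default_tiers()
    floor_id = min(t.min_identity for t in tiers)
    hits = local_search(element, genome, min_len_bp=1, min_identity=max(0.0, floor_id - 5))
    out = []
    for tier in tiers:
        accepted = [h for h in hits if tier.accepts(h)]
        accepted.sort(key=lambda h: -h.score)
        chosen: list[LocalAlignment] = []
        for h in accepted:
            if any(
                h.subject_interval.overlaps(c.subject_interval) for c in chosen
            ):
                continue
            chosen.append(h)
        out.append(replace(tier, copy_count=len(chosen)))
    return out
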
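"""Independent oracles used by the test suite.

These deliberately avoid the package's own matching/alignment code paths:
motif matching is checked against Python's ``re`` engine over fixed-length
expansions of each expression, and local alignment against a small numpy
Smith-Waterman.
"""

from __future__ import annotations

import itertools
import re

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def expand_variants(expr: str) -> list[str]:
    """Fixed-quantifier regex variants of a motif expression ('.' = [ACGT])."""
    expr = re.sub(r"\{(\d+)\s*,\s*(\d+)\}", lambda m: "{%s,%s}" % (m.group(1), m.group(2)), expr)
    expr = expr.replace(".", "[ACGT]")
    spans = list(re.finditer(r"\{(\d+),(\d+)\}", expr))
    if not spans:
        return [expr]
    ranges = [range(int(m.group(1)), int(m.group(2)) + 1) for m in spans]
    variants = []
    for combo in itertools.product(*ranges):
        out, last = [], 0
        for m, k in zip(spans, combo):
            out.append(expr[last : m.start()])
            out.append("{%d}" % k)
            last = m.end()
        out.append(expr[last:])
        variants.append("".join(out))
    return variants


def regex_scan(seq: str, expr: str, strand_mode: str = "both") -> set[tuple[int, int, str]]:
    """All (start, end, strand) motif matches via the re engine."""
    hits: set[tuple[int, int, str]] = set()
    variants = [re.compile(r"(?=(%s))" % v) for v in expand_variants(expr)]
    for pat in variants:
        for m in pat.finditer(seq):
            hits.add((m.start(), m.start() + len(m.group(1)), "+"))
    if strand_mode == "both":
        rc = revcomp(seq)
        n = len(seq)
        for pat in variants:
            for m in pat.finditer(rc):
                s, e = m.start(), m.start() + len(m.group(1))
                hits.add((n - e, n - s, "-"))
    return hits


def brute_force_scan(seq: str, expr: str, max_len: int) -> set[tuple[int, int]]:
    """Forward-strand matches by full-matching every substring (slow)."""
    variants = [re.compile(v) for v in expand_variants(expr)]
    hits = set()
    for start in range(len(seq)):
        for length in range(1, min(max_len, len(seq) - start) + 1):
            sub = seq[start : start + length]
            if any(v.fullmatch(sub) for v in variants):
                hits.add((start, start + length))
    return hits


def smith_waterman_score(a: str, b: str, match=1.0, mismatch=-2.0, gap=-3.0) -> float:
    """Best local alignment score, plain O(nm) dynamic programming."""
    n, m = len(a), len(b)
    prev = np.zeros(m + 1)
    best = 0.0
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        cur = np.zeros(m + 1)
        sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
        for j in range(1, m + 1):
            cur[j] = max(0.0, prev[j - 1] + sub[j - 1], prev[j] + gap, cur[j - 1] + gap)
        best = max(best, cur.max())
        prev = cur
    return best


def brute_force_pairing(hits, max_span_bp=20_000):
    """Reference pairing: for every 5'-hit, the farthest in-range same-family
    same-strand 3'-hit, with all nearer in-range 3'-ends collected."""
    calls = []
    for f in hits:
        if f.end_type != "five_prime" or f.pass_level == "pseudo":
            continue
        cands = []
        for t in hits:
            if (
                t.end_type != "three_prime"
                or t.pass_level == "pseudo"
                or t.family != f.family
                or t.interval.strand != f.interval.strand
                or t.interval.seq_id != f.interval.seq_id
            ):
                continue
            if f.interval.strand == "+":
                if t.interval.start >= f.interval.end and (
                    t.interval.end - f.interval.start < max_span_bp
                ):
                    cands.append(t)
            else:
                if t.interval.end <= f.interval.start and (
                    f.interval.end - t.interval.start < max_span_bp
                ):
                    cands.append(t)
        if not cands:
            continue
        if f.interval.strand == "+":
            ends = sorted({t.interval.end for t in cands})
            span = (f.interval.start, max(ends))
        else:
            ends = sorted({t.interval.start for t in cands})
            span = (min(ends), f.interval.end)
        calls.append((f.interval.seq_id, span[0], span[1], f.interval.strand, f.family, len(ends)))
    return sorted(calls)
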
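"""Terminal-motif patterns and genome scanning for terminus candidates.

The motif language covers exactly what the published terminal consensus
expressions need: literal bases, ``.`` (any of ACGT), character classes like
``[AT]``, and bounded quantifiers ``{n}`` / ``{m,n}``.  ``N`` (and any other
ambiguity code, and soft-masked bases) never matches, including at wildcard
positions.  Matching is exhaustive: every distinct match length at every
start position is reported, so downstream pairing can choose among
variable-length termini rather than being stuck with a single greedy match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import GenomeSequence, GenomicInterval, reverse_complement

DNA = "ACGT"

FAMILIES = ("helA", "helB")
END_TYPES = ("five_prime", "three_prime")
PASS_LEVELS = ("loose", "strict", "pseudo")


class MotifSyntaxError(ValueError):
    """Raised for malformed or unbounded motif expressions."""


@dataclass(frozen=True)
class _Token:
    """One motif unit: a character set repeated between min_n and max_n times."""

    chars: str  # sorted subset of ACGT
    min_n: int
    max_n: int


def _parse_tokens(expr: str) -> tuple[_Token, ...]:
    tokens: list[_Token] = []
    i, n = 0, len(expr)
    while i < n:
        ch = expr[i]
        if ch in DNA:
            chars = ch
            i += 1
        elif ch == ".":
            chars = DNA
            i += 1
        elif ch == "[":
            j = expr.find("]", i)
            if j < 0:
                raise MotifSyntaxError(f"unclosed '[' at position {i} in {expr!r}")
            inner = expr[i + 1 : j]
            if not inner or set(inner) - set(DNA):
                raise MotifSyntaxError(
                    f"character class [{inner}] is not over ACGT in {expr!r}"
                )
            chars = "".join(sorted(set(inner)))
            i = j + 1
        else:
            raise MotifSyntaxError(f"unexpected character {ch!r} at position {i} in {expr!r}")
        min_n = max_n = 1
        if i < n and expr[i] == "{":
            j = expr.find("}", i)
            if j < 0:
                raise MotifSyntaxError(f"unclosed '{{' at position {i} in {expr!r}")
            body = expr[i + 1 : j].replace(" ", "")
            m = re.fullmatch(r"(\d+)(?:,(\d*))?", body)
            if not m:
                raise MotifSyntaxError(f"bad quantifier {{{body}}} in {expr!r}")
            min_n = int(m.group(1))
            if m.group(2) is None:
                max_n = min_n
            elif m.group(2) == "":
                raise MotifSyntaxError(f"unbounded quantifier {{{body}}} in {expr!r}")
            else:
                max_n = int(m.group(2))
            if max_n < min_n:
                raise MotifSyntaxError(f"quantifier {{{body}}} has max < min in {expr!r}")
            i = j + 1
        tokens.append(_Token(chars, min_n, max_n))
    if not tokens:
        raise MotifSyntaxError("empty motif expression")
    return tuple(tokens)


def _compile_ops(tokens: Sequence[_Token]) -> list[tuple]:
    """Merge fixed single-base tokens into literal runs for fast matching."""
    ops: list[tuple] = []
    lit: list[str] = []
    for tok in tokens:
        if len(tok.chars) == 1 and tok.min_n == tok.max_n:
            lit.append(tok.chars * tok.min_n)
            continue
        if lit:
            ops.append(("lit", "".join(lit)))
            lit = []
        ops.append(("cls", frozenset(tok.chars), tok.min_n, tok.max_n))
    if lit:
        ops.append(("lit", "".join(lit)))
    return ops


@dataclass(frozen=True)
class TerminusPattern:
    """A compiled terminal-motif pattern for one family/end/pass level."""

    family: str
    end_type: str
    pass_level: str
    pattern: str
    _tokens: tuple[_Token, ...] = field(default=None, repr=False, compare=False)
    _ops: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.end_type not in END_TYPES:
            raise ValueError(f"unknown end type {self.end_type!r}")
        if self.pass_level not in PASS_LEVELS:
            raise ValueError(f"unknown pass level {self.pass_level!r}")
        tokens = _parse_tokens(self.pattern)
        object.__setattr__(self, "_tokens", tokens)
        object.__setattr__(self, "_ops", tuple(_compile_ops(tokens)))

    @property
    def min_length(self) -> int:
        return sum(t.min_n for t in self._tokens)

    @property
    def max_length(self) -> int:
        return sum(t.max_n for t in self._tokens)

    @property
    def prefix(self) -> str:
        """Leading fixed literal, used to pre-screen candidate start positions."""
        op = self._ops[0]
        return op[1] if op[0] == "lit" else ""

    def match_ends(self, seq: str, pos: int) -> list[int]:
        """All end positions of matches starting at ``pos`` (longest first)."""
        ends: set[int] = set()
        self._walk(0, seq, pos, ends)
        return sorted(ends, reverse=True)

    def _walk(self, k: int, seq: str, pos: int, ends: set[int]) -> None:
        ops = self._ops
        if k == len(ops):
            ends.add(pos)
            return
        op = ops[k]
        if op[0] == "lit":
            lit = op[1]
            if seq.startswith(lit, pos):
                self._walk(k + 1, seq, pos + len(lit), ends)
            return
        _, chars, min_n, max_n = op
        run = 0
        limit = min(max_n, len(seq) - pos)
        while run < limit and seq[pos + run] in chars:
            run += 1
        for n in range(min_n, run + 1):
            self._walk(k + 1, seq, pos + n, ends)

    def fullmatch(self, s: str) -> bool:
        """True iff the whole string ``s`` belongs to the pattern language."""
        return len(s) in self.match_ends(s, 0) if s else False

    def sample(self, rng) -> str:
        """Draw uniformly from the pattern's (finite) string set."""
        out: list[str] = []
        for tok in self._tokens:
            c = len(tok.chars)
            lengths = list(range(tok.min_n, tok.max_n + 1))
            if len(lengths) == 1:
                n = lengths[0]
            else:
                # uniform over strings => length L weighted by c**L
                weights = [c**L for L in lengths]
                total = sum(weights)
                r = rng.random() * total
                acc = 0
                n = lengths[-1]
                for L, w in zip(lengths, weights):
                    acc += w
                    if r < acc:
                        n = L
                        break
            out.append("".join(tok.chars[rng.randrange(c)] for _ in range(n)))
        return "".join(out)


@dataclass(frozen=True)
class TerminusHit:
    """One motif match on a genome, strand-oriented."""

    interval: GenomicInterval
    family: str
    end_type: str
    pass_level: str
    matched_text: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def gff_type(self) -> str:
        if self.pass_level == "pseudo":
            return "pseudo_terminus"
        return "terminus_5" if self.end_type == "five_prime" else "terminus_3"

    @property
    def name(self) -> str:
        return (
            f"{self.family}_{self.gff_type}_{self.interval.seq_id}"
            f"_{self.interval.start}_{self.interval.end}{self.interval.strand}"
        )


# ---------------------------------------------------------------------------
# Built-in patterns (published terminal consensus expressions, verbatim; the
# typographic space in the pseudo quantifier "{6, 8}" is normalized away by
# the parser).

_BUILTIN_SPECS = [
    ("helA", "three_prime", "loose", "CCCGT.{6,8}ACG[GA][GA].{6,8}CTAGT"),
    ("helA", "five_prime", "loose", "ATC[TC][ATCG]TA[TC]TA[TCA][ATCG]{5,6}AAG"),
    ("helB", "three_prime", "loose", "CGCC.{5,7}GGCG.{8,10}CTAGT"),
    ("helB", "five_prime", "loose", "ATC[ATCG]{7,8}TTAAAA"),
    ("helA", "three_prime", "strict", "CCGT.GCA[AT]CGCACG[GA]{2}.{7}CTAGT"),
    ("helA", "five_prime", "strict", "ATCT[ATCG]TACTAC.{5}A"),
    ("helB", "three_prime", "strict", "GCGCCC.{4}GGGCGC.{8}CTAGT"),
    ("helB", "five_prime", "strict", "ATC[TGA].{4}[TC][AC]TTAAAA"),
    ("helA", "three_prime", "pseudo", "CCGT[ATCG]GCA[AT]CGCACG[AG]{2}[ATCG]{6, 8}CTAT"),
]


def builtin_patterns() -> list[TerminusPattern]:
    """The nine built-in terminal patterns: 4 loose, 4 strict, 1 pseudo-3'."""
    return [TerminusPattern(*spec) for spec in _BUILTIN_SPECS]


def get_pattern(family: str, end_type: str, pass_level: str) -> TerminusPattern:
    for p in builtin_patterns():
        if (p.family, p.end_type, p.pass_level) == (family, end_type, pass_level):
            return p
    raise KeyError((family, end_type, pass_level))


def patterns_for_pass(pass_level: str) -> list[TerminusPattern]:
    """Patterns to scan for one pass level ('loose', 'strict' or 'both')."""
    if pass_level == "both":
        return [p for p in builtin_patterns() if p.pass_level in ("loose", "strict")]
    return [p for p in builtin_patterns() if p.pass_level == pass_level]


def load_patterns(path: str | Path) -> list[TerminusPattern]:
    """Load patterns from a plain-text config: family, end, pass, expression.

    Whitespace-separated, one pattern per line, '#' comments allowed.
    """
    patterns = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise MotifSyntaxError(
                    f"{path}:{lineno}: expected 'family end pass expression', got {raw!r}"
                )
            family, end_type, pass_level, expr = fields
            patterns.append(TerminusPattern(family, end_type, pass_level, expr))
    return patterns


def max_match_length(pattern: TerminusPattern) -> int:
    """Maximum length any match of ``pattern`` can have (quantifier bound)."""
    return pattern.max_length


# ---------------------------------------------------------------------------
# Scanning


def _candidate_starts(seq: str, pattern: TerminusPattern) -> Iterable[int]:
    prefix = pattern.prefix
    if prefix:
        pos = seq.find(prefix)
        while pos >= 0:
            yield pos
            pos = seq.find(prefix, pos + 1)
    else:
        first = pattern._ops[0][1]
        for pos, ch in enumerate(seq):
            if ch in first:
                yield pos


def _scan_one_strand(
    seq: str, seq_id: str, pattern: TerminusPattern, strand: str, seq_len: int
) -> list[TerminusHit]:
    hits = []
    for pos in _candidate_starts(seq, pattern):
        for end in pattern.match_ends(seq, pos):
            if strand == "+":
                iv = GenomicInterval(seq_id, pos, end, "+")
            else:
                iv = GenomicInterval(seq_id, seq_len - end, seq_len - pos, "-")
            hits.append(
                TerminusHit(
                    interval=iv,
                    family=pattern.family,
                    end_type=pattern.end_type,
                    pass_level=pattern.pass_level,
                    matched_text=seq[pos:end],
                )
            )
    return hits


def hit_sort_key(hit: TerminusHit):
    return (
        hit.interval.seq_id,
        hit.interval.start,
        -hit.interval.end,
        hit.interval.strand,
        hit.family,
        hit.end_type,
        hit.pass_level,
    )


def scan_termini(
    genome: GenomeSequence | str,
    patterns: Sequence[TerminusPattern],
    strand_mode: str = "both",
    respect_mask: bool = True,
) -> list[TerminusHit]:
    """Scan a genome for every terminus-motif match.

    Overlapping matches and all distinct match lengths at a start position
    are reported.  ``strand_mode`` is ``"forward"`` or ``"both"``; hits are
    sorted by (seq_id, start), longest-first within a start.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if isinstance(genome, str):
        genome = GenomeSequence(seq_id="seq", residues=genome.upper())
    fwd = genome.scan_residues(respect_mask)
    hits: list[TerminusHit] = []
    for pattern in patterns:
        hits.extend(_scan_one_strand(fwd, genome.seq_id, pattern, "+", genome.length))
    if strand_mode == "both":
        rev = reverse_complement(fwd)
        for pattern in patterns:
            hits.extend(_scan_one_strand(rev, genome.seq_id, pattern, "-", genome.length))
    hits.sort(key=hit_sort_key)
    return hits


def scan_genomes(
    genomes: Sequence[GenomeSequence],
    patterns: Sequence[TerminusPattern],
    strand_mode: str = "both",
) -> list[TerminusHit]:
    hits: list[TerminusHit] = []
    for g in genomes:
        hits.extend(scan_termini(g, patterns, strand_mode))
    hits.sort(key=hit_sort_key)
    return hits


def strict_loose_containment_violations(
    genome: GenomeSequence | str,
) -> list[TerminusHit]:
    """Strict helA-3' hits whose loose-pattern counterpart is absent.

    The printed loose helA 3' expression begins ``CCCGT`` while the strict
    one begins ``CCGT``, so a strict hit is expected to sit inside a loose
    hit only when the genomic base preceding it supplies the extra leading
    ``C``.  Hits where that context is present but the loose pattern still
    fails are returned (reported, never silently dropped).
    """
    if isinstance(genome, str):
        genome = GenomeSequence(seq_id="seq", residues=genome.upper())
    strict = get_pattern("helA", "three_prime", "strict")
    loose = get_pattern("helA", "three_prime", "loose")
    strict_hits = scan_termini(genome, [strict])
    loose_hits = scan_termini(genome, [loose])
    loose_keys = {
        (h.interval.seq_id, h.interval.strand, h.interval.end if h.strand == "+" else h.interval.start)
        for h in loose_hits
    }
    violations = []
    seq = genome.residues
    for h in strict_hits:
        iv = h.interval
        if iv.strand == "+":
            context = iv.start > 0 and seq[iv.start - 1] == "C"
            key = (iv.seq_id, "+", iv.end)
        else:
            context = iv.end < genome.length and seq[iv.end] == "G"
            key = (iv.seq_id, "-", iv.start)
        if context and key not in loose_keys:
            violations.append(h)
    return violations
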
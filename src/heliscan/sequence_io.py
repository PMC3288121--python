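"""FASTA input/output, call serialization, and shared coordinate conventions.

All internal coordinates are 0-based half-open.  Conversion to 1-based
inclusive coordinates happens only at GFF3 serialization; BED output keeps
the internal convention.  Strand is ``"+"`` or ``"-"``; sequences of
minus-strand features are reported strand-oriented (reverse complemented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted on input.
IUPAC_NT = frozenset("ACGTNRYSWKMBDHVU")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)

OUTPUT_FORMATS = ("bed", "gff3", "tsv", "fasta")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GenomeSequence:
    """One loaded sequence: uppercase residues plus an optional soft-mask track.

    ``mask`` records the intervals that were lowercase in the input; masked
    positions are excluded from motif matching via :meth:`scan_residues`.
    """

    seq_id: str
    residues: str
    mask: tuple[tuple[int, int], ...] = ()
    _scan_cache: str | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def scan_residues(self, respect_mask: bool = True) -> str:
        """Residues with soft-masked positions replaced by ``N``."""
        if not respect_mask or not self.mask:
            return self.residues
        if self._scan_cache is None:
            chars = list(self.residues)
            for s, e in self.mask:
                chars[s:e] = "N" * (e - s)
            self._scan_cache = "".join(chars)
        return self._scan_cache

    def slice(self, interval: GenomicInterval) -> str:
        """Strand-oriented substring at ``interval``."""
        if interval.end > self.length:
            raise ValueError(
                f"interval end {interval.end} beyond {self.seq_id} length {self.length}"
            )
        sub = self.residues[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; message names the offending line."""


def _validate_fasta_lines(path: Path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if not line[1:].strip():
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
                continue
            if not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            bad = set(line.upper()) - IUPAC_NT
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: non-IUPAC character(s) {sorted(bad)!r}"
                )


def _lowercase_runs(seq: str) -> tuple[tuple[int, int], ...]:
    runs: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return tuple(runs)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Load a FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased; lowercase (soft-masked) stretches are preserved
    in the ``mask`` track.  Duplicate IDs and non-IUPAC characters raise
    :class:`FastaParseError`.  An empty file yields an empty list with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_lines(path)
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        genomes.append(
            GenomeSequence(
                seq_id=rec.id,
                residues=raw.upper(),
                mask=_lowercase_runs(raw),
            )
        )
    if not genomes:
        log.warning("no sequences found in %s", path)
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.residues), id=g.seq_id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Call serialization
#
# Records are duck-typed: anything with an ``interval`` attribute serializes;
# ``gff_type``, ``name``, ``family`` and ``to_row()`` are used when present.


def _rec_name(rec, i: int) -> str:
    return getattr(rec, "name", None) or f"feature_{i}"


def _rec_type(rec) -> str:
    return getattr(rec, "gff_type", "helitron")


def _rec_attributes(rec, i: int) -> str:
    parts = [f"ID={_rec_name(rec, i)}"]
    for key in ("family", "pass_level", "end_type"):
        val = getattr(rec, key, None)
        if val is not None:
            parts.append(f"{key}={val}")
    for key in ("at_insertion", "putative_autonomous"):
        val = getattr(rec, key, None)
        if val is not None:
            parts.append(f"{key}={'true' if val else 'false'}")
    for key in ("multi_termini_5", "multi_termini_3"):
        val = getattr(rec, key, None)
        if val is not None:
            parts.append(f"{key}={val}")
    return ";".join(parts)


def _rec_row(rec, i: int) -> dict:
    if hasattr(rec, "to_row"):
        return rec.to_row()
    iv = rec.interval
    row = {
        "seq_id": iv.seq_id,
        "start": iv.start,
        "end": iv.end,
        "strand": iv.strand,
        "name": _rec_name(rec, i),
        "type": _rec_type(rec),
    }
    for key in ("family", "pass_level", "end_type"):
        val = getattr(rec, key, None)
        if val is not None:
            row[key] = val
    return row


def write_calls(
    calls: Sequence,
    path: str | Path,
    fmt: str,
    genomes: dict[str, GenomeSequence] | None = None,
) -> None:
    """Serialize feature records to ``bed``, ``gff3``, ``tsv`` or ``fasta``.

    BED is 0-based half-open, GFF3 1-based inclusive.  FASTA output emits the
    element substring, reverse complemented for minus-strand features, and
    requires ``genomes``.
    """
    fmt = fmt.lower()
    if fmt not in OUTPUT_FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; expected one of {OUTPUT_FORMATS}")
    path = Path(path)
    if fmt == "bed":
        with open(path, "w") as fh:
            fh.write('track name="heliscan"\n')
            for i, rec in enumerate(calls):
                iv = rec.interval
                fh.write(
                    f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{_rec_name(rec, i)}"
                    f"\t0\t{iv.strand}\n"
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, rec in enumerate(calls):
                iv = rec.interval
                fh.write(
                    f"{iv.seq_id}\theliscan\t{_rec_type(rec)}\t{iv.start + 1}"
                    f"\t{iv.end}\t.\t{iv.strand}\t.\t{_rec_attributes(rec, i)}\n"
                )
    elif fmt == "tsv":
        rows = [_rec_row(rec, i) for i, rec in enumerate(calls)]
        cols: list[str] = []
        for row in rows:
            for key in row:
                if key not in cols:
                    cols.append(key)
        if not cols:
            cols = ["seq_id", "start", "end", "strand", "name", "type"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    else:  # fasta
        if genomes is None:
            raise ValueError("FASTA output requires the source genomes")
        records = []
        for i, rec in enumerate(calls):
            iv = rec.interval
            genome = genomes[iv.seq_id]
            records.append(
                SeqRecord(Seq(genome.slice(iv)), id=_rec_name(rec, i), description="")
            )
        SeqIO.write(records, str(path), "fasta")
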
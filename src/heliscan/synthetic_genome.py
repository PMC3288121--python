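"""Synthetic genomes with planted elements and full ground truth.

Every other module is testable offline against these genomes: planted
elements carry termini sampled uniformly from the strict pattern languages,
AT host flanks, a sub-terminal hairpin, optional decayed (CTAT) internal
pseudo 3'-termini, optional captured segments, and optional nested
insertions.  A fixed seed makes the emitted FASTA and truth byte-identical.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .motif_engine import get_pattern
from .sequence_io import GenomeSequence, GenomicInterval, reverse_complement

DNA = "ACGT"


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.47
    n_helA: int = 3
    n_helB: int = 0
    # published element-size range: 128 bp to 20,874 bp
    element_length_range: tuple[int, int] = (500, 4_000)
    p_capture: float = 0.0
    p_internal_pseudo3: float = 0.0
    p_nest: float = 0.0
    nesting_depth: int = 2  # total levels when a nest triggers
    p_minus_strand: float = 0.0
    p_terminus_decay: float = 0.0  # planted element's own 3' CTAG -> CTAT
    min_spacing: int = 20_000  # keeps distinct elements from chaining
    plant_hairpin: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("p_capture", "p_internal_pseudo3", "p_nest",
                     "p_minus_strand", "p_terminus_decay", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.element_length_range
        if not 128 <= lo <= hi <= 20_874:
            raise ValueError("element_length_range must lie within [128, 20874]")


@dataclass
class ElementTruth:
    name: str
    family: str
    strand: str
    start: int  # final genome coordinates, 0-based half-open
    end: int
    five_terminus: str
    three_terminus: str
    flank_upstream: str
    flank_downstream: str
    hairpin: tuple[int, int] | None  # element-local coords of the palindrome
    pseudo3_offsets: tuple[int, ...] = ()  # element-local starts of CTAT loci
    captured: tuple[tuple[int, int, str], ...] = ()  # (start, end, donor_id)
    nesting_parent: str | None = None
    three_decayed: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval("synth", self.start, self.end, self.strand)


@dataclass
class SyntheticTruth:
    seq_id: str
    genome_length: int
    elements: list[ElementTruth]
    events: list[dict]  # simulation-order event log
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "seq_id": self.seq_id,
            "genome_length": self.genome_length,
            "elements": [asdict(e) for e in self.elements],
            "events": self.events,
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=2)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.truth.json", "w") as fh:
            fh.write(self.to_json() + "\n")
        with open(f"{prefix}.truth.bed", "w") as fh:
            for e in self.elements:
                fh.write(f"{self.seq_id}\t{e.start}\t{e.end}\t{e.name}\t0\t{e.strand}\n")
        with open(f"{prefix}.events.log", "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")


def _random_dna(rng: random.Random, n: int, gc: float) -> str:
    at, gcw = (1 - gc) / 2, gc / 2
    return "".join(rng.choices("ACGT", weights=(at, gcw, gcw, at), k=n))


def _decay_three_terminus(terminus: str) -> str:
    """Turn an intact 3'-terminus (...CTAGT) into a decayed one (...CTATT)."""
    if not terminus.endswith("CTAGT"):
        raise ValueError("expected an intact CTAGT ending")
    return terminus[:-2] + "TT"


@dataclass
class _BuiltElement:
    seq: str
    five: str
    three: str
    hairpin_local: tuple[int, int] | None
    pseudo3_offsets: tuple[int, ...]
    captured: tuple[tuple[int, int, str], ...]
    three_decayed: bool


def _build_element(
    rng: random.Random,
    family: str,
    length: int,
    config: SimulationConfig,
    donor_counter: list[int],
) -> _BuiltElement:
    five = get_pattern(family, "five_prime", "strict").sample(rng)
    three = get_pattern(family, "three_prime", "strict").sample(rng)
    three_decayed = False
    if rng.random() < config.p_terminus_decay:
        three = _decay_three_terminus(three)
        three_decayed = True

    hairpin = None
    tail = ""
    if config.plant_hairpin:
        stem = _random_dna(rng, 8, 0.5)
        hairpin_seq = stem + _random_dna(rng, 2, 0.5) + reverse_complement(stem)
        tail = hairpin_seq + _random_dna(rng, 4, config.gc_fraction)

    body_len = length - len(five) - len(three) - len(tail)
    parts: list[str] = []
    pseudo_offsets: list[int] = []
    captured: list[tuple[int, int, str]] = []
    pos = len(five)

    if rng.random() < config.p_internal_pseudo3 and body_len > 80:
        pseudo = _decay_three_terminus(
            get_pattern(family, "three_prime", "strict").sample(rng)
        )
        pre = _random_dna(rng, (body_len - len(pseudo)) // 2, config.gc_fraction)
        post_len = body_len - len(pseudo) - len(pre)
        parts = [pre, pseudo, _random_dna(rng, post_len, config.gc_fraction)]
        pseudo_offsets.append(pos + len(pre))
    elif rng.random() < config.p_capture and body_len > 400:
        frag_len = rng.randint(150, min(600, body_len - 100))
        donor_id = f"donor{donor_counter[0]}"
        donor_counter[0] += 1
        frag = _random_dna(rng, frag_len, 0.5)
        pre_len = rng.randint(30, body_len - frag_len - 30)
        pre = _random_dna(rng, pre_len, config.gc_fraction)
        post = _random_dna(rng, body_len - frag_len - pre_len, config.gc_fraction)
        parts = [pre, frag, post]
        captured.append((pos + pre_len, pos + pre_len + frag_len, donor_id))
    else:
        parts = [_random_dna(rng, max(body_len, 0), config.gc_fraction)]

    seq = five + "".join(parts) + tail + three
    if hairpin is None and config.plant_hairpin:
        hp_start = len(seq) - len(three) - len(tail)
        hairpin = (hp_start, hp_start + 18)
    return _BuiltElement(
        seq=seq,
        five=five,
        three=three,
        hairpin_local=hairpin,
        pseudo3_offsets=tuple(pseudo_offsets),
        captured=tuple(captured),
        three_decayed=three_decayed,
    )


def generate(config: SimulationConfig) -> tuple[GenomeSequence, SyntheticTruth]:
    """Generate one genome with planted elements plus its ground truth.

    Background is i.i.d. at the configured GC; elements are inserted between
    a forced A/T host dinucleotide, spaced at least ``min_spacing`` apart so
    that distinct elements never chain under the pairing rule.  Nesting
    inserts child elements into the body of a host element; every event is
    logged in simulation order.
    """
    rng = random.Random(config.seed)
    events: list[dict] = []
    donor_counter = [0]

    plan: list[tuple[str, int]] = []  # (family, target length)
    lo, hi = config.element_length_range
    for family, n in (("helA", config.n_helA), ("helB", config.n_helB)):
        for _ in range(n):
            plan.append((family, rng.randint(lo, hi)))
    rng.shuffle(plan)

    built: list[tuple[_BuiltElement, str, str, str | None]] = []
    counter = 0
    for family, length in plan:
        elem = _build_element(rng, family, length, config, donor_counter)
        name = f"{family}_{counter}"
        counter += 1
        strand = "-" if rng.random() < config.p_minus_strand else "+"
        built.append([elem, family, name, strand, None])  # type: ignore[list-item]
        if rng.random() < config.p_nest:
            host = built[-1]
            for _ in range(max(config.nesting_depth - 1, 0)):
                child_len = max(lo, min(hi, rng.randint(lo, max(lo + 1, length // 2))))
                child = _build_element(rng, family, child_len, config, donor_counter)
                child_name = f"{family}_{counter}"
                counter += 1
                built.append([child, family, child_name, host[3], host[2]])  # type: ignore[list-item]
                events.append(
                    {"type": "nested_insertion", "child": child_name, "parent": host[2]}
                )
                host = built[-1]

    # nested children are spliced into their parent rather than placed alone
    top_level = [b for b in built if b[4] is None]
    children = {b[2]: b for b in built if b[4] is not None}

    total_elem = sum(len(b[0].seq) for b in built)
    bg_len = config.genome_length - total_elem
    if bg_len < (len(top_level) + 1) * config.min_spacing:
        raise ValueError(
            f"cannot place {len(top_level)} elements with spacing "
            f"{config.min_spacing} in a {config.genome_length} bp genome; "
            "lower n_elements or min_spacing"
        )
    background = list(_random_dna(rng, bg_len, config.gc_fraction))

    # jittered even placement keeps consecutive sites >= min_spacing apart
    n_top = len(top_level)
    chosen: list[int] = []
    if n_top:
        slot = bg_len // (n_top + 1)
        jitter = max(0, (slot - config.min_spacing) // 2 - 1)
        for i in range(n_top):
            off = (i + 1) * slot + (rng.randint(-jitter, jitter) if jitter else 0)
            chosen.append(off)

    def _assemble(b) -> tuple[str, list[dict]]:
        """Splice nested children into their host; return the assembled
        sequence plus per-element records with coordinates local to it."""
        elem, family, name, strand_, parent = b
        seq = elem.seq
        my = {
            "b": b,
            "start": 0,
            "hairpin": elem.hairpin_local,
            "pseudo3": list(elem.pseudo3_offsets),
            "captured": list(elem.captured),
        }
        recs = [my]
        for cb in children.values():
            if cb[4] != name:
                continue
            child_seq, sub_recs = _assemble(cb)
            lo_ins = len(elem.five) + 10
            hi_ins = len(elem.seq) - len(elem.three) - 40
            ins = rng.randint(lo_ins, max(lo_ins + 1, hi_ins))
            # forced A/T host dinucleotide around the nested child
            seq = seq[: ins - 1] + "A" + child_seq + "T" + seq[ins + 1 :]
            shift = len(child_seq)
            if my["hairpin"] and my["hairpin"][0] >= ins:
                my["hairpin"] = (my["hairpin"][0] + shift, my["hairpin"][1] + shift)
            my["pseudo3"] = [p + shift if p >= ins else p for p in my["pseudo3"]]
            my["captured"] = [
                ((s + shift, e + shift, d) if s >= ins else (s, e, d))
                for s, e, d in my["captured"]
            ]
            for r in sub_recs:
                r["start"] += ins
            recs.extend(sub_recs)
        my["length"] = len(seq)
        return seq, recs

    elements_truth: list[ElementTruth] = []
    pieces: list[str] = []
    cursor = 0
    genome_pos = 0
    for b, off in zip(top_level, chosen):
        _, family, name, strand, _parent = b
        seq, recs = _assemble(b)
        oriented = seq if strand == "+" else reverse_complement(seq)
        # background up to the site, with forced A/T flanks around the element
        pieces.append("".join(background[cursor : off - 1]) + "A")
        genome_pos += off - cursor
        start = genome_pos
        pieces.append(oriented)
        genome_pos += len(oriented)
        end = genome_pos
        background[off] = "T"
        cursor = off
        for r in recs:
            bb = r["b"]
            length = r.get("length") or len(bb[0].seq)
            if strand == "+":
                g_start = start + r["start"]
                g_end = g_start + length
            else:
                g_end = end - r["start"]
                g_start = g_end - length
            elements_truth.append(
                ElementTruth(
                    name=bb[2],
                    family=bb[1],
                    strand=strand,
                    start=g_start,
                    end=g_end,
                    five_terminus=bb[0].five,
                    three_terminus=bb[0].three,
                    flank_upstream="A",
                    flank_downstream="T",
                    hairpin=r["hairpin"],
                    pseudo3_offsets=tuple(r["pseudo3"]),
                    captured=tuple(r["captured"]),
                    nesting_parent=bb[4],
                    three_decayed=bb[0].three_decayed,
                )
            )
        events.append(
            {"type": "insertion", "element": name, "start": start, "end": end,
             "strand": strand}
        )

    pieces.append("".join(background[cursor:]))
    residues = "".join(pieces)
    genome = GenomeSequence(seq_id="synth", residues=residues)
    truth = SyntheticTruth(
        seq_id="synth",
        genome_length=len(residues),
        elements=elements_truth,
        events=events,
        config=config,
    )
    return genome, truth


def mutate_copies(
    element: str,
    n: int,
    divergence: float,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Make ``n`` copies with i.i.d. substitutions at rate ``divergence``.

    Returns (copy, realized identity percent) pairs.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must be in [0, 0.3]")
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        chars = list(element)
        changed = 0
        for i, ch in enumerate(chars):
            if rng.random() < divergence:
                chars[i] = rng.choice([b for b in DNA if b != ch])
                changed += 1
        out.append(("".join(chars), 100.0 * (len(element) - changed) / len(element)))
    return out


# ---------------------------------------------------------------------------
# Forward-simulated capture/loss histories (for event-inference tests)


def simulate_capture_history(
    seed: int,
    k: int,
    ancestor_length: int = 2_000,
    capture_range: tuple[int, int] = (300, 800),
    loss_range: tuple[int, int] = (150, 400),
    p_loss: float = 0.3,
    edge_margin: int = 120,
    breakpoint_margin: int = 80,
) -> tuple[dict[str, str], list[dict]]:
    """Simulate k sequential capture/loss steps from a random ancestor.

    Returns the element series (``e0`` ... ``e<k>``) and the true event log.
    Event positions keep ``breakpoint_margin`` bp away from earlier
    breakpoints so that every shared block stays detectable.
    """
    rng = random.Random(seed)
    seq = _random_dna(rng, ancestor_length, 0.5)
    elements = {"e0": seq}
    truth: list[dict] = []
    breakpoints: list[int] = []

    for step in range(1, k + 1):
        prev = seq
        for _ in range(200):
            if rng.random() < p_loss and len(prev) > 2 * edge_margin + loss_range[1]:
                length = rng.randint(*loss_range)
                pos = rng.randint(edge_margin, len(prev) - edge_margin - length)
                span = (pos, pos + length)
                ev_type = "loss"
            else:
                length = rng.randint(*capture_range)
                pos = rng.randint(edge_margin, len(prev) - edge_margin)
                span = (pos, pos)
                ev_type = "capture"
            near = any(
                abs(edge - b) < breakpoint_margin
                for b in breakpoints
                for edge in span
            )
            if not near:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place event away from old breakpoints")

        if ev_type == "capture":
            frag = _random_dna(rng, length, 0.5)
            seq = prev[:pos] + frag + prev[pos:]
            breakpoints = [b if b < pos else b + length for b in breakpoints]
            breakpoints += [pos, pos + length]
            truth.append(
                {"type": "capture", "parent": f"e{step-1}", "child": f"e{step}",
                 "start": pos, "end": pos + length}
            )
        else:
            seq = prev[:pos] + prev[pos + length :]
            breakpoints = [
                b if b < pos else b - length for b in breakpoints
                if b < pos or b >= pos + length
            ]
            breakpoints += [pos]
            truth.append(
                {"type": "loss", "parent": f"e{step-1}", "child": f"e{step}",
                 "start": pos, "end": pos + length}
            )
        elements[f"e{step}"] = seq
    return elements, truth
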
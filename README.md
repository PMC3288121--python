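# heliscan

A toolkit for discovering and characterizing **helitron** DNA transposons in
genomic sequence by their terminal hallmarks, and for reasoning about their
structural evolution:

- **Terminal-motif scanning** — the helA/helB 5'- and 3'-terminus consensus
  patterns (a loose and a strict pass per family, plus the decayed CTAT
  pseudo-3' consensus), matched exhaustively on both strands with every
  distinct match length reported.
- **Element calling** — pairing 5'/3' terminus hits into intact element
  calls under the < 20 kb span rule, with AT-flank, sub-terminal hairpin,
  multiple-termini and putative-autonomous annotation.
- **Termini analysis** — real (CTAG-intact) vs pseudo (CTAT) 3'-terminus
  classification, per-element multiple-termini profiling, and prediction of
  the products of partial read-out transposition from nested elements.
- **Homology engine** — a BLASTN-like seed-and-extend local search used for
  seed-based discovery, multi-copy boundary validation, and tiered
  copy-number counting (coverage/identity tiers from >95/>95 down to
  >200 bp/>80).
- **Capture analysis** — decomposition of related elements into shared
  homologous segment blocks and inference of stepwise gene-fragment
  capture, internal loss and nested-insertion histories, with exact replay
  of every inferred event.
- **Synthetic genomes** — a ground-truthed simulator planting elements with
  sampled strict termini, AT host flanks, hairpins, pseudo termini, capture
  events and nested insertions, so the whole pipeline is testable offline.

## CLI

All subcommands hang off a single entry point; every run writes a
`manifest.json` (parameters, input checksums, version, seed) next to its
outputs.

```bash
# simulate a ground-truthed genome
heliscan --seed 7 simulate --config sim.yaml --out-prefix out/sim

# scan + pair + annotate element calls (GFF3 + TSV)
heliscan call --fasta genome.fasta --pass strict --out-prefix out/calls

# pseudo-terminus scan and multiple-termini profile
heliscan termini --fasta genome.fasta --out out/termini.tsv

# nested-transposition product prediction
heliscan nested --config nest.json     # {"elements": [...], "launch": "..."}

# homology-based discovery from seed elements
heliscan discover --seeds seeds.fasta --fasta genome.fasta --out out/cand.gff3

# tiered copy-number table
heliscan copynum --element element.fasta --fasta genome.fasta --out out/cn.tsv

# segment decomposition + capture/loss/nesting event graph
heliscan capture-graph --elements related.fasta --out-prefix out/graph
```

## Library

```python
from heliscan import motif_engine, helitron_caller, synthetic_genome

cfg = synthetic_genome.SimulationConfig(genome_length=500_000, n_helA=5, seed=1)
genome, truth = synthetic_genome.generate(cfg)
hits = motif_engine.scan_termini(genome, motif_engine.patterns_for_pass("strict"))
calls = helitron_caller.pair_termini(hits)
```

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Strand-oriented sequence is reverse complemented for minus-strand
features.  `N` and soft-masked bases never match any motif position.

## Tests and acceptance report

```bash
python -m pytest -q                 # full suite (unit + property + acceptance)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(nested-product worked example, pairing rule, regex-oracle equivalence on
100×10 kb, planted-element recovery on 50×1 Mb genomes plus a
false-positive floor on 100 element-free megabases, pseudo-terminus
soundness, copy-tier monotonicity, and capture-history recovery over 100
forward simulations).  `scripts/acceptance.py` recomputes the reported
target by simulating a depth-3 nested element, re-deriving its configuration
from terminal-motif hits alone, and counting the predicted product termini.
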
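import random

import pytest

from heliscan.sequence_io import GenomeSequence


def random_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    at, gcw = (1 - gc) / 2, gc / 2
    return "".join(rng.choices("ACGT", weights=(at, gcw, gcw, at), k=n))


@pytest.fixture
def rng():
    return random.Random(20110609)


@pytest.fixture
def small_genome(rng):
    return GenomeSequence(seq_id="chr1", residues=random_dna(rng, 10_000))


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(records: dict[str, str], name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for seq_id, seq in records.items():
                fh.write(f">{seq_id}\n{seq}\n")
        return path

    return _write
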
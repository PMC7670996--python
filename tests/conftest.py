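from __future__ import annotations

import numpy as np
import pytest

from triplexome.simulate import write_fasta


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write {name: seq} dicts to temporary FASTA files."""

    counter = {"n": 0}

    def _write(sequences: dict[str, str]) -> str:
        counter["n"] += 1
        path = tmp_path / f"seqs{counter['n']}.fa"
        write_fasta(sequences, path)
        return str(path)

    return _write


def random_seq(rng: np.random.Generator, length: int, probs=(0.25, 0.25, 0.25, 0.25), n_rate=0.0) -> str:
    bases = rng.choice(np.array(list("ACGT")), size=length, p=np.asarray(probs) / np.sum(probs))
    if n_rate:
        mask = rng.random(length) < n_rate
        bases[mask] = "N"
    return "".join(bases)
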
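import random

import pytest

from genefam.seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(0)


@pytest.fixture
def random_peptide(rng):
    def make(n, seed=None):
        r = random.Random(seed) if seed is not None else rng
        return "".join(r.choice(AA20) for _ in range(n))

    return make


@pytest.fixture
def fasta_file(tmp_path):
    def make(records, name="test.faa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec in records:
                rid, seq = (rec.id, rec.residues) if isinstance(rec, SequenceRecord) else rec
                fh.write(f">{rid}\n{seq}\n")
        return path

    return make
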
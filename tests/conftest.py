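import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fasta_file(tmp_path):
    """Write records to a temporary FASTA file and return its path."""

    def _write(records, name="seqs.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, bases in records:
                fh.write(f">{rid}\n{bases}\n")
        return path

    return _write
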
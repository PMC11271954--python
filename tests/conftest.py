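import numpy as np
import pandas as pd
import pytest

from dogwoodkin import GenotypeMatrix

M = -1  # missing call shorthand for fixtures


def toy_matrix(calls, positions=None, contigs=None, accessions=None):
    """Build a small GenotypeMatrix from a nested list of dosage calls
    (rows = accessions)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_mark = calls.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_mark)]
    if contigs is None:
        contigs = ["chr1"] * n_mark
    if accessions is None:
        accessions = [f"acc{i}" for i in range(n_acc)]
    markers = pd.DataFrame({
        "id": [f"mk{j}" for j in range(n_mark)],
        "contig": contigs,
        "position": positions,
        "ref": ["A"] * n_mark,
        "alt": ["T"] * n_mark,
    })
    return GenotypeMatrix(calls=calls, markers=markers, accessions=accessions)


def random_matrix(rng, n_acc=20, n_mark=300, missing_rate=0.05):
    """Random dosage matrix with missingness, for oracle-equivalence tests."""
    calls = rng.integers(0, 3, size=(n_acc, n_mark)).astype(np.int8)
    calls[rng.random((n_acc, n_mark)) < missing_rate] = M
    return toy_matrix(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240725)
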
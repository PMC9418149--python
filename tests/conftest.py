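import numpy as np
import pytest

import matriline as m
from matriline.seqio import AlignedSequence


@pytest.fixture(scope="session")
def ref():
    return m.default_reference()


@pytest.fixture(scope="session")
def tree():
    return m.default_motif_tree()


@pytest.fixture(scope="session")
def founders(ref, tree):
    return m.make_founders(tree, ref)


def make_alns(seqs: list[str], prefix: str = "s") -> list[AlignedSequence]:
    """Wrap raw in-frame strings as aligned sequences."""
    return [AlignedSequence(sample_id=f"{prefix}{i + 1}", states=s) for i, s in enumerate(seqs)]


def random_state_strings(rng: np.random.Generator, n: int, L: int, alphabet="ACGT") -> list[str]:
    arr = rng.choice(list(alphabet), size=(n, L))
    return ["".join(row) for row in arr]
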
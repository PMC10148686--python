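import math
import random

import numpy as np
import pytest

from ehmmalign import (Alignment, SubAlignment, build_profile_hmm)
from ehmmalign.alphabet import DNA


def random_profile_hmm(rng: random.Random, max_match=4, backbone_len=6):
    """A random, properly normalised profile HMM for oracle batteries.

    Built through the public builder on a random sub-alignment so the
    column map, transition support and normalisation are all realistic.
    """
    nrows = rng.randint(1, 4)
    L = rng.randint(max(2, max_match), backbone_len)
    rows = {}
    for r in range(nrows):
        rows[f"r{r}"] = "".join(
            rng.choice("ACGT-") if rng.random() < 0.8 else "-"
            for _ in range(L))
    # ensure at least one fully occupied column so match states exist
    j = rng.randrange(L)
    rows = {i: s[:j] + rng.choice("ACGT") + s[j + 1:]
            for i, s in rows.items()}
    sub = SubAlignment(rows, list(range(L)))
    hmm = build_profile_hmm(sub, symfrac=rng.choice([0.3, 0.5, 1.0]),
                            pseudocount=rng.choice([0.3, 1.0]),
                            transition_pseudocount=rng.choice([0.05, 0.2]),
                            alphabet=DNA)
    if hmm.S_local > max_match:
        return None
    return hmm


def random_query(rng: random.Random, max_len=4) -> str:
    return "".join(rng.choice("ACGT") for _ in range(rng.randint(0, max_len)))


@pytest.fixture
def toy_backbone():
    """Small ungapped backbone of distinct sequences (noiseless toy)."""
    return Alignment({
        "a": "ACGTGCAT",
        "b": "ACGTGCAA",
        "c": "CCGTGCAT",
    })


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240917)


def assert_dist_sums(dist: dict, tol=1e-9):
    assert math.isclose(sum(dist.values()), 1.0, abs_tol=tol)
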
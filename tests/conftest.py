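"""Shared fixtures: synthetic databases and randomized test instances."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qtitrate import ProteinSequence, find_ionizable_sites, synthesize_db

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: residues used for randomized sequences: all titratable types plus spacers
RANDOM_ALPHABET = list("DEHKCYGAS")


@pytest.fixture(scope="session")
def db():
    """Default synthetic database: window 5, 1 kcal/mol coupling."""
    return synthesize_db(window=5, coupling_a=1.0, decay_p=1.0, seed=0)


@pytest.fixture(scope="session")
def decoupled_db():
    """Coupling-free database: every site titrates at its model pKa."""
    return synthesize_db(window=5, coupling_a=0.0, decay_p=1.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def random_instance(rng, n_min=2, n_max=12, window=None):
    """A random (sequence, sites, database) triple with n_min..n_max sites."""
    target = int(rng.integers(n_min, n_max + 1))
    chars = []
    n_ion = 0
    while n_ion < target:
        c = str(rng.choice(RANDOM_ALPHABET))
        chars.append(c)
        if c in "DEHKCY":
            n_ion += 1
    seq = ProteinSequence.from_string("rand", "".join(chars))
    w = int(rng.integers(1, 6)) if window is None else window
    inst_db = synthesize_db(
        window=w,
        coupling_a=float(rng.uniform(0.0, 2.0)),
        decay_p=float(rng.uniform(0.5, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sites = find_ionizable_sites(seq)
    return seq, sites, inst_db
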
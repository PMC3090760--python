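"""Shared helpers for the test suite: random instances and schemes."""

import numpy as np

from rsalign.core import ALPHABET, RnaSequence, ScoringScheme
from rsalign.scan import random_regular_structure


def make_seq(rng: np.random.Generator, k: int, name: str = "r") -> RnaSequence:
    return RnaSequence(name, "".join(ALPHABET[c] for c in rng.integers(0, 4, size=k)))


def make_scheme(rng: np.random.Generator, kind=None) -> ScoringScheme:
    """One of three scheme families; kind 0 is the paper's h=5, s=0.1 default."""
    if kind is None:
        kind = int(rng.integers(0, 3))
    if kind == 0:
        return ScoringScheme.default()  # h=5, s=0.1
    if kind == 1:
        return ScoringScheme.default(
            h=float(rng.uniform(0, 3)),
            s=float(rng.uniform(0, 1)),
            match=2.0,
            mismatch=-0.5,
            pair_bonus=1.0,
        )
    gamma = rng.uniform(-2, 2, size=(4, 4))
    delta = rng.uniform(-4, 6, size=(4, 4, 4, 4))
    return ScoringScheme(gamma, delta, h=float(rng.uniform(0, 4)), s=float(rng.uniform(0, 1)))


def make_instance(rng: np.random.Generator, max_size: int = 6, scheme_kind=None):
    """Random (query, structure, target, scheme) tuple for oracle checks."""
    m = int(rng.integers(0, max_size + 1))
    n = int(rng.integers(0, max_size + 1))
    query = make_seq(rng, m, "q")
    target = make_seq(rng, n, "t")
    structure = random_regular_structure(m, rng)
    scheme = make_scheme(rng, scheme_kind)
    return query, structure, target, scheme
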
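"""Deterministic seed fan-out.

A single master seed must reproduce every stochastic step bit-for-bit:
bootstrap draws, tree construction, OOB permutations, repeat loops and
synthetic-data generation.  All sub-streams are derived from
``numpy.random.SeedSequence(master, spawn_key=(domain, *indices))`` with a
fixed domain constant per purpose, so independent loops (e.g. a brute-force
re-implementation of permutation importance in a test) can reconstruct the
exact same streams from the documented scheme.
"""

from __future__ import annotations

import numpy as np

# domain constants — part of the public determinism contract
BOOTSTRAP = 0
TREE = 1
PERMUTE = 2
ELIMINATE = 3
REPEAT = 4
SIMULATE = 5
SUBSET = 6


def rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def derive_int(master_seed: int, *key: int) -> int:
    """A 31-bit integer sub-seed (usable as an sklearn random_state)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def bootstrap_rng(seed: int, tree_index: int, attempt: int = 0) -> np.random.Generator:
    return rng(seed, BOOTSTRAP, tree_index, attempt)


def tree_seed(seed: int, tree_index: int) -> int:
    return derive_int(seed, TREE, tree_index)


def permutation_rng(seed: int, tree_index: int, feature_index: int) -> np.random.Generator:
    return rng(seed, PERMUTE, tree_index, feature_index)


def elimination_seed(seed: int, step: int) -> int:
    return derive_int(seed, ELIMINATE, step)


def repeat_seed(seed: int, repeat_index: int) -> int:
    return derive_int(seed, REPEAT, repeat_index)
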
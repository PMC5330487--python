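"""Seeding helpers: one master seed, independent named substreams."""

from __future__ import annotations

import hashlib

import numpy as np

# Stream names used across the package. New names may be added freely;
# the hash-derived spawn key keeps existing streams stable.
STREAMS = ("ancestry", "genotypes", "phenotypes", "permutations", "covariates")


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of a master seed.

    Streams with distinct names are statistically independent; the same
    (seed, name) pair always yields an identical stream.
    """
    ss = np.random.SeedSequence(seed, spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)
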
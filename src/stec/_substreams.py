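"""Named random substreams derived from one master seed.

Every source of randomness in the package (scenes, gaze, position
permutations, train/test noise, weight init, decoder seeds) draws from a
named child of a single master seed, so runs are reproducible and the
train/test noise streams are disjoint by construction.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Distinct name tuples yield statistically independent streams; the same
    tuple always yields the same stream.
    """
    keys = [_name_key(n) if isinstance(n, str) else int(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *keys]))


def substream_seed(master_seed: int, *names: str | int) -> int:
    """A plain integer seed (< 2**31) for APIs that take one (e.g. sklearn)."""
    return int(substream(master_seed, *names).integers(0, 2**31 - 1))
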
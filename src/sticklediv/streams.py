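"""Splittable random streams.

One user-facing seed drives independent substreams for data generation,
bootstrap resampling and permutation shuffling, so that e.g. changing the
number of bootstrap replicates never perturbs the generated data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream", "substream_seed"]

_STREAM_IDS = {
    "generate": 11,
    "bootstrap": 23,
    "permutation": 37,
    "missingness": 41,
    "sizes": 43,
}


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    if name not in _STREAM_IDS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAM_IDS)}")
    return np.random.SeedSequence([_STREAM_IDS[name], int(seed)])


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a global seed."""
    return np.random.default_rng(substream_seed(seed, name))
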
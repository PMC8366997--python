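"""Deterministic seed fan-out.

A single global seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence`` keyed by a stable hash of the stage name, so
every pipeline stage is reproducible in isolation and stages never share a
random stream.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31  # keep derived seeds valid for scikit-learn random_state


def child_seed(seed: int, *keys: str | int) -> int:
    """Derive a stage seed from a global seed and a sequence of labels."""
    ints = [seed % _MOD]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k) % _MOD)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % _MOD)


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))
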
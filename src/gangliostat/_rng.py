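"""Deterministic per-component random substreams.

Every stochastic stage takes one top-level integer seed.  Components derive
independent generators by hashing their name into the seed sequence, so adding
a new component never perturbs the stream of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, component: str) -> np.random.Generator:
    """Return a Generator for *component* derived from the top-level *seed*.

    The component name is hashed with CRC-32 (stable across processes and
    Python versions, unlike ``hash()``), and the pair (seed, crc) seeds a
    ``numpy.random.SeedSequence``.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    crc = zlib.crc32(component.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), crc]))
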
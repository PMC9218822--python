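"""Robust location/spread statistics used throughout the pipeline.

The spread estimator everywhere is the consistency-scaled median absolute
deviation (MADe), ``1.4826 * median(|x - median(x)|)``, which estimates the
standard deviation under normality while being insensitive to the heavy
upper tail of linker- and match-length distributions.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

MADE_SCALE = 1.4826


def made(values: Sequence[float]) -> float:
    """Consistency-scaled median absolute deviation of ``values``."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("MADe is undefined for an empty sample")
    return MADE_SCALE * float(np.median(np.abs(x - np.median(x))))


def median(values: Sequence[float]) -> float:
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("median of an empty sample")
    return float(np.median(x))


def stable_seed(base_seed: int, *tokens: str | int) -> int:
    """Derive a reproducible 31-bit sub-seed from a base seed and tokens.

    Used to give every (profile, sequence) pair its own shuffle null while
    keeping the whole run a pure function of one seed.
    """
    import zlib

    h = zlib.crc32(repr(tokens).encode())
    return (int(base_seed) * 1_000_003 + h) % (2**31 - 1)
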
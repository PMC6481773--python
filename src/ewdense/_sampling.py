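"""Vectorized without-replacement subset sampling for permutation nulls.

Every permutation null in the pipeline (module significance, Monte-Carlo
score standardization, nominal-gene overrepresentation) reduces to the same
primitive: draw ``b`` independent subsets of ``size`` distinct elements from
a value vector and return each subset's sum.  Two strategies are used:

* rejection sampling with replacement when the birthday-collision bound
  ``size**2 / (2 n)`` is small, redrawing only rows that contain duplicates;
* chunked random-key ``argpartition`` otherwise (assign each element a
  uniform key, keep the ``size`` smallest), which is exact uniform sampling
  at O(n) per draw with bounded memory.
"""

from __future__ import annotations

import numpy as np

__all__ = ["subset_sums", "spawn_rng"]

# keys matrix is capped at ~16 MB per chunk
_CHUNK_FLOATS = 2_000_000


def subset_sums(
    values: np.ndarray, size: int, b: int, rng: np.random.Generator
) -> np.ndarray:
    """Sums of ``b`` uniform without-replacement subsets of ``values``.

    Parameters
    ----------
    values
        1-D array to sample from.
    size
        Subset cardinality; ``0 <= size <= len(values)``.
    b
        Number of independent subsets.
    rng
        Source of randomness.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if size < 0 or size > n:
        raise ValueError(f"subset size {size} outside [0, {n}]")
    if b < 1:
        raise ValueError("number of draws must be >= 1")
    if size == 0:
        return np.zeros(b)
    if size == n:
        return np.full(b, values.sum())
    if size * size <= n // 4:
        return _rejection_sums(values, size, b, rng)
    return _argpartition_sums(values, size, b, rng)


def _rejection_sums(values, size, b, rng):
    n = values.size
    idx = rng.integers(0, n, size=(b, size))
    if size > 1:
        srt = np.sort(idx, axis=1)
        bad = (np.diff(srt, axis=1) == 0).any(axis=1)
        while bad.any():
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), size))
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
    return values[idx].sum(axis=1)


def _argpartition_sums(values, size, b, rng):
    n = values.size
    out = np.empty(b)
    chunk = max(1, _CHUNK_FLOATS // n)
    for lo in range(0, b, chunk):
        hi = min(lo + chunk, b)
        keys = rng.random((hi - lo, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        out[lo:hi] = values[idx].sum(axis=1)
    return out


def spawn_rng(seed: int, *stream: int | str) -> np.random.Generator:
    """Named independent substream of the pipeline-wide seed.

    String tags are hashed onto small integers so that every stage draws
    from its own reproducible stream of a single user-facing seed.
    """
    key = [int(seed)]
    for s in stream:
        if isinstance(s, str):
            key.append(sum(ord(c) * (i + 1) for i, c in enumerate(s)) % (2**20))
        else:
            key.append(int(s))
    return np.random.default_rng(key)
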
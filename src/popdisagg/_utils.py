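"""Small shared helpers: seeding and array conveniences."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, *names) -> int:
    """Deterministic sub-seed from a global seed and a label chain.

    One global seed fans out to independent per-module streams so every
    component is reproducible in isolation. Result is < 2**31.
    """
    label = ":".join(str(n) for n in names)
    h = zlib.crc32(label.encode("utf8"), int(seed) & 0xFFFFFFFF)
    return int(h & 0x7FFFFFFF)


def rng_for(seed: int, *names) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *names))


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=np.float64)
    return np.logaddexp(0.0, x)


def region_sums(values_flat: np.ndarray, ids_flat: np.ndarray, region_ids: np.ndarray) -> np.ndarray:
    """Sum ``values_flat`` per region id, returned in ``region_ids`` order."""
    if len(region_ids) == 0:
        return np.zeros(0)
    maxid = max(int(ids_flat.max(initial=0)), int(region_ids.max()))
    sums = np.bincount(ids_flat, weights=values_flat, minlength=maxid + 1)
    return sums[np.asarray(region_ids, dtype=np.int64)]
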
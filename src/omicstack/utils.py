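"""Small shared numerics."""

from __future__ import annotations

import numpy as np


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant vector maps to all 0.5 by convention."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("minmax_normalize: empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("minmax_normalize: non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)
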
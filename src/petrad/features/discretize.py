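"""Fixed-bin-width gray-level discretization."""

from __future__ import annotations

import numpy as np

__all__ = ["discretize"]


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Map intensities to integer gray levels ``1..Ng`` with fixed bin width.

    ``level(x) = floor(x / W) - floor(min / W) + 1``; the minimum is taken over
    the input, so levels always start at 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty array")
    lo = np.floor(values.min() / bin_width)
    return (np.floor(values / bin_width) - lo + 1).astype(np.int64)
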
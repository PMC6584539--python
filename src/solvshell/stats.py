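"""Small statistical helpers shared across analyses."""

from __future__ import annotations

import numpy as np


def block_standard_error(x: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean from block averaging.

    The series is split into ``n_blocks`` equal contiguous blocks; the
    spread of block means estimates the error including short-range
    correlation. Falls back to the naive SE when the series is shorter
    than the block count.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return float("nan")
    if n < n_blocks:
        return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    m = n // n_blocks
    blocks = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))
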
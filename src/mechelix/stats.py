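"""Small statistical helpers for correlated time series."""

from __future__ import annotations

import numpy as np

__all__ = ["blocked_sem"]


def blocked_sem(x: np.ndarray, n_blocks: int = 50) -> float:
    """Standard error of the mean of a correlated series by block averaging.

    The series is cut into ``n_blocks`` contiguous blocks; the SEM of the
    block means is robust to autocorrelation shorter than a block.
    """
    x = np.asarray(x, float)
    n_blocks = min(n_blocks, len(x))
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    usable = (len(x) // n_blocks) * n_blocks
    means = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))
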
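"""Reblocking analysis for serially correlated Monte-Carlo series.

Repeatedly averages neighbouring pairs; at each level the naive standard
error of the blocked means is recorded.  The plateau (the level at which
blocks are long compared to the autocorrelation time) is detected with the
block-size criterion ``B^3 >= 2 N (se_B^2 / se_1^2)^2``; the standard error at
that level is the reported error bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockLevel", "reblock", "blocking_error", "ratio_estimate"]

MIN_LENGTH = 32


@dataclass(frozen=True)
class BlockLevel:
    block_size: int
    n_blocks: int
    mean: float
    std_err: float
    std_err_err: float


def reblock(series) -> list[BlockLevel]:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < MIN_LENGTH:
        raise ValueError(f"series must be 1-D with at least {MIN_LENGTH} points")
    levels = []
    size = 1
    while x.size >= 2:
        n = x.size
        se = float(x.std(ddof=1) / np.sqrt(n))
        levels.append(BlockLevel(
            block_size=size, n_blocks=n, mean=float(x.mean()), std_err=se,
            std_err_err=se / np.sqrt(2.0 * (n - 1)),
        ))
        if n % 2 == 1:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
        size *= 2
    return levels


def _optimal_level(levels: list[BlockLevel], n_total: int) -> int:
    se0 = levels[0].std_err
    if se0 == 0.0:
        return 0
    for k, lv in enumerate(levels):
        ratio = (lv.std_err / se0) ** 2
        if lv.block_size ** 3 >= 2.0 * n_total * ratio * ratio:
            return k
    # No plateau within the data: the series is short relative to its
    # correlation time and every level underestimates.  Report the largest
    # error among well-populated levels — conservative rather than optimistic.
    candidates = [k for k in range(len(levels)) if levels[k].n_blocks >= 8]
    if not candidates:
        return len(levels) - 1
    return max(candidates, key=lambda k: levels[k].std_err)


def blocking_error(series) -> float:
    """Plateau standard error of the mean of a correlated series."""
    x = np.asarray(series, dtype=float)
    levels = reblock(x)
    k = _optimal_level(levels, x.size)
    return levels[k].std_err


def ratio_estimate(num, den) -> tuple[float, float]:
    """Estimate ``mean(num)/mean(den)`` with a reblocked error bar.

    Uses the delta method: the fluctuation series ``t_i = num_i - f den_i``
    has ``mean(t) = 0`` and ``se(f) = se(mean(t)) / |mean(den)|``, so the
    serial correlation of the ratio is handled by a single reblocking of
    ``t``.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if num.size != den.size:
        raise ValueError("series length mismatch")
    dbar = den.mean()
    if dbar == 0.0:
        raise ValueError("denominator series has zero mean")
    f = num.mean() / dbar
    t = num - f * den
    if np.all(t == 0.0):
        return float(f), 0.0
    err = blocking_error(t) / abs(dbar)
    return float(f), float(err)
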
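"""Genomic islands of divergence from kernel-smoothed windowed Dxy.

The observed windowed Dxy series is smoothed with a Gaussian
Nadaraya-Watson kernel.  The null is built by permuting the order of the
window values over the same positions many times, smoothing each
permutation, and taking the single most extreme smoothed value anywhere in
any permutation as the significance threshold -- the most conservative
max-null reading.  Islands are maximal runs of window midpoints whose
observed smoothed value strictly exceeds that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IslandCall:
    chrom: str
    start_bp: int
    end_bp: int
    peak: float
    threshold: float
    n_permutations: int
    seed: int


def _kernel_weights(positions: np.ndarray, bandwidth_bp: float) -> np.ndarray:
    """Gaussian kernel matrix K[i, j] = exp(-(x_i - x_j)^2 / 2h^2)."""
    x = np.asarray(positions, dtype=float)
    dd = x[:, None] - x[None, :]
    return np.exp(-0.5 * (dd / bandwidth_bp) ** 2)


def kernel_smooth(positions, values, bandwidth_bp: float) -> np.ndarray:
    """Nadaraya-Watson estimate at each position; missing (NaN) values get
    weight zero.  Raises on non-positive bandwidth or all-missing input."""
    if bandwidth_bp <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth_bp}")
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("all window values are missing; nothing to smooth")
    K = _kernel_weights(positions, bandwidth_bp)
    num = K @ np.where(ok, v, 0.0)
    den = K @ ok.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def island_permutation_test(
    windows: pd.DataFrame,
    value_col: str = "dxy",
    n_perm: int = 10_000,
    bandwidth_bp: float = 50_000.0,
    seed: int = 0,
) -> tuple[dict, list[IslandCall]]:
    """Permutation max-null island test, per chromosome.

    ``windows`` needs columns (chrom, start, end, value_col).  Returns a
    {chrom: threshold} dict and the island calls; deterministic under
    ``seed``.  By the max-null construction the family-wise chance of any
    island on exchangeable data is about 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    thresholds: dict = {}
    calls: list[IslandCall] = []
    for c in dict.fromkeys(windows.chrom):
        sub = windows[windows.chrom == c]
        mid = ((sub.start + sub.end) / 2.0).to_numpy()
        vals = sub[value_col].to_numpy(dtype=float)
        smoothed = kernel_smooth(mid, vals, bandwidth_bp)

        K = _kernel_weights(mid, bandwidth_bp)
        # permute the order of the values over the same positions
        perm_cols = np.stack([rng.permutation(vals) for _ in range(n_perm)], axis=1)
        ok = np.isfinite(perm_cols)
        num = K @ np.where(ok, perm_cols, 0.0)
        den = K @ ok.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_smoothed = np.where(den > 0, num / den, -np.inf)
        threshold = float(np.nanmax(perm_smoothed))
        thresholds[c] = threshold

        above = np.isfinite(smoothed) & (smoothed > threshold)
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                calls.append(
                    IslandCall(
                        chrom=str(c),
                        start_bp=int(starts[i]),
                        end_bp=int(ends[j]),
                        peak=float(np.max(smoothed[i : j + 1])),
                        threshold=threshold,
                        n_permutations=n_perm,
                        seed=seed,
                    )
                )
                i = j + 1
            else:
                i += 1
    return thresholds, calls
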
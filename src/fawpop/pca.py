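"""Principal-component analysis of the genotype matrix, smartPCA-style.

Sites are normalized as (g - 2*p_hat) / sqrt(p_hat * (1 - p_hat)) with the
shrunk frequency p_hat = (1 + sum g) / (2 + 2*n_called); missing entries
are set to 0 after centering and monomorphic sites are dropped.  The top-k
components come from the exact eigendecomposition of the sample covariance
of the normalized matrix, so results are deterministic up to the sign of
each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING
from .popstats import wc_fst


def patterson_normalize(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (n_samples, n_kept_sites) matrix and the kept site index."""
    d = gm.dosage.astype(float)
    called = gm.dosage != MISSING
    n_obs = called.sum(axis=0)
    g_sum = np.where(called, d, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (1.0 + g_sum) / (2.0 + 2.0 * n_obs)
    # monomorphic among called genotypes -> zero variance -> dropped
    mono = np.array([
        len(np.unique(gm.dosage[called[:, j], j])) <= 1 if n_obs[j] else True
        for j in range(gm.n_sites)
    ])
    keep = np.nonzero(~mono & (n_obs > 0))[0]
    p = p[keep]
    x = (d[:, keep] - 2.0 * p[None, :]) / np.sqrt(p * (1.0 - p))[None, :]
    x = np.where(called[:, keep], x, 0.0)
    return x, keep


@dataclass
class PCAResult:
    coords: pd.DataFrame        # sample + PC1..PCk
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    dataset: str


def pca(gm_or_matrix, k: int = 10, dataset: str = "all", samples=None) -> PCAResult:
    """Top-k PCA of a genotype matrix (or a pre-normalized array)."""
    if isinstance(gm_or_matrix, GenotypeMatrix):
        x, _ = patterson_normalize(gm_or_matrix)
        samples = gm_or_matrix.samples
    else:
        x = np.asarray(gm_or_matrix, dtype=float)
        if samples is None:
            samples = np.array([f"s{i}" for i in range(x.shape[0])], dtype=object)
    n = x.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n - 1}")
    cov = (x @ x.T) / max(1, x.shape[1])
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    total = max(evals.sum(), np.finfo(float).tiny)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))[None, :]
    frame = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "sample", list(samples))
    return PCAResult(
        coords=frame,
        eigenvalues=evals[:k],
        pct_variance=100.0 * evals[:k] / total,
        dataset=dataset,
    )


def pairwise_group_fst(gm: GenotypeMatrix, grouping: dict) -> pd.DataFrame:
    """Weighted Weir-Cockerham Fst for every pair of a-priori groups.

    Pairs involving a group with fewer than 2 samples are reported
    missing.  Returns a symmetric table."""
    labels = sorted(grouping)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    table = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, la in enumerate(labels):
        table.loc[la, la] = 0.0
        for lb in labels[i + 1 :]:
            if len(grouping[la]) < 2 or len(grouping[lb]) < 2:
                continue
            fst = wc_fst(gm, grouping[la], grouping[lb], window_bp=None).weighted
            table.loc[la, lb] = fst
            table.loc[lb, la] = fst
    return table
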
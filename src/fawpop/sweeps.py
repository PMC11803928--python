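"""Selective-sweep scans: an SFS composite-likelihood-ratio (CLR) scan and
an omega-statistic LD scan.

CLR scan
--------
A hitchhiking model in the star-tree approximation is contrasted against
the genome-wide background site-frequency spectrum.  At a candidate sweep
position x, a lineage at distance d escapes the sweep with probability
p_e = 1 - exp(-alpha * d).  Conditional on k of the n sampled lineages
escaping, the k escapees plus the single sweeping ancestor form a sample
of k+1 from the background spectrum; the ancestor's allele is then copied
into the n-k swept lineages.  At p_e = 1 this reduces exactly to the
background spectrum, so the model nests the null and the per-site
log-ratio is 0 in the all-escape limit.

The background spectrum is estimated genome-wide with hypergeometric
projection to a common allele count n and, deliberately, includes the
group-monomorphic classes (counts 0 and n): sites that segregate in the
full cohort but are fixed within the scanned population carry the local
loss-of-diversity signal a completed hard sweep leaves in SNP-only data.
``BackgroundSFS.spectrum`` exposes the conventional folded polymorphic
spectrum phi(j), j = 1..floor(n/2).

alpha is maximized over a fixed logarithmic ladder (deterministic and
testable), and per-site likelihoods are binned over alpha*d so each scan
is a handful of matrix products plus searchsorted range sums.

omega scan
----------
For each 5 kb evaluation window the SNPs are split into a left and right
block around each inter-SNP boundary; omega is the ratio of mean within-
block r^2 to mean between-block r^2, maximized over splits and over block
extents between ``minwin`` and ``maxwin`` bp.  Run on autosomes only:
Z-chromosome LD is globally elevated in the pooled cohort, so an LD scan
there would be dominated by false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AUTOSOMES, GenotypeMatrix, MISSING

OMEGA_CAP = 1e6  # declared ceiling when between-block r^2 sums to zero

DEFAULT_ALPHAS = tuple(np.logspace(-7.0, -2.0, 16))

# alpha*d bins for the composite likelihood; beyond the last edge the
# per-site log-ratio is 0 to numerical precision (all lineages escape)
_AD_EDGES = np.logspace(np.log10(1e-4), np.log10(25.0), 49)


@dataclass
class BackgroundSFS:
    """Genome-wide background spectrum at projection size n.

    ``phi_full`` has length n+1 and includes the group-monomorphic mass;
    it is symmetric when folded.  ``spectrum`` is the normalized folded
    polymorphic spectrum phi(j), j = 1..floor(n/2).
    """

    n: int
    phi_full: np.ndarray
    folded: bool = True

    @property
    def spectrum(self) -> np.ndarray:
        poly = self.phi_full[1:-1]
        if self.folded:
            half = self.n // 2
            folded = np.array(
                [poly[j - 1] + (poly[self.n - j - 1] if j != self.n - j else 0.0)
                 for j in range(1, half + 1)]
            )
            s = folded.sum()
            return folded / s if s > 0 else folded
        s = poly.sum()
        return poly / s if s > 0 else poly


def projection_weights(m: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Hypergeometric projection of sites with m called alleles (b of them
    ALT) down to n alleles: rows are distributions over counts 0..n."""
    j = np.arange(n + 1)
    return stats.hypergeom.pmf(j[None, :], np.asarray(m)[:, None], np.asarray(b)[:, None], n)


def _site_counts(gm: GenotypeMatrix, idx: np.ndarray):
    d = gm.dosage[idx]
    called = d != MISSING
    m = 2 * called.sum(axis=0).astype(np.int64)
    b = np.where(called, d, 0).sum(axis=0).astype(np.int64)
    return m, b


def background_sfs(
    gm: GenotypeMatrix,
    group,
    folded: bool = True,
    n_proj: int | None = None,
) -> BackgroundSFS:
    """Estimate the background SFS over all sites genome-wide.

    Sites with fewer called alleles than the projection size are skipped.
    ``n_proj`` defaults to the most common called-allele count."""
    idx = gm.sample_indices(group)
    m, b = _site_counts(gm, idx)
    usable = m >= 4
    if not usable.any():
        raise ValueError("fewer than 4 observed alleles at every site")
    if n_proj is None:
        counts = np.bincount(m[usable])
        n_proj = int(np.argmax(counts))
    ok = m >= n_proj
    W = projection_weights(m[ok], b[ok], n_proj)
    phi = W.sum(axis=0)
    if folded:
        phi = 0.5 * (phi + phi[::-1])
    phi = phi / phi.sum()
    return BackgroundSFS(n=n_proj, phi_full=phi, folded=folded)


def _sweep_tables(sfs: BackgroundSFS) -> np.ndarray:
    """T[k, b]: probability of count b given k of n lineages escaped."""
    n = sfs.n
    phi = sfs.phi_full
    T = np.zeros((n + 1, n + 1))
    T[n] = phi  # every lineage escaped: background exactly
    j = np.arange(n + 1)
    for k in range(n):
        size = k + 1
        # k escapees + the sweeping ancestor: a background sample of k+1
        psi = (stats.hypergeom.pmf(np.arange(size + 1)[None, :], n, j[:, None], size) * phi[:, None]).sum(axis=0)
        jp = np.arange(size + 1)
        p_anc_derived = jp / size
        # ancestor carries the derived allele -> its n-k copies do too
        for jj in jp:
            if psi[jj] == 0:
                continue
            b_yes = jj - 1 + (n - k)
            T[k, b_yes] += psi[jj] * p_anc_derived[jj]
            T[k, jj] += psi[jj] * (1.0 - p_anc_derived[jj])
    return T


def clr_scan(
    gm: GenotypeMatrix,
    group,
    grid_bp: int = 5_000,
    chroms=None,
    sfs: BackgroundSFS | None = None,
    alphas=DEFAULT_ALPHAS,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Composite-likelihood-ratio scan on a grid of floor(length/grid_bp)
    evenly spaced points per chromosome.

    Returns a frame (chrom, pos, clr, alpha); CLR is floored at 0 and the
    reported alpha is the maximizing ladder value.
    """
    if sfs is None:
        sfs = background_sfs(gm, group)
    n = sfs.n
    idx = gm.sample_indices(group)
    T = _sweep_tables(sfs)
    lengths = chrom_lengths or gm.metadata.get("chrom_lengths", {})
    if chroms is None:
        chroms = list(dict.fromkeys(gm.chrom))

    alphas = np.asarray(alphas, dtype=float)
    edges = _AD_EDGES
    nb = len(edges) - 1
    centers = np.sqrt(edges[:-1] * edges[1:])
    p_e = 1.0 - np.exp(-centers)
    M = stats.binom.pmf(np.arange(n + 1)[None, :], n, p_e[:, None])  # (nb, n+1)
    Ptable = M @ T                                                   # (nb, n+1)

    out_rows = []
    for c in chroms:
        c = str(c)
        on = np.nonzero(gm.chrom == c)[0]
        if len(on) == 0:
            continue
        m, b = _site_counts_sub(gm, idx, on)
        ok = m >= n
        pos = gm.pos[on][ok].astype(float)
        if len(pos) == 0:
            continue
        W = projection_weights(m[ok], b[ok], n)
        L0 = W @ sfs.phi_full
        good = L0 > 0
        pos, W, L0 = pos[good], W[good], L0[good]
        logL0 = np.log(L0)

        length = float(lengths.get(c, gm.pos[on].max()))
        n_grid = int(length // grid_bp)
        if n_grid < 1:
            continue
        x = (np.arange(n_grid) + 0.5) * (length / n_grid)

        l1 = W @ Ptable.T                       # (ms, nb)
        with np.errstate(divide="ignore"):
            lr = np.log(np.maximum(l1, 1e-300)) - logL0[:, None]
        P = np.vstack([np.zeros(nb), np.cumsum(lr, axis=0)])  # (ms+1, nb)

        best = np.full(n_grid, -np.inf)
        best_a = np.zeros(n_grid)
        for a in alphas:
            total = np.zeros(n_grid)
            d_edges = edges / a
            for bi in range(nb):
                d_lo = 0.0 if bi == 0 else d_edges[bi]
                d_hi = d_edges[bi + 1]
                col = P[:, bi]
                lo = np.searchsorted(pos, x + d_lo, side="right")
                hi = np.searchsorted(pos, x + d_hi, side="right")
                total += col[hi] - col[lo]
                lo2 = np.searchsorted(pos, x - d_hi, side="left")
                hi2 = np.searchsorted(pos, x - d_lo, side="left")
                total += col[hi2] - col[lo2]
            upd = total > best
            best[upd] = total[upd]
            best_a[upd] = a
        clr = np.maximum(best, 0.0)
        out_rows.append(pd.DataFrame({"chrom": c, "pos": x, "clr": clr, "alpha": best_a}))

    if not out_rows:
        return pd.DataFrame(columns=["chrom", "pos", "clr", "alpha"])
    out = pd.concat(out_rows, ignore_index=True)
    out.attrs["grid_bp"] = grid_bp
    out.attrs["n_proj"] = n
    return out


def _site_counts_sub(gm: GenotypeMatrix, idx: np.ndarray, site_idx: np.ndarray):
    d = gm.dosage[np.ix_(idx, site_idx)]
    called = d != MISSING
    m = 2 * called.sum(axis=0).astype(np.int64)
    b = np.where(called, d, 0).sum(axis=0).astype(np.int64)
    return m, b


def find_clr_outliers(grid: pd.DataFrame, percentile: float = 99.99) -> tuple[float, pd.DataFrame]:
    """Outlier grid points at the pooled empirical percentile.

    Degenerate grids (all CLR equal) yield no outliers.  Returns
    (threshold, outlier rows)."""
    v = grid.clr.to_numpy(dtype=float)
    if len(v) < 10_000:
        warnings.warn(f"only {len(v)} grid points pooled; the {percentile}th "
                      "percentile is poorly resolved")
    if len(v) == 0 or v.max() == v.min():
        return float("nan"), grid.iloc[0:0]
    thr = float(np.percentile(v, percentile))
    return thr, grid[grid.clr >= thr]


@dataclass
class SweepRegion:
    population: str
    chrom: str
    focal_pos: float
    start: int
    end: int
    peak_clr: float
    outlier_percentile: float
    region_percentile: float


def refine_sweep_region(
    gm: GenotypeMatrix,
    group,
    chrom: str,
    outlier_pos: float,
    fine_bp: int = 1_000,
    region_percentile: float = 99.0,
    population: str = "",
    sfs: BackgroundSFS | None = None,
    outlier_percentile: float = 99.99,
    **scan_kwargs,
) -> SweepRegion | None:
    """Delineate a sweep around an outlier on a 1 kb fine grid.

    The region is the maximal run of consecutive fine windows containing
    the outlier whose CLR is at or above the chromosome's
    ``region_percentile`` fine-grid CLR.  Returns None (with a warning)
    when the outlier is not elevated on the fine grid.
    """
    fine = clr_scan(gm, group, grid_bp=fine_bp, chroms=[chrom], sfs=sfs, **scan_kwargs)
    if len(fine) == 0:
        return None
    v = fine.clr.to_numpy()
    thr = np.percentile(v, region_percentile)
    elevated = v >= thr
    i0 = int(np.argmin(np.abs(fine.pos.to_numpy() - outlier_pos)))
    if not elevated[i0] or v.max() == v.min():
        warnings.warn(f"outlier at {chrom}:{outlier_pos:.0f} not elevated on the fine grid")
        return None
    lo = i0
    while lo > 0 and elevated[lo - 1]:
        lo -= 1
    hi = i0
    while hi + 1 < len(elevated) and elevated[hi + 1]:
        hi += 1
    spacing = fine.pos.iloc[1] - fine.pos.iloc[0] if len(fine) > 1 else fine_bp
    start = int(fine.pos.iloc[lo] - spacing / 2)
    end = int(fine.pos.iloc[hi] + spacing / 2)
    return SweepRegion(
        population=population,
        chrom=str(chrom),
        focal_pos=float(outlier_pos),
        start=start,
        end=end,
        peak_clr=float(v[lo : hi + 1].max()),
        outlier_percentile=outlier_percentile,
        region_percentile=region_percentile,
    )


# ---------------------------------------------------------------------
# omega statistic

def _omega_window(r2: np.ndarray, pos: np.ndarray, minwin: float, maxwin: float,
                  n_extents: int, cap: float) -> float:
    W = len(pos)
    if W < 4:
        return float("nan")
    valid = np.isfinite(r2)
    extents = np.linspace(minwin, maxwin, n_extents)
    best = np.nan
    for split in range(2, W - 1):
        boundary = 0.5 * (pos[split - 1] + pos[split])
        for e in extents:
            left = np.nonzero((np.arange(W) < split) & (pos > boundary - e))[0]
            right = np.nonzero((np.arange(W) >= split) & (pos <= boundary + e))[0]
            if len(left) < 2 or len(right) < 2:
                continue
            rl = r2[np.ix_(left, left)]
            rr = r2[np.ix_(right, right)]
            rb = r2[np.ix_(left, right)]
            vl = valid[np.ix_(left, left)]
            vr = valid[np.ix_(right, right)]
            vb = valid[np.ix_(left, right)]
            n_within = vl.sum() / 2 + vr.sum() / 2
            n_between = vb.sum()
            if n_within == 0 or n_between == 0:
                continue
            within = (np.nansum(np.where(vl, rl, 0.0)) / 2 + np.nansum(np.where(vr, rr, 0.0)) / 2) / n_within
            between = np.nansum(np.where(vb, rb, 0.0)) / n_between
            omega = cap if between == 0 else within / between
            omega = min(omega, cap)
            if not np.isfinite(best) or omega > best:
                best = omega
    return best


def omega_scan(
    gm: GenotypeMatrix,
    group,
    chroms=None,
    window_bp: int = 5_000,
    minwin: float = 500.0,
    maxwin: float = 2_500.0,
    n_extents: int = 5,
    cap: float = OMEGA_CAP,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Per-window omega on the autosomes (Z excluded by default)."""
    from .popstats import r2_matrix

    idx = gm.sample_indices(group)
    lengths = chrom_lengths or gm.metadata.get("chrom_lengths", {})
    if chroms is None:
        present = list(dict.fromkeys(gm.chrom))
        chroms = [c for c in present if c in AUTOSOMES]
    rows = []
    for c in chroms:
        c = str(c)
        if c not in AUTOSOMES:
            raise ValueError(f"omega scan is autosome-only; got chromosome {c!r}")
        on = np.nonzero(gm.chrom == c)[0]
        if len(on) == 0:
            continue
        pos = gm.pos[on]
        length = int(lengths.get(c, pos.max()))
        n_win = max(1, length // window_bp)
        for w in range(n_win):
            start, end = w * window_bp, (w + 1) * window_bp
            inwin = on[(pos > start) & (pos <= end)]
            if len(inwin) < 4:
                rows.append({"chrom": c, "start": start, "end": end, "omega": np.nan,
                             "n_snps": int(len(inwin))})
                continue
            sub = gm.dosage[np.ix_(idx, inwin)]
            r2 = r2_matrix(sub)
            om = _omega_window(r2, gm.pos[inwin].astype(float), minwin, maxwin, n_extents, cap)
            rows.append({"chrom": c, "start": start, "end": end, "omega": om,
                         "n_snps": int(len(inwin))})
    return pd.DataFrame(rows)
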
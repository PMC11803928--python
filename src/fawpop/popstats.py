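"""Windowed population-genetic statistics.

* Weir & Cockerham (1984) theta at each SNP and as a ratio-of-sums
  ("weighted") estimate over 10 kb windows and genome-wide,
* nucleotide diversity pi and between-group Dxy with invariant-site-aware
  denominators (sum of per-site differences over sum of per-site
  comparisons, the convention of invariant-site-aware Dxy tools),
* Tajima's D in 5 kb windows,
* LD decay: genotype-dosage r^2 averaged within eleven fixed distance
  bins (+/- 50 bp).

Windows are non-overlapping tiles of the configured width anchored at
position 0, half-open [start, end) in 0-based coordinates; a 1-based site
at position P falls in window floor((P-1)/width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING

LD_BIN_DISTANCES = (100, 250, 500, 1000, 2500, 5000, 7500, 10000, 25000, 50000, 75000)
LD_BIN_TOL = 50


# ---------------------------------------------------------------------
# helpers

def _window_index(pos: np.ndarray, width: int) -> np.ndarray:
    return (pos - 1) // width


def _window_frame(chrom, pos, width, values, extras, chrom_lengths=None):
    """Assemble tiled windows per chromosome, including empty tiles up to
    the last site (or the declared chromosome length)."""
    if len(pos) == 0:
        cols = ["chrom", "start", "end", *values, *extras]
        return pd.DataFrame(columns=cols)
    rows = []
    df = pd.DataFrame({"chrom": chrom, "win": _window_index(pos, width)})
    for c in dict.fromkeys(chrom):
        on = df.chrom == c
        length = None if chrom_lengths is None else chrom_lengths.get(str(c))
        last = (length - 1) // width if length else int(df.win[on].max())
        for w in range(last + 1):
            rows.append({"chrom": c, "start": w * width, "end": (w + 1) * width})
    out = pd.DataFrame(rows)
    out["key"] = list(zip(out.chrom, out.start // width))
    keys = [np.asarray(chrom, dtype=object), _window_index(pos, width)]
    for name, v in values.items():
        agg = pd.Series(np.asarray(v, dtype=float)).groupby(keys).sum()
        out[name] = [float(agg.get(k, 0.0)) for k in out.key]
    for name, v in extras.items():
        agg = pd.Series(np.asarray(v)).groupby(keys).sum()
        out[name] = [int(agg.get(k, 0)) for k in out.key]
    return out.drop(columns="key")


def group_freq_stats(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-site (n genotyped, ALT frequency, observed het fraction) for a
    sample subset."""
    d = gm.dosage[idx]
    called = d != MISSING
    n = called.sum(axis=0).astype(np.int64)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, ((d == 1) & called).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


# ---------------------------------------------------------------------
# Weir & Cockerham Fst

@dataclass
class FstResult:
    per_site: pd.DataFrame          # chrom, pos, a, abc, theta
    windows: pd.DataFrame | None    # chrom, start, end, fst, n_sites
    weighted: float                 # ratio-of-sums over all usable sites


def wc_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) two-population variance components per site.

    Returns (a, b, c) arrays; sites with insufficient data yield NaN."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst(
    gm: GenotypeMatrix,
    group_a,
    group_b,
    window_bp: int | None = 10_000,
    chrom_lengths: dict | None = None,
) -> FstResult:
    """Per-SNP and windowed Weir-Cockerham theta between two groups.

    The window and global estimates are ratio-of-sums (sum a over sum
    a+b+c), never a mean of per-site ratios.  Sites where a+b+c = 0 are
    skipped and counted out.
    """
    ia, ib = gm.sample_indices(group_a), gm.sample_indices(group_b)
    n1, p1, h1 = group_freq_stats(gm, ia)
    n2, p2, h2 = group_freq_stats(gm, ib)
    a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
    abc = a + b + c
    usable = np.isfinite(abc) & (abc != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(usable, a / abc, np.nan)

    per_site = pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos, "a": a, "abc": abc, "theta": theta}
    )
    a_u = np.where(usable, a, 0.0)
    abc_u = np.where(usable, abc, 0.0)
    weighted = float(a_u.sum() / abc_u.sum()) if abc_u.sum() != 0 else float("nan")

    windows = None
    if window_bp is not None:
        w = _window_frame(
            gm.chrom, gm.pos, window_bp,
            values={"sum_a": a_u, "sum_abc": abc_u},
            extras={"n_sites": usable.astype(int)},
            chrom_lengths=chrom_lengths,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            w["fst"] = np.where(w.sum_abc != 0, w.sum_a / w.sum_abc, np.nan)
        windows = w.drop(columns=["sum_a", "sum_abc"])
    return FstResult(per_site=per_site, windows=windows, weighted=weighted)


# ---------------------------------------------------------------------
# pi / Dxy with invariant-site denominators

def site_diffs_comps_within(gm: GenotypeMatrix, idx: np.ndarray):
    """Per-site (pairwise differences, pairwise comparisons) within a
    group: with m called alleles of which c1 are ALT, diffs = c0*c1 and
    comps = m(m-1)/2.  Invariant genotyped sites contribute comps only."""
    d = gm.dosage[idx]
    called = d != MISSING
    m = 2 * called.sum(axis=0).astype(np.int64)
    c1 = np.where(called, d, 0).sum(axis=0).astype(np.int64)
    diffs = c1 * (m - c1)
    comps = m * (m - 1) // 2
    return diffs.astype(float), comps.astype(float), m


def pi_windowed(
    gm: GenotypeMatrix,
    group,
    window_bp: int = 5_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per window: sum(diffs)/sum(comps) over all
    genotyped sites in the window.  Windows with zero comparisons are
    reported with a missing value."""
    idx = gm.sample_indices(group)
    diffs, comps, _ = site_diffs_comps_within(gm, idx)
    w = _window_frame(
        gm.chrom, gm.pos, window_bp,
        values={"sum_diffs": diffs, "sum_comps": comps},
        extras={"n_sites": (comps > 0).astype(int)},
        chrom_lengths=chrom_lengths,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w["pi"] = np.where(w.sum_comps > 0, w.sum_diffs / w.sum_comps, np.nan)
    w["n_comparisons"] = w.sum_comps
    return w.drop(columns=["sum_diffs", "sum_comps"])


def dxy_windowed(
    gm: GenotypeMatrix,
    group_a,
    group_b,
    window_bp: int = 10_000,
    site_missing_max: float = 0.2,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Between-group Dxy per window with invariant-site denominators.

    Sites with more than ``site_missing_max`` missing genotypes (over the
    two groups' samples) are excluded before computation."""
    ia, ib = gm.sample_indices(group_a), gm.sample_indices(group_b)
    both = np.concatenate([ia, ib])
    frac = gm.site_missing_fraction(both)
    ok = frac <= site_missing_max

    da, db = gm.dosage[ia], gm.dosage[ib]
    ca, cb = da != MISSING, db != MISSING
    mA = 2 * ca.sum(axis=0).astype(np.int64)
    mB = 2 * cb.sum(axis=0).astype(np.int64)
    c1A = np.where(ca, da, 0).sum(axis=0).astype(np.int64)
    c1B = np.where(cb, db, 0).sum(axis=0).astype(np.int64)
    diffs = (c1A * (mB - c1B) + (mA - c1A) * c1B).astype(float)
    comps = (mA * mB).astype(float)
    diffs[~ok] = 0.0
    comps[~ok] = 0.0

    w = _window_frame(
        gm.chrom, gm.pos, window_bp,
        values={"sum_diffs": diffs, "sum_comps": comps},
        extras={"n_sites": ((comps > 0) & ok).astype(int)},
        chrom_lengths=chrom_lengths,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w["dxy"] = np.where(w.sum_comps > 0, w.sum_diffs / w.sum_comps, np.nan)
    w["n_comparisons"] = w.sum_comps
    return w.drop(columns=["sum_diffs", "sum_comps"])


# ---------------------------------------------------------------------
# Tajima's D

def tajima_constants(n: int) -> dict:
    """The standard a1..e2 constants at sample size n (alleles)."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_hat: float, S: int, n: int) -> float:
    """Tajima's D from window pairwise diversity, segregating sites and
    effective allele count; NaN where undefined."""
    if S <= 0 or n < 4:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_hat - S / k["a1"]) / np.sqrt(var))


def tajimas_d_windowed(
    gm: GenotypeMatrix,
    group,
    window_bp: int = 5_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Windowed Tajima's D.

    Missing data make the allele count site-specific; the single n the
    formula needs is taken as the median called-allele count over the
    window's segregating sites.  Windows with S = 0 are missing."""
    idx = gm.sample_indices(group)
    diffs, comps, m = site_diffs_comps_within(gm, idx)
    seg = (diffs > 0) & (comps > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(comps > 0, diffs / np.maximum(comps, 1.0), 0.0)

    win = list(zip(gm.chrom, _window_index(gm.pos, window_bp)))
    df = pd.DataFrame({"key": win, "pi": pi_site, "seg": seg.astype(int),
                       "m": np.where(seg, m, np.nan)})
    agg = df.groupby("key", sort=False).agg(
        pi_hat=("pi", "sum"), S=("seg", "sum"), n_eff=("m", "median")
    )

    w = _window_frame(gm.chrom, gm.pos, window_bp,
                      values={}, extras={"n_sites": (comps > 0).astype(int)},
                      chrom_lengths=chrom_lengths)
    keys = list(zip(w.chrom, w.start // window_bp))
    S = np.array([int(agg.S.get(k, 0)) for k in keys])
    pi_hat = np.array([float(agg.pi_hat.get(k, 0.0)) for k in keys])
    n_eff = np.array([float(agg.n_eff.get(k, np.nan)) for k in keys])
    d_vals = [
        tajimas_d(p, s, int(round(ne)) if np.isfinite(ne) else 0)
        for p, s, ne in zip(pi_hat, S, n_eff)
    ]
    w["tajimas_d"] = d_vals
    w["S"] = S
    w["n_eff"] = n_eff
    return w


# ---------------------------------------------------------------------
# LD (genotype-dosage r^2)

def r2_pairs(d: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """r^2 between dosage columns i and j with pairwise deletion of
    missing genotypes.  Zero-variance pairs yield NaN."""
    x = d[:, i_idx].astype(float)
    y = d[:, j_idx].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x = np.where(ok, x, 0.0)
    y = np.where(ok, y, 0.0)
    k = ok.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx, sy = x.sum(0), y.sum(0)
        sxx = (x * x).sum(0) - sx * sx / k
        syy = (y * y).sum(0) - sy * sy / k
        sxy = (x * y).sum(0) - sx * sy / k
        r2 = np.where((sxx > 0) & (syy > 0) & (k > 1), sxy**2 / (sxx * syy), np.nan)
    return r2


def r2_matrix(d: np.ndarray) -> np.ndarray:
    """Full r^2 matrix among the columns of a dosage block (pairwise
    deletion); diagonal and zero-variance entries are NaN."""
    ok = d != MISSING
    x = np.where(ok, d, 0).astype(float)
    okf = ok.astype(float)
    k = okf.T @ okf
    sx = x.T @ okf
    sxy = x.T @ x
    sxx = (x * x).T @ okf
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / k
        varx = sxx - sx**2 / k
        vary = varx.T
        r2 = np.where((varx > 0) & (vary > 0) & (k > 1), cov**2 / (varx * vary), np.nan)
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_pairs_in_range(gm: GenotypeMatrix, group, dmin: int, dmax: int) -> np.ndarray:
    """r^2 values for all same-chromosome site pairs separated by a
    distance in [dmin, dmax]."""
    idx = gm.sample_indices(group)
    d = gm.dosage[idx]
    out = []
    for c in dict.fromkeys(gm.chrom):
        on = np.nonzero(gm.chrom == c)[0]
        pos = gm.pos[on]
        lo = np.searchsorted(pos, pos + dmin, side="left")
        hi = np.searchsorted(pos, pos + dmax, side="right")
        ii = np.repeat(np.arange(len(pos)), hi - lo)
        jj = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)]) if len(pos) else np.array([], int)
        if len(ii):
            out.append(r2_pairs(d[:, on], ii, jj))
    if not out:
        return np.array([])
    vals = np.concatenate(out)
    return vals[np.isfinite(vals)]


def ld_decay(
    gm: GenotypeMatrix,
    group,
    distances=LD_BIN_DISTANCES,
    tol: int = LD_BIN_TOL,
) -> pd.DataFrame:
    """Mean and median r^2 in the eleven fixed distance bins (+/- tol bp)."""
    rows = []
    for dist in distances:
        vals = ld_pairs_in_range(gm, group, max(1, dist - tol), dist + tol)
        rows.append(
            {
                "distance": dist,
                "mean_r2": float(np.mean(vals)) if len(vals) else np.nan,
                "median_r2": float(np.median(vals)) if len(vals) else np.nan,
                "n_pairs": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
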
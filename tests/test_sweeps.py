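"""Sweep scans: background SFS, CLR model limits, outlier rules, omega."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fawpop import popstats
from fawpop.simulate import SimConfig, inject_sweep, simulate_cohort
from fawpop.sweeps import (
    DEFAULT_ALPHAS,
    OMEGA_CAP,
    _omega_window,
    _sweep_tables,
    background_sfs,
    clr_scan,
    find_clr_outliers,
    omega_scan,
    projection_weights,
    refine_sweep_region,
)

from conftest import make_gm


class TestProjection:
    def test_hypergeometric_enumeration(self):
        # site with 3 ALT of 8 alleles projected to 4: exhaustive combinatorics
        W = projection_weights(np.array([8]), np.array([3]), 4)[0]
        denom = math.comb(8, 4)
        expected = [math.comb(3, j) * math.comb(5, 4 - j) / denom for j in range(5)]
        assert np.allclose(W, expected)

    def test_rows_are_distributions(self):
        W = projection_weights(np.array([10, 12, 20]), np.array([2, 6, 19]), 8)
        assert np.allclose(W.sum(axis=1), 1.0)


class TestBackgroundSfs:
    def test_all_singletons_concentrates_at_one(self):
        # 10 samples, each site has exactly one het carrier
        d = np.zeros((10, 30), dtype=np.int8)
        d[np.arange(30) % 10, np.arange(30)] = 1
        gm = make_gm(d, pos=np.arange(1, 31) * 100)
        sfs = background_sfs(gm, [f"s{i}" for i in range(10)])
        spec = sfs.spectrum
        assert spec[0] > 0.95

    def test_neutral_shape_proportional_to_harmonic(self):
        cfg = SimConfig(n_samples_per_group=25, chrom_lengths=tuple([500_000] * 31),
                        n_sites_per_chrom=300, seed=13, freq_mode="neutral",
                        fst_autosome=0.0, fst_z=0.0, fst_subpop=0.0,
                        hybrid_fraction=0.0, n_diagnostic_markers=0)
        gm, _ = simulate_cohort(cfg)
        grp = [s for s in gm.samples if s.startswith("R_")]
        sfs = background_sfs(gm, grp)
        n = sfs.n
        j = np.arange(1, n // 2 + 1)
        expected = 1.0 / j + 1.0 / (n - j)
        expected[j == n - j] /= 2.0
        expected /= expected.sum()
        # coarse shape agreement within Monte-Carlo error
        assert np.corrcoef(sfs.spectrum, expected)[0, 1] > 0.98

    def test_refuses_tiny_samples(self):
        gm = make_gm([[1]])
        with pytest.raises(ValueError, match="4 observed alleles"):
            background_sfs(gm, ["s0"])


class TestClrModel:
    def test_all_escape_limit_recovers_background(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, rng.uniform(0.05, 0.95, 40), size=(10, 40)).astype(np.int8)
        gm = make_gm(d, pos=np.arange(1, 41) * 100)
        sfs = background_sfs(gm, [f"s{i}" for i in range(10)])
        T = _sweep_tables(sfs)
        # k = n escaped lineages: the sweep model is exactly the background,
        # so the per-site log-ratio vanishes in the all-escape limit
        assert np.allclose(T[sfs.n], sfs.phi_full)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)

    def test_neutral_data_median_clr_near_zero(self):
        cfg = SimConfig(n_samples_per_group=20,
                        chrom_lengths=tuple([5_000_000] + [10_000] * 30),
                        n_sites_per_chrom=[1500] + [10] * 30,
                        seed=21, hybrid_fraction=0.0, n_diagnostic_markers=0,
                        c_subpops=("central",))
        gm, _ = simulate_cohort(cfg)
        grp = [s for s in gm.samples if s.startswith("R_")]
        grid = clr_scan(gm, grp, grid_bp=5_000, chroms=["1"])
        assert grid.clr.median() < 1.0
        assert (grid.clr >= 0).all()

    def test_injected_sweep_localized(self):
        cfg = SimConfig(n_samples_per_group=25,
                        chrom_lengths=tuple([10_000_000] + [10_000] * 30),
                        n_sites_per_chrom=[3000] + [10] * 30,
                        seed=3, hybrid_fraction=0.0, n_diagnostic_markers=0,
                        c_subpops=("central",))
        gm, truth = simulate_cohort(cfg)
        grp = [s for s in gm.samples if s.startswith("R_")]
        gm_s, truth = inject_sweep(gm, truth, "1", 5_000_000, 150_000, seed=9,
                                   group=gm.sample_indices(grp))
        sfs = background_sfs(gm_s, grp)
        grid = clr_scan(gm_s, grp, grid_bp=5_000, sfs=sfs, chroms=["1"])
        top = grid.loc[grid.clr.idxmax()]
        assert abs(top.pos - 5_000_000) <= 2 * 5_000


class TestOutliers:
    def test_degenerate_all_equal(self):
        grid = pd.DataFrame({"chrom": "1", "pos": np.arange(20) * 5000.0, "clr": 1.0})
        with pytest.warns(UserWarning):
            thr, out = find_clr_outliers(grid)
        assert len(out) == 0

    def test_order_statistics_on_neutral_grid(self):
        rng = np.random.default_rng(1)
        grid = pd.DataFrame({"chrom": "1", "pos": np.arange(20_000) * 5000.0,
                             "clr": rng.exponential(1.0, 20_000)})
        thr, out = find_clr_outliers(grid, percentile=99.99)
        # oracle: order statistics -- about 2 of 20,000 exceed the threshold
        assert 1 <= len(out) <= 4

    def test_injected_sweep_is_an_outlier(self):
        rng = np.random.default_rng(2)
        clr = rng.exponential(0.5, 15_000)
        clr[7000] = 500.0
        grid = pd.DataFrame({"chrom": "1", "pos": np.arange(15_000) * 5000.0, "clr": clr})
        thr, out = find_clr_outliers(grid, percentile=99.99)
        assert 7000 * 5000.0 in set(out.pos)


class TestRefine:
    def test_refined_region_overlaps_truth(self):
        cfg = SimConfig(n_samples_per_group=25,
                        chrom_lengths=tuple([4_000_000] + [10_000] * 30),
                        n_sites_per_chrom=[2000] + [10] * 30,
                        seed=7, hybrid_fraction=0.0, n_diagnostic_markers=0,
                        c_subpops=("central",))
        gm, truth = simulate_cohort(cfg)
        grp = [s for s in gm.samples if s.startswith("R_")]
        gm_s, truth = inject_sweep(gm, truth, "1", 2_000_000, 120_000, seed=4,
                                   group=gm.sample_indices(grp))
        sfs = background_sfs(gm_s, grp)
        grid = clr_scan(gm_s, grp, grid_bp=5_000, sfs=sfs, chroms=["1"])
        top = grid.loc[grid.clr.idxmax()]
        region = refine_sweep_region(gm_s, grp, "1", top.pos, fine_bp=1_000, sfs=sfs)
        assert region is not None
        true_sweep = truth.sweeps[0]
        overlap = min(region.end, true_sweep["end"]) - max(region.start, true_sweep["start"])
        assert overlap > 0  # Jaccard > 0 with the injected interval
        assert region.start <= top.pos <= region.end


class TestOmega:
    @staticmethod
    def omega_oracle(r2, pos, minwin, maxwin):
        """Exhaustive split/extent maximization, written independently."""
        W = len(pos)
        best = np.nan
        for split in range(2, W - 1):
            boundary = (pos[split - 1] + pos[split]) / 2
            for e in np.linspace(minwin, maxwin, 5):
                L = [i for i in range(split) if pos[i] > boundary - e]
                R = [i for i in range(split, W) if pos[i] <= boundary + e]
                if len(L) < 2 or len(R) < 2:
                    continue
                wl = [r2[i, j] for i, j in itertools.combinations(L, 2) if np.isfinite(r2[i, j])]
                wr = [r2[i, j] for i, j in itertools.combinations(R, 2) if np.isfinite(r2[i, j])]
                bt = [r2[i, j] for i in L for j in R if np.isfinite(r2[i, j])]
                if not bt or (not wl and not wr):
                    continue
                within = (sum(wl) + sum(wr)) / (len(wl) + len(wr))
                between = sum(bt) / len(bt)
                om = OMEGA_CAP if between == 0 else min(within / between, OMEGA_CAP)
                if not np.isfinite(best) or om > best:
                    best = om
        return best

    def test_six_snp_matrix_matches_brute_force(self):
        rng = np.random.default_rng(11)
        d = rng.choice([0, 1, 2], size=(12, 6)).astype(np.int8)
        pos = np.array([100.0, 500.0, 900.0, 1400.0, 1900.0, 2400.0])
        r2 = popstats.r2_matrix(d)
        ours = _omega_window(r2, pos, 500, 2500, 5, OMEGA_CAP)
        assert ours == pytest.approx(self.omega_oracle(r2, pos, 500, 2500))

    def test_independent_sites_near_one(self):
        rng = np.random.default_rng(12)
        vals = []
        for rep in range(30):
            d = rng.binomial(2, 0.5, size=(60, 10)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(100, 4900), 10, replace=False)).astype(float)
            vals.append(_omega_window(popstats.r2_matrix(d), pos, 500, 2500, 5, OMEGA_CAP))
        # maximization biases omega upward; the median stays near 1
        assert 0.8 < np.nanmedian(vals) < 3.0

    def test_two_perfect_blocks_hit_the_cap(self):
        # left block: two identical sites; right block: two identical sites
        # whose dosage vector is exactly uncorrelated with the left pattern
        x = np.array([0, 1, 2, 1, 0, 2] * 2)
        y = np.array([1, 0, 1, 2, 2, 0, 1, 0, 2, 0, 1, 2])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.0, abs=1e-12)
        d = np.stack([x, x, y, y], axis=1).astype(np.int8)
        pos = np.array([100.0, 200.0, 2000.0, 2100.0])
        r2 = popstats.r2_matrix(d)
        om = _omega_window(r2, pos, 500, 2500, 5, OMEGA_CAP)
        assert om == OMEGA_CAP

    def test_window_with_too_few_snps_missing(self):
        assert np.isnan(_omega_window(np.zeros((3, 3)), np.array([1.0, 2.0, 3.0]),
                                      500, 2500, 5, OMEGA_CAP))

    def test_scan_refuses_z(self):
        gm = make_gm(np.ones((4, 2)), chrom=["31", "31"], pos=[100, 200])
        with pytest.raises(ValueError, match="autosome-only"):
            omega_scan(gm, [f"s{i}" for i in range(4)], chroms=["31"])

    def test_scan_runs_on_autosomes(self, small_cohort):
        gm, truth, cfg = small_cohort
        om = omega_scan(gm, list(gm.samples), chroms=["1"])
        assert (om.chrom == "1").all()
        assert om.omega.notna().sum() > 0
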
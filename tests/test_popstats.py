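"""Windowed statistics against longhand / brute-force oracles."""

import itertools

import numpy as np
import pytest

from fawpop import popstats
from fawpop.core import MISSING
from fawpop.popstats import (
    ld_decay,
    dxy_windowed,
    pi_windowed,
    r2_pairs,
    tajima_constants,
    tajimas_d_windowed,
    wc_fst,
)

from conftest import make_gm


# ---------------------------------------------------------------------
# independent oracles (plain longhand arithmetic)

def wc_theta_oracle(genos_a, genos_b):
    """Weir-Cockerham (1984) theta for one site from genotype lists."""
    def summarize(genos):
        genos = [g for g in genos if g is not None]
        n = len(genos)
        p = sum(genos) / (2 * n)
        h = sum(1 for g in genos if g == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(genos_a)
    n2, p2, h2 = summarize(genos_b)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a / (a + b + c)


def pairwise_pi_oracle(dosage):
    """Brute-force pi: enumerate every allele pair at every site."""
    total_diff = 0
    total_comp = 0
    for col in np.asarray(dosage).T:
        alleles = []
        for d in col:
            if d != MISSING:
                alleles.extend([1] * d + [0] * (2 - d))
        for x, y in itertools.combinations(alleles, 2):
            total_comp += 1
            total_diff += int(x != y)
    return total_diff / total_comp


# ---------------------------------------------------------------------
# Weir-Cockerham Fst

class TestWcFst:
    def test_fixed_difference_gives_theta_one(self):
        d = np.r_[np.zeros((10, 1)), np.full((10, 1), 2)]
        gm = make_gm(d)
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        res = wc_fst(gm, a, b, window_bp=None)
        assert res.per_site.theta.iloc[0] == pytest.approx(1.0)
        assert res.weighted == pytest.approx(1.0)

    def test_identical_count_configurations_nonpositive(self):
        col = [0] * 3 + [1] * 4 + [2] * 3
        gm = make_gm(np.array(col + col).reshape(-1, 1))
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        res = wc_fst(gm, a, b, window_bp=None)
        assert res.per_site.theta.iloc[0] <= 0

    def test_matches_longhand_components(self):
        genos_a = [0] * 3 + [1] * 4 + [2] * 3
        genos_b = [0] * 8 + [1] * 2
        gm = make_gm(np.array(genos_a + genos_b).reshape(-1, 1))
        a = [f"s{i}" for i in range(10)]
        b = [f"s{i}" for i in range(10, 20)]
        res = wc_fst(gm, a, b, window_bp=None)
        expected = wc_theta_oracle(genos_a, genos_b)
        assert res.per_site.theta.iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.2777778, abs=1e-6)

    def test_weighted_is_ratio_of_sums(self):
        rng = np.random.default_rng(2)
        d = rng.choice([0, 1, 2, MISSING], size=(12, 40), p=[0.4, 0.25, 0.25, 0.1])
        gm = make_gm(d, pos=np.arange(1, 41) * 400)  # spans multiple 10 kb windows
        a = [f"s{i}" for i in range(6)]
        b = [f"s{i}" for i in range(6, 12)]
        res = wc_fst(gm, a, b, window_bp=10_000)
        ps = res.per_site.dropna()
        usable = ps[ps.abc != 0]
        assert res.weighted == pytest.approx(usable.a.sum() / usable.abc.sum())
        # associativity: summing window numerators/denominators reproduces it
        assert res.windows.fst.notna().sum() >= 2


# ---------------------------------------------------------------------
# pi / Dxy

class TestPi:
    def test_monomorphic_window_is_zero(self):
        gm = make_gm(np.zeros((4, 5)), alt=["."] * 5)
        w = pi_windowed(gm, [f"s{i}" for i in range(4)], window_bp=1000)
        assert w.pi.iloc[0] == 0.0

    def test_single_site_two_of_four_alleles(self):
        gm = make_gm([[1], [1]])
        w = pi_windowed(gm, ["s0", "s1"], window_bp=1000)
        # oracle: 6 allele pairs, 4 differ
        assert w.pi.iloc[0] == pytest.approx(4 / 6)

    def test_invariant_sites_dilute_the_denominator(self):
        d = np.zeros((2, 1000), dtype=np.int8)
        d[:, 0] = 1  # one site with counts 2/2; 999 invariant sites
        gm = make_gm(d, pos=np.arange(1, 1001))
        w = pi_windowed(gm, ["s0", "s1"], window_bp=1000)
        assert w.pi.iloc[0] == pytest.approx(4 / 6000)

    def test_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        d = rng.choice([0, 1, 2], size=(6, 20))
        gm = make_gm(d, pos=np.arange(1, 21) * 10)
        w = pi_windowed(gm, [f"s{i}" for i in range(6)], window_bp=1000)
        assert w.pi.iloc[0] == pytest.approx(pairwise_pi_oracle(d))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        d = rng.choice([0, 1, 2, MISSING], size=(6, 15))
        gm = make_gm(d)
        grp = [f"s{i}" for i in range(6)]
        w1 = pi_windowed(gm, grp, window_bp=5000)
        w2 = pi_windowed(gm, list(reversed(grp)), window_bp=5000)
        assert np.allclose(w1.pi, w2.pi, equal_nan=True)


class TestDxy:
    def test_fixed_difference_site(self):
        gm = make_gm([[0], [0], [2], [2]])
        w = dxy_windowed(gm, ["s0", "s1"], ["s2", "s3"], window_bp=1000)
        assert w.dxy.iloc[0] == pytest.approx(1.0)

    def test_cross_pair_enumeration(self):
        # group A alleles 1/4 ALT, group B 3/4 ALT
        gm = make_gm([[1], [0], [2], [1]])
        w = dxy_windowed(gm, ["s0", "s1"], ["s2", "s3"], window_bp=1000)
        # oracle: 16 cross pairs, diffs = 1*1 + 3*3 = 10
        assert w.dxy.iloc[0] == pytest.approx(10 / 16)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        d = rng.choice([0, 1, 2, MISSING], size=(8, 30), p=[0.4, 0.2, 0.3, 0.1])
        gm = make_gm(d)
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        w1 = dxy_windowed(gm, a, b, window_bp=5000)
        w2 = dxy_windowed(gm, b, a, window_bp=5000)
        assert np.allclose(w1.dxy, w2.dxy, equal_nan=True)

    def test_site_missing_filter(self):
        d = np.array([[1, 1], [0, MISSING], [2, MISSING], [1, 1]])
        gm = make_gm(d)
        w = dxy_windowed(gm, ["s0", "s1"], ["s2", "s3"], window_bp=5000,
                         site_missing_max=0.2)
        assert w.n_sites.iloc[0] == 1  # second site: 50% missing > 20%

    def test_identical_frequencies_approximate_pooled_pi(self):
        # same sample frequency in both groups: Dxy and pooled pi agree up
        # to the self-pairing m/(m-1) correction
        d = np.array([[0], [1], [2], [0], [1], [2]])
        gm = make_gm(d)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        dxy = dxy_windowed(gm, a, b, window_bp=1000).dxy.iloc[0]
        pi = pi_windowed(gm, a + b, window_bp=1000).pi.iloc[0]
        m = 12
        assert dxy == pytest.approx(pi, rel=1.5 / (m - 1))

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(6)
        d = rng.choice([0, 1, 2, MISSING], size=(8, 50), p=[0.3, 0.2, 0.3, 0.2])
        gm = make_gm(d)
        a = [f"s{i}" for i in range(4)]
        b = [f"s{i}" for i in range(4, 8)]
        w = dxy_windowed(gm, a, b, window_bp=2000, site_missing_max=0.5)
        vals = w.dxy.dropna()
        assert ((vals >= 0) & (vals <= 1)).all()


# ---------------------------------------------------------------------
# Tajima's D

class TestTajimasD:
    def test_no_segregating_sites_is_missing(self):
        gm = make_gm(np.zeros((4, 10)))
        w = tajimas_d_windowed(gm, [f"s{i}" for i in range(4)], window_bp=5000)
        assert w.tajimas_d.isna().all()

    def test_four_allele_worked_example(self):
        # n=4 alleles, two segregating sites with derived counts 1 and 2
        gm = make_gm([[1, 1], [0, 1]])
        w = tajimas_d_windowed(gm, ["s0", "s1"], window_bp=5000)
        # oracle: longhand Tajima constants at n=4
        k = tajima_constants(4)
        assert k["a1"] == pytest.approx(11 / 6)
        assert k["a2"] == pytest.approx(49 / 36)
        pi_hat, S = 7 / 6, 2
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        expected = (pi_hat - S / k["a1"]) / np.sqrt(var)
        assert w.tajimas_d.iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.59, abs=0.01)


# ---------------------------------------------------------------------
# LD

class TestLd:
    def test_duplicated_site_r2_one(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        gm = make_gm(d, pos=[100, 200])
        bins = ld_decay(gm, [f"s{i}" for i in range(4)], distances=(100,))
        assert bins.mean_r2.iloc[0] == pytest.approx(1.0)
        assert bins.n_pairs.iloc[0] == 1

    def test_dosage_vector_worked_example(self):
        x = np.array([[0, 0], [1, 1], [2, 1], [2, 2]])
        gm = make_gm(x, pos=[100, 200])
        r2 = r2_pairs(gm.dosage, np.array([0]), np.array([1]))
        assert r2[0] == pytest.approx(4 / 5.5)

    def test_zero_variance_pair_skipped(self):
        d = np.array([[0, 1], [0, 2], [0, 0], [0, 1]])
        gm = make_gm(d, pos=[100, 200])
        bins = ld_decay(gm, [f"s{i}" for i in range(4)], distances=(100,))
        assert bins.n_pairs.iloc[0] == 0

    def test_independent_sites_mean_r2_near_reciprocal_n(self):
        rng = np.random.default_rng(7)
        n = 50
        d = rng.binomial(2, 0.4, size=(n, 200))
        gm = make_gm(d, pos=np.arange(1, 201) * 100)
        bins = ld_decay(gm, [f"s{i}" for i in range(n)], distances=(100,))
        # analytic approximation: E[r^2] about 1/n under independence
        assert bins.mean_r2.iloc[0] == pytest.approx(1 / n, rel=0.6)
        assert bins.n_pairs.iloc[0] > 100

    def test_bin_tolerance_window(self):
        d = np.tile([[0], [1], [2], [1], [0], [2]], (1, 3))
        gm = make_gm(d, pos=[100, 240, 360])  # pair distances 140, 120, 260
        bins = ld_decay(gm, [f"s{i}" for i in range(6)], distances=(100, 250))
        # 140 and 120 fall in 100 +/- 50; 260 falls in 250 +/- 50
        assert bins.n_pairs.tolist() == [2, 1]
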
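"""Synthetic two-strain cohorts with the structure the analysis assumes.

The generator is a Balding-Nichols differentiation model: each site has an
ancestral frequency p, and each population draws its own frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), so that the Weir-Cockerham estimator is a
consistent estimator of F.  Differentiation is strong on the Z (chromosome
"31") and weak on the autosomes; the C-strain additionally carries flyway
sub-structure at a much smaller F.  All simulated moths are male (ZZ), so
the Z is an ordinary diploid chromosome throughout.

F1-like hybrids receive one haplotype drawn from each strain's frequencies
at every site, which makes them heterozygous with high probability at
fixed-difference diagnostic markers -- exactly the signal the strain caller
keys on.

Two ancestral-frequency modes exist:

* ``"uniform"`` (default): p ~ Uniform(0.05, 0.95).  This is a convenient
  stated world for differentiation statistics but deliberately over-weights
  intermediate frequencies, so Tajima's D is positive by construction.
* ``"neutral"``: p drawn with density proportional to 1/p, which under
  binomial sampling yields the exact 1/j neutral site-frequency spectrum
  (integral of Binom(j; n, p)/p over p is 1/j).  Use this mode when a
  statistic's null behaviour under neutrality is the question.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING, Z_CHROM

_BASES = np.array(list("ACGT"))

#: defaults follow the study design: strong Z-linked differentiation
#: (Fst 0.671) versus weak autosomal differentiation (0.086), and
#: C-strain flyway sub-structure at Fst 0.047.
@dataclass
class SimConfig:
    n_samples_per_group: int = 50
    chrom_lengths: tuple = tuple([1_000_000] * 31)
    n_sites_per_chrom: int = 2_000
    fst_autosome: float = 0.086
    fst_z: float = 0.671
    fst_subpop: float = 0.047
    hybrid_fraction: float = 0.03
    missing_rate: float = 0.05
    depth_mean: float = 100.0
    gq_mean: float = 60.0
    n_diagnostic_markers: int = 4
    c_subpops: tuple = ("central", "eastern")
    freq_mode: str = "uniform"  # or "neutral"
    sweep_specs: tuple = ()     # (chrom, center_bp, strength_bp) triples
    seed: int = 0

    def validate(self) -> None:
        if len(self.chrom_lengths) != 31:
            raise ValueError("chrom_lengths must list 31 chromosomes (30 autosomes + Z)")
        for name in ("fst_autosome", "fst_z", "fst_subpop", "hybrid_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        counts = self.site_counts()
        if len(counts) != 31:
            raise ValueError("n_sites_per_chrom must be a count or a list of 31 counts")
        if min(counts) < 1:
            raise ValueError("need at least one site per chromosome")
        if self.freq_mode not in ("uniform", "neutral"):
            raise ValueError(f"unknown freq_mode {self.freq_mode!r}")

    def site_counts(self) -> tuple:
        """Per-chromosome site counts (a scalar count applies to all 31)."""
        if np.isscalar(self.n_sites_per_chrom):
            return tuple([int(self.n_sites_per_chrom)] * 31)
        return tuple(int(c) for c in self.n_sites_per_chrom)


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated cohort."""

    samples: pd.DataFrame   # sample, strain, subpop
    sites: pd.DataFrame     # chrom, pos, p_anc and per-group frequencies
    sweeps: list = field(default_factory=list)   # dicts with chrom/center/strength/start/end/group
    markers: pd.DataFrame | None = None  # chrom, pos, name, c_allele, r_allele


def _bn_freq(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols draw of a subpopulation frequency around p.

    F = 0 degenerates to p itself (the Beta parameters diverge)."""
    if F <= 0.0:
        return p.copy()
    # frequencies already fixed at 0 or 1 stay fixed (degenerate Beta)
    safe = np.clip(p, 1e-12, 1.0 - 1e-12)
    a = safe * (1.0 - F) / F
    b = (1.0 - safe) * (1.0 - F) / F
    q = rng.beta(a, b)
    return np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, q))


def _positions(rng: np.random.Generator, length: int, m: int) -> np.ndarray:
    """m distinct sorted 1-based positions on [1, length]."""
    if m > length:
        raise ValueError(f"cannot place {m} sites on a {length} bp chromosome")
    pos = np.unique(rng.integers(1, length + 1, size=int(m * 1.3) + 8))
    while len(pos) < m:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=m)]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate a two-strain cohort under the Balding-Nichols model.

    Returns the genotype matrix (no missingness or DP/GQ noise; see
    :func:`degrade`) and the ground-truth table.  Deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples_per_group

    # sample sheet: R strain, C subpopulations, then hybrids
    names, strains, subpops = [], [], []
    for i in range(n):
        names.append(f"R_{i:03d}")
        strains.append("R")
        subpops.append("none")
    for sub in config.c_subpops:
        for i in range(n):
            names.append(f"C_{sub}_{i:03d}")
            strains.append("C")
            subpops.append(sub)
    n_groups = 1 + len(config.c_subpops)
    n_hyb = int(round(config.hybrid_fraction * n * n_groups))
    for i in range(n_hyb):
        names.append(f"HYB_{i:03d}")
        strains.append("hybrid")
        subpops.append("none")
    samples_df = pd.DataFrame({"sample": names, "strain": strains, "subpop": subpops})

    idx_r = np.array([i for i, s in enumerate(strains) if s == "R"])
    idx_c = {
        sub: np.array([i for i, (s, sp) in enumerate(zip(strains, subpops)) if s == "C" and sp == sub])
        for sub in config.c_subpops
    }
    idx_h = np.array([i for i, s in enumerate(strains) if s == "hybrid"], dtype=np.intp)

    all_chrom, all_pos, all_ref, all_alt = [], [], [], []
    dosage_blocks = []
    site_rows = []
    marker_rows = []

    site_counts = config.site_counts()
    for ci in range(31):
        chrom = str(ci + 1)
        length = int(config.chrom_lengths[ci])
        m = site_counts[ci]
        pos = _positions(rng, length, m)
        F = config.fst_z if chrom == Z_CHROM else config.fst_autosome

        if config.freq_mode == "uniform":
            p = rng.uniform(0.05, 0.95, size=m)
        else:  # density ~ 1/p on (eps, 1 - eps): exact neutral SFS
            eps = 0.002
            u = rng.uniform(size=m)
            p = eps * ((1.0 - eps) / eps) ** u

        q_c = _bn_freq(rng, p, F)
        q_r = _bn_freq(rng, p, F)
        q_sub = {sub: _bn_freq(rng, q_c, config.fst_subpop) for sub in config.c_subpops}

        if chrom == Z_CHROM and config.n_diagnostic_markers > 0:
            # fixed differences, evenly spread along the Z
            k = config.n_diagnostic_markers
            midx = np.linspace(0, m - 1, k).round().astype(int)
            q_c[midx] = 0.0
            q_r[midx] = 1.0
            for sub in config.c_subpops:
                q_sub[sub][midx] = 0.0

        dosage = np.empty((len(names), m), dtype=np.int8)
        dosage[idx_r] = rng.binomial(2, q_r, size=(len(idx_r), m))
        for sub in config.c_subpops:
            dosage[idx_c[sub]] = rng.binomial(2, q_sub[sub], size=(len(idx_c[sub]), m))
        if len(idx_h):
            hap_c = rng.binomial(1, q_c, size=(len(idx_h), m))
            hap_r = rng.binomial(1, q_r, size=(len(idx_h), m))
            dosage[idx_h] = (hap_c + hap_r).astype(np.int8)

        ref_i = rng.integers(0, 4, size=m)
        alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
        ref = _BASES[ref_i]
        alt = _BASES[alt_i]

        if chrom == Z_CHROM and config.n_diagnostic_markers > 0:
            for j, gi in enumerate(midx):
                marker_rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(pos[gi]),
                        "name": "Tpi" if j == 0 else f"SNP{j}",
                        "c_allele": str(ref[gi]),
                        "r_allele": str(alt[gi]),
                    }
                )

        all_chrom.append(np.full(m, chrom, dtype=object))
        all_pos.append(pos)
        all_ref.append(ref.astype(object))
        all_alt.append(alt.astype(object))
        dosage_blocks.append(dosage)

        rows = pd.DataFrame({"chrom": chrom, "pos": pos, "p_anc": p, "q_C": q_c, "q_R": q_r})
        for sub in config.c_subpops:
            rows[f"q_C_{sub}"] = q_sub[sub]
        site_rows.append(rows)

    gm = GenotypeMatrix(
        samples=np.array(names, dtype=object),
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref=np.concatenate(all_ref),
        alt=np.concatenate(all_alt),
        dosage=np.concatenate(dosage_blocks, axis=1),
        metadata={"simulated": True, "seed": config.seed,
                  "chrom_lengths": {str(i + 1): int(L) for i, L in enumerate(config.chrom_lengths)}},
    )
    truth = TruthTable(
        samples=samples_df,
        sites=pd.concat(site_rows, ignore_index=True),
        sweeps=[],
        markers=pd.DataFrame(marker_rows) if marker_rows else None,
    )

    for chrom, center, strength in config.sweep_specs:
        gm, truth = inject_sweep(gm, truth, str(chrom), int(center), float(strength),
                                 seed=rng.integers(0, 2**31 - 1))
    return gm, truth


def inject_sweep(
    gm: GenotypeMatrix,
    truth: TruthTable,
    chrom: str,
    center_bp: int,
    strength: float,
    seed: int = 0,
    group: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Drive the minor allele toward loss around ``center_bp``.

    Each site at distance d from the center is, with probability
    exp(-d/strength), swept: the target group's genotypes are set to the
    homozygote of the group-major allele, leaving at most negligible minor
    frequency.  ``strength`` is the e-folding distance in bp.  The recorded
    truth interval is center +/- strength.
    """
    if strength <= 0:
        raise ValueError(f"sweep strength must be positive, got {strength}")
    chrom = str(chrom)
    on = np.nonzero(gm.chrom == chrom)[0]
    if len(on) == 0:
        raise ValueError(f"chromosome {chrom!r} has no sites")
    lengths = gm.metadata.get("chrom_lengths", {})
    if chrom in lengths and not (1 <= center_bp <= lengths[chrom]):
        raise ValueError(f"sweep center {center_bp} outside chromosome {chrom}")

    rng = np.random.default_rng(seed)
    rows = np.arange(gm.n_samples) if group is None else np.asarray(group)
    out = gm.copy()

    d = np.abs(gm.pos[on] - center_bp).astype(float)
    hit = rng.uniform(size=len(on)) < np.exp(-d / strength)
    hit_idx = on[hit]
    sub = out.dosage[np.ix_(rows, hit_idx)]
    called = sub != MISSING
    alt_cnt = np.where(called, sub, 0).sum(axis=0)
    tot = 2 * called.sum(axis=0)
    major_is_alt = alt_cnt * 2 > tot
    fill = np.where(major_is_alt, 2, 0).astype(np.int8)
    swept = np.where(called, np.broadcast_to(fill, sub.shape), MISSING).astype(np.int8)
    out.dosage[np.ix_(rows, hit_idx)] = swept

    truth = TruthTable(
        samples=truth.samples,
        sites=truth.sites,
        sweeps=truth.sweeps
        + [
            {
                "chrom": chrom,
                "center": int(center_bp),
                "strength": float(strength),
                "start": int(max(1, center_bp - strength)),
                "end": int(center_bp + strength),
                "group": "all" if group is None else "subset",
            }
        ],
        markers=truth.markers,
    )
    return out, truth


def degrade(
    gm: GenotypeMatrix,
    missing_rate: float,
    depth_mean: float,
    gq_mean: float,
    seed: int = 0,
) -> GenotypeMatrix:
    """Add i.i.d. missingness plus Poisson DP and clamped-normal GQ fields."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"missing_rate={missing_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    shape = out.dosage.shape
    out.dp = rng.poisson(depth_mean, size=shape).astype(np.int16)
    out.gq = np.clip(rng.normal(gq_mean, 15.0, size=shape), 0, 99).round().astype(np.int16)
    if missing_rate > 0:
        mask = rng.uniform(size=shape) < missing_rate
        out.dosage = np.where(mask, np.int8(MISSING), out.dosage)
    out.metadata["degraded"] = {"missing_rate": missing_rate, "depth_mean": depth_mean,
                                "gq_mean": gq_mean, "seed": seed}
    return out


def table1_fixture() -> pd.DataFrame:
    """The packaged 2021 pheromone-trap collection table (24 rows).

    Columns: county, state, flyway, month, host, n, n_c, n_hybrid, n_r,
    where n = n_c + n_hybrid + n_r on every row and the n column sums to
    the 412 strain-typed moths.
    """
    text = resources.files("fawpop.data").joinpath("collections_2021.csv").read_text()
    df = pd.read_csv(io.StringIO(text))
    bad = df[df.n != df.n_c + df.n_hybrid + df.n_r]
    if len(bad):  # pragma: no cover - data integrity guard
        raise ValueError(f"inconsistent fixture rows:\n{bad}")
    return df
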
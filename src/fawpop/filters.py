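"""Site filters applied to the genotype matrix, mirroring the study's
bcftools/VCFtools filtering chain.

Order used by the pipeline: per-genotype DP/GQ masking with a >50%-missing
site cut, restriction to the 31 placed chromosomes, then (for the
population-structure dataset) biallelic + maf >= 0.01.  The DP threshold is
interpreted per genotype (FORMAT/DP), like VCFtools' ``--minDP``: GQ in the
same rule is per-genotype, and a site-level reading would make the joint
sentence incoherent.  Ties at exactly 50% missing are retained ("more than
50%" removes strictly greater).
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import GenotypeMatrix, MISSING, PLACED_CHROMS


def filter_site_quality(
    gm: GenotypeMatrix,
    min_depth: int = 6,
    min_gq: int = 10,
    max_missing: float = 0.5,
) -> GenotypeMatrix:
    """Mask genotypes with DP < min_depth or GQ < min_gq, then drop sites
    whose post-masking missing fraction exceeds ``max_missing``.

    Negative DP/GQ entries mean "not annotated" and never trigger masking.
    With no DP/GQ fields at all, only the missingness rule applies (with a
    warning).
    """
    out = gm.copy()
    n_in = out.n_sites
    if out.dp is None and out.gq is None:
        warnings.warn("no DP/GQ annotations; applying only the missingness rule")
    mask = np.zeros(out.dosage.shape, dtype=bool)
    if out.dp is not None:
        mask |= (out.dp >= 0) & (out.dp < min_depth)
    if out.gq is not None:
        mask |= (out.gq >= 0) & (out.gq < min_gq)
    out.dosage = np.where(mask, np.int8(MISSING), out.dosage)

    frac = (out.dosage == MISSING).mean(axis=0) if out.n_samples else np.zeros(out.n_sites)
    keep = np.nonzero(frac <= max_missing)[0]
    out = out.take_sites(keep)
    out.log_filter(f"site_quality(dp>={min_depth},gq>={min_gq},missing<={max_missing})", n_in, out.n_sites)
    return out


def filter_biallelic_maf(gm: GenotypeMatrix, maf_min: float = 0.01) -> GenotypeMatrix:
    """Keep sites with exactly one ALT allele and global maf >= maf_min.

    maf is computed over the non-missing dosages of *all* samples (hybrids
    are only removed later, for the between-strain statistics)."""
    n_in = gm.n_sites
    alt, tot = gm.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
    maf = np.minimum(f, 1.0 - f)
    keep = np.nonzero((gm.n_alt == 1) & (tot > 0) & (maf >= maf_min))[0]
    out = gm.take_sites(keep)
    out.log_filter(f"biallelic_maf(>={maf_min})", n_in, out.n_sites)
    return out


def restrict_chromosomes(gm: GenotypeMatrix, keep=PLACED_CHROMS) -> GenotypeMatrix:
    """Drop sites not mapped to one of the kept chromosomes (default: the
    30 autosomes plus the Z, "1".."31")."""
    n_in = gm.n_sites
    out = gm.take_sites(np.nonzero(gm.sites_on(keep))[0])
    out.log_filter("restrict_chromosomes", n_in, out.n_sites)
    return out


IMPUTE_MODES = ("drop-missing-pairwise", "major-genotype-fill")


def naive_impute(gm: GenotypeMatrix, mode: str = "drop-missing-pairwise") -> GenotypeMatrix:
    """Declared stand-in for model-based genotype imputation.

    ``drop-missing-pairwise`` leaves the matrix untouched and records that
    downstream statistics handle missingness by pairwise deletion;
    ``major-genotype-fill`` replaces each missing genotype with the site's
    most frequent called dosage (ties break toward the smaller dosage).
    """
    if mode not in IMPUTE_MODES:
        raise ValueError(f"unknown impute mode {mode!r}; expected one of {IMPUTE_MODES}")
    out = gm.copy()
    if mode == "major-genotype-fill" and out.n_sites:
        counts = np.stack([(out.dosage == k).sum(axis=0) for k in (0, 1, 2)])
        fill = counts.argmax(axis=0).astype(np.int8)  # argmax ties -> smaller dosage
        out.dosage = np.where(out.dosage == MISSING, fill[None, :], out.dosage)
    out.metadata["impute"] = mode
    return out
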
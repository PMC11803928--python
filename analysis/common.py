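"""Shared paths and the cohort configuration used by the analysis scripts.

The cohort is a scaled-down stand-in for the 412-moth study: 31
chromosomes (the Z is "31"), two strains with C-strain flyway
sub-structure, a few F1 hybrids, per-genotype DP/GQ and 5% missingness.
"""

from pathlib import Path

from fawpop.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"

COHORT_SEED = 2021

COHORT = SimConfig(
    n_samples_per_group=30,
    chrom_lengths=tuple([300_000] * 30 + [600_000]),
    n_sites_per_chrom=[250] * 30 + [500],
    seed=COHORT_SEED,
)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
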
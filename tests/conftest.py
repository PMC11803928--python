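import numpy as np
import pytest

from fawpop.core import GenotypeMatrix
from fawpop.simulate import SimConfig, simulate_cohort


def make_gm(dosage, chrom=None, pos=None, ref=None, alt=None, samples=None, dp=None, gq=None):
    """Build a small GenotypeMatrix from a dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    return GenotypeMatrix(
        samples=np.array(samples if samples is not None else [f"s{i}" for i in range(n)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 100, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.array(alt if alt is not None else ["T"] * m, dtype=object),
        dosage=dosage,
        dp=None if dp is None else np.asarray(dp, dtype=np.int16),
        gq=None if gq is None else np.asarray(gq, dtype=np.int16),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured two-strain cohort (shared, read-only)."""
    cfg = SimConfig(
        n_samples_per_group=20,
        chrom_lengths=tuple([300_000] * 31),
        n_sites_per_chrom=200,
        seed=5,
    )
    gm, truth = simulate_cohort(cfg)
    return gm, truth, cfg


def strain_samples(gm, prefix):
    return [s for s in gm.samples if s.startswith(prefix)]
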
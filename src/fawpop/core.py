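"""Core in-memory model: a samples x sites diploid dosage matrix.

Genotypes are stored as ALT-allele dosages in {0, 1, 2} with ``MISSING``
(-1) for uncalled genotypes.  Chromosomes are kept as strings so that
unplaced scaffolds survive reading; the study's convention is that
chromosomes "1".."30" are autosomes and "31" is the Z.  All positions are
1-based (VCF convention) and strictly increasing within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

#: chromosome label of the lepidopteran Z in this assembly
Z_CHROM = "31"

#: the 31 placed chromosomes (30 autosomes + Z)
PLACED_CHROMS = tuple(str(i) for i in range(1, 32))
AUTOSOMES = tuple(str(i) for i in range(1, 31))


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosages with optional per-genotype DP and GQ.

    Attributes
    ----------
    samples : (n,) array of sample IDs
    chrom, pos, ref, alt : (m,) per-site arrays; ``alt`` is the
        comma-joined ALT string, ``"."`` for invariant (no-ALT) records.
    dosage : (n, m) int8 array of ALT dosages, ``MISSING`` where uncalled.
    dp, gq : optional (n, m) int arrays (read depth / phred genotype
        quality); negative entries mean "not annotated".
    """

    samples: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        if self.n_sites < 2:
            return
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            bad = int(np.nonzero(same & (np.diff(self.pos) <= 0))[0][0]) + 1
            raise ValueError(
                f"positions not strictly increasing within chromosome "
                f"{self.chrom[bad]} at site index {bad} (pos {self.pos[bad]})"
            )
        # chromosomes must appear in contiguous blocks
        seen: set[str] = set()
        prev = None
        for c in self.chrom:
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c} appears in two blocks; input unsorted")
                seen.add(c)
                prev = c

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_alt(self) -> np.ndarray:
        """Number of ALT alleles per site (0 for invariant records)."""
        return np.array(
            [0 if a in (".", "") else a.count(",") + 1 for a in self.alt],
            dtype=np.int32,
        )

    # -- indexing ------------------------------------------------------
    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            metadata=dict(self.metadata),
        )

    def take_samples(self, names_or_idx) -> "GenotypeMatrix":
        arr = np.asarray(names_or_idx)
        idx = self.sample_indices(arr) if arr.dtype.kind in ("U", "S", "O") else arr
        return GenotypeMatrix(
            samples=self.samples[idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx, :],
            dp=None if self.dp is None else self.dp[idx, :],
            gq=None if self.gq is None else self.gq[idx, :],
            metadata=dict(self.metadata),
        )

    def sites_on(self, chroms: Iterable[str]) -> np.ndarray:
        keep = set(str(c) for c in chroms)
        return np.array([c in keep for c in self.chrom], dtype=bool)

    # -- summaries -----------------------------------------------------
    def called_mask(self, sample_idx=None) -> np.ndarray:
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        return d != MISSING

    def allele_counts(self, sample_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT allele count, total called alleles) over the
        given samples (all samples by default)."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0).astype(np.int64)
        tot = 2 * called.sum(axis=0).astype(np.int64)
        return alt, tot

    def site_missing_fraction(self, sample_idx=None) -> np.ndarray:
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        return (d == MISSING).mean(axis=0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            dosage=self.dosage.copy(),
            dp=None if self.dp is None else self.dp.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            metadata=dict(self.metadata),
        )

    def log_filter(self, rule: str, n_in: int, n_out: int) -> None:
        self.metadata.setdefault("filter_log", []).append(
            {"rule": rule, "sites_in": int(n_in), "sites_out": int(n_out)}
        )


def groups_to_indices(gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]]) -> dict[str, np.ndarray]:
    """Resolve a {label: [sample names]} mapping to row indices."""
    return {label: gm.sample_indices(names) for label, names in groups.items()}
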
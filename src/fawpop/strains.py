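"""Z-linked diagnostic-marker strain calling and composition tables.

Each sample is classified from a panel of Z-chromosome markers (Tpi plus
diagnostic SNPs) with known C- and R-strain alleles:

* fewer than 2 markers with a called genotype  -> ``unknown`` (removed),
* one or more heterozygous markers            -> ``hybrid``,
* all observed markers homozygous C           -> ``C``,
* all observed markers homozygous R           -> ``R``,
* discordant homozygotes (C-hom and R-hom, no het) -> ``unknown`` with a
  ``discordant`` flag -- the conservative reading, so hybrid counts are
  never inflated by genotyping artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING

LABELS = ("C", "R", "hybrid", "unknown")


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos: int
    c_allele: str
    r_allele: str
    name: str


@dataclass
class MarkerPanel:
    markers: list[Marker]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("a marker panel needs at least 2 markers")
        for m in self.markers:
            if m.c_allele == m.r_allele:
                raise ValueError(f"marker {m.name}: C and R alleles must differ")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        return cls([
            Marker(str(r.chrom), int(r.pos), str(r.c_allele), str(r.r_allele), str(r.name))
            for r in df.itertuples()
        ])

    @classmethod
    def read_tsv(cls, path) -> "MarkerPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class StrainCall:
    sample: str
    label: str
    n_markers_observed: int
    marker_classes: dict  # marker name -> "C-hom" | "R-hom" | "het" | "missing"
    discordant: bool = False


def _marker_orientation(gm: GenotypeMatrix, marker: Marker) -> tuple[int | None, bool]:
    """Locate the marker site and report whether the C allele is REF.

    Returns (site index or None if absent, c_is_ref)."""
    hits = np.nonzero((gm.chrom == marker.chrom) & (gm.pos == marker.pos))[0]
    if len(hits) == 0:
        return None, True
    j = int(hits[0])
    ref, alt = str(gm.ref[j]), str(gm.alt[j])
    if {ref, alt} != {marker.c_allele, marker.r_allele}:
        raise ValueError(
            f"marker {marker.name} at {marker.chrom}:{marker.pos}: VCF alleles "
            f"{ref}/{alt} do not match panel {marker.c_allele}/{marker.r_allele}"
        )
    return j, ref == marker.c_allele


def classify_marker_genotypes(gm: GenotypeMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample, per-marker genotype class table."""
    classes = {}
    for marker in panel.markers:
        j, c_is_ref = _marker_orientation(gm, marker)
        if j is None:
            classes[marker.name] = np.full(gm.n_samples, "missing", dtype=object)
            continue
        d = gm.dosage[:, j]
        hom_ref, hom_alt = ("C-hom", "R-hom") if c_is_ref else ("R-hom", "C-hom")
        cls = np.where(d == MISSING, "missing",
                       np.where(d == 1, "het", np.where(d == 0, hom_ref, hom_alt)))
        classes[marker.name] = cls.astype(object)
    return pd.DataFrame(classes, index=list(gm.samples))


def call_strain(marker_classes: dict) -> tuple[str, bool]:
    """Classify one sample from its marker classes; returns (label, discordant)."""
    observed = [c for c in marker_classes.values() if c != "missing"]
    if len(observed) < 2:
        return "unknown", False
    if any(c == "het" for c in observed):
        return "hybrid", False
    has_c = any(c == "C-hom" for c in observed)
    has_r = any(c == "R-hom" for c in observed)
    if has_c and has_r:
        return "unknown", True
    return ("C", False) if has_c else ("R", False)


def call_strains(gm: GenotypeMatrix, panel: MarkerPanel) -> list[StrainCall]:
    table = classify_marker_genotypes(gm, panel)
    calls = []
    for sample, row in table.iterrows():
        classes = row.to_dict()
        label, discordant = call_strain(classes)
        n_obs = sum(1 for c in classes.values() if c != "missing")
        calls.append(StrainCall(sample, label, n_obs, classes, discordant))
    return calls


def calls_to_frame(calls: list[StrainCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "label": [c.label for c in calls],
            "n_markers_observed": [c.n_markers_observed for c in calls],
            "discordant": [c.discordant for c in calls],
        }
    )


def round_half_up(x) -> np.ndarray:
    """Integer rounding with .5 going up, as the printed percentages use."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def aggregate_composition(calls: pd.DataFrame, grouping: pd.DataFrame) -> pd.DataFrame:
    """Per-group strain composition with integer percentages.

    ``calls`` needs columns (sample, label); ``grouping`` maps sample ->
    group.  Unknowns are excluded from the denominators; percentages are
    100*count/n rounded half-up.  Empty groups get n=0 and NaN percentages.
    """
    df = calls.merge(grouping, on="sample", how="left")
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample"].tolist()
        raise ValueError(f"samples without a group label: {missing[:5]}")
    rows = []
    for group, sub in df.groupby("group", sort=True):
        called = sub[sub.label != "unknown"]
        n = len(called)
        counts = {lab: int((called.label == lab).sum()) for lab in ("C", "R", "hybrid")}
        row = {"group": group, "n": n, "n_removed": int((sub.label == "unknown").sum()), **{f"n_{k}": v for k, v in counts.items()}}
        for lab in ("C", "R", "hybrid"):
            row[f"pct_{lab}"] = float(round_half_up(100.0 * counts[lab] / n)) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def composition_from_counts(table: pd.DataFrame, by: str = "flyway") -> pd.DataFrame:
    """Aggregate a collection-count table (n_c/n_hybrid/n_r columns) into
    per-group compositions with half-up integer percentages."""
    g = table.groupby(by, sort=True)[["n", "n_c", "n_hybrid", "n_r"]].sum().reset_index()
    for lab, col in (("C", "n_c"), ("R", "n_r"), ("hybrid", "n_hybrid")):
        g[f"pct_{lab}"] = round_half_up(100.0 * g[col] / g["n"])
    return g
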
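"""Windowed differentiation and diversity: between-strain Weir-Cockerham
Fst (per SNP and 10 kb windows), pi and Tajima's D in 5 kb windows for the
combined and per-strain datasets split by autosomes vs Z, and LD decay
over the eleven fixed distance bins."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

import numpy as np
import pandas as pd

from fawpop import popstats
from fawpop.core import Z_CHROM
from fawpop.vcfio import read_vcf


def main() -> None:
    out = results_dir()
    gm = read_vcf(out / "biallelic.vcf")
    calls = pd.read_csv(out / "strain_calls.tsv", sep="\t").set_index("sample").label
    C = [s for s in gm.samples if calls.get(s) == "C"]
    R = [s for s in gm.samples if calls.get(s) == "R"]

    zmask = gm.chrom == Z_CHROM
    gz = gm.take_sites(np.nonzero(zmask)[0])
    ga = gm.take_sites(np.nonzero(~zmask)[0])
    fst_z = popstats.wc_fst(gz, C, R, window_bp=None).weighted
    fst_a = popstats.wc_fst(ga, C, R, window_bp=None).weighted
    print(f"between-strain weighted Fst (hybrids removed): "
          f"Z = {fst_z:.3f}, autosomes = {fst_a:.3f}")

    fst = popstats.wc_fst(gm, C, R, window_bp=10_000)
    fst.per_site.to_csv(out / "fst_per_site.tsv", sep="\t", index=False, float_format="%.6g")
    fst.windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False, float_format="%.6g")

    rows = []
    for label, grp in (("all", list(gm.samples)), ("C", C), ("R", R)):
        pi = popstats.pi_windowed(gm, grp, window_bp=5_000)
        td = popstats.tajimas_d_windowed(gm, grp, window_bp=5_000)
        pi.to_csv(out / f"pi_{label}.tsv", sep="\t", index=False, float_format="%.6g")
        td.to_csv(out / f"tajimas_d_{label}.tsv", sep="\t", index=False, float_format="%.6g")
        for part, sel in (("autosomes", pi.chrom != Z_CHROM), ("Z", pi.chrom == Z_CHROM)):
            tdsel = td.chrom.eq(Z_CHROM) if part == "Z" else td.chrom.ne(Z_CHROM)
            rows.append({
                "dataset": label, "chromosomes": part,
                "median_pi": float(np.nanmedian(pi[sel].pi)),
                "median_tajimas_d": float(np.nanmedian(td[tdsel].tajimas_d)),
            })
        ld = popstats.ld_decay(gm, grp)
        ld.to_csv(out / f"ld_decay_{label}.tsv", sep="\t", index=False, float_format="%.6g")
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "diversity_summary.tsv", sep="\t", index=False, float_format="%.6g")
    print("\nmedian pi and Tajima's D per dataset:")
    print(summary.to_string(index=False))

    ld_all = pd.read_csv(out / "ld_decay_all.tsv", sep="\t")
    print(f"\ncombined-population mean r2 at 10 kb: "
          f"{float(ld_all.loc[ld_all.distance == 10_000, 'mean_r2'].iloc[0]):.3f}")


if __name__ == "__main__":
    main()
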
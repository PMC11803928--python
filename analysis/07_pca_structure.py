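"""smartPCA-style structure analysis on the autosomes, the Z, and the
full SNP set, with pairwise a-priori group Fst (strain, flyway-like
subpopulation, and strain x subpopulation)."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

import numpy as np
import pandas as pd

from fawpop.core import Z_CHROM
from fawpop.pca import pairwise_group_fst, pca
from fawpop.vcfio import read_vcf


def main() -> None:
    out = results_dir()
    gm = read_vcf(out / "biallelic.vcf")
    truth = pd.read_csv(out / "truth_samples.tsv", sep="\t").set_index("sample")

    zmask = gm.chrom == Z_CHROM
    datasets = {
        "all": gm,
        "autosomes": gm.take_sites(np.nonzero(~zmask)[0]),
        "z": gm.take_sites(np.nonzero(zmask)[0]),
    }
    for label, g in datasets.items():
        res = pca(g, k=min(10, g.n_samples - 1), dataset=label)
        res.coords.to_csv(out / f"pca_{label}.tsv", sep="\t", index=False, float_format="%.6g")
        if label == "autosomes":
            pc1 = res.coords.set_index("sample").PC1
            pc2 = res.coords.set_index("sample").PC2
            strain = truth.strain
            c_pc1 = pc1[strain[strain == "C"].index]
            r_pc1 = pc1[strain[strain == "R"].index]
            sep = c_pc1.min() > r_pc1.max() or r_pc1.min() > c_pc1.max()
            print(f"autosomal PCA: PC1 explains {res.pct_variance[0]:.2f}% "
                  f"and separates the strains with zero overlap: {sep}")
            sub = truth[truth.strain == "C"].subpop
            means = pc2[sub.index].groupby(sub).mean()
            print("C-strain subpopulation means on PC2: "
                  + ", ".join(f"{k}={v:.3f}" for k, v in means.items()))

    calls = pd.read_csv(out / "strain_calls.tsv", sep="\t").set_index("sample").label
    groups = {}
    for s in gm.samples:
        if calls.get(s) in ("C", "R"):
            key = f"{calls[s]}_{truth.loc[s, 'subpop']}"
            groups.setdefault(key, []).append(s)
    table = pairwise_group_fst(gm.take_sites(np.nonzero(zmask)[0]), groups)
    table.to_csv(out / "pairwise_fst_z.tsv", sep="\t", float_format="%.6g")
    table_a = pairwise_group_fst(gm.take_sites(np.nonzero(~zmask)[0]), groups)
    table_a.to_csv(out / "pairwise_fst_autosomes.tsv", sep="\t", float_format="%.6g")
    print("\npairwise weighted Fst on the Z (strain x subpopulation groups):")
    print(table.round(3).to_string())


if __name__ == "__main__":
    main()
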
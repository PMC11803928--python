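"""Apply the site-filter chain: per-genotype DP/GQ masking with the >50%
missingness cut, restriction to the 31 chromosomes, then the biallelic
maf >= 0.01 screen used for all structure analyses."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import results_dir

import pandas as pd

from fawpop.filters import filter_biallelic_maf, filter_site_quality, restrict_chromosomes
from fawpop.vcfio import read_vcf, write_vcf


def main() -> None:
    out = results_dir()
    gm = read_vcf(out / "cohort.vcf")
    gm = filter_site_quality(gm, min_depth=6, min_gq=10, max_missing=0.5)
    gm = restrict_chromosomes(gm)
    full = gm.n_sites  # the "full" dataset used by the sweep scans
    write_vcf(gm, out / "full_dataset.vcf")
    gm = filter_biallelic_maf(gm, maf_min=0.01)
    write_vcf(gm, out / "biallelic.vcf")

    log = pd.DataFrame(gm.metadata["filter_log"])
    log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
    print(log.to_string(index=False))
    print(f"full dataset (sweep scans): {full} SNPs; "
          f"biallelic maf>=0.01 dataset (structure): {gm.n_sites} SNPs")


if __name__ == "__main__":
    main()
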
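"""Simulate the two-strain cohort: VCF with DP/GQ noise, truth tables,
and the Z-linked diagnostic marker panel."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import COHORT, results_dir

from fawpop.simulate import degrade, simulate_cohort
from fawpop.vcfio import write_vcf


def main() -> None:
    out = results_dir()
    gm, truth = simulate_cohort(COHORT)
    gm = degrade(gm, COHORT.missing_rate, COHORT.depth_mean, COHORT.gq_mean,
                 seed=COHORT.seed + 1)
    write_vcf(gm, out / "cohort.vcf")
    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
    truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False, float_format="%.6g")
    truth.markers.to_csv(out / "marker_panel.tsv", sep="\t", index=False)

    n_hyb = int((truth.samples.strain == "hybrid").sum())
    print(f"cohort: {gm.n_samples} samples x {gm.n_sites} sites "
          f"({n_hyb} F1 hybrids), missing fraction "
          f"{float((gm.dosage == -1).mean()):.3f}")
    print(f"wrote cohort.vcf, truth tables and {len(truth.markers)}-marker panel to {out}")


if __name__ == "__main__":
    main()
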
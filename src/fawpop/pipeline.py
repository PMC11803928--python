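"""End-to-end pipeline: simulate -> filter -> strain-call -> stats ->
islands -> sweeps -> pca, driven by one declarative config with explicit
seeds, writing TSV/VCF outputs and a manifest of output hashes."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, islands, pca, popstats, strains, sweeps, vcfio
from .core import AUTOSOMES, GenotypeMatrix, Z_CHROM
from .simulate import SimConfig, degrade, simulate_cohort

log = logging.getLogger("fawpop.pipeline")

DEFAULT_CONFIG = {
    "simulate": {"seed": 1},
    "filter": {"min_depth": 6, "min_gq": 10, "max_missing": 0.5, "maf_min": 0.01},
    "stats": {"fst_window_bp": 10_000, "pi_window_bp": 5_000, "dxy_window_bp": 10_000},
    "islands": {"n_perm": 1_000, "bandwidth_bp": 50_000.0, "seed": 11},
    "sweeps": {"grid_bp": 5_000, "fine_bp": 1_000, "outlier_percentile": 99.99,
               "region_percentile": 99.0},
    "pca": {"k": 10},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage declared in ``config``; returns the manifest.

    Any stage failure raises with the stage name.  Rerunning with the same
    config and seeds reproduces byte-identical outputs.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": []}

    def record(stage: str, params: dict, paths: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": {k: v for k, v in params.items() if not isinstance(v, (pd.DataFrame,))},
                "outputs": {p.name: _sha256(p) for p in paths},
            }
        )

    def run_stage(stage, fn):
        log.info("stage %s", stage)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- 1. simulate (or load) --------------------------------------
    sim_params = dict(cfg["simulate"])
    simulate_only = cfg.get("simulate_only", False)

    def stage_simulate():
        sc = SimConfig(**{k: v for k, v in sim_params.items() if k != "degrade"})
        gm, truth = simulate_cohort(sc)
        deg = sim_params.get("degrade", True)
        if deg:
            gm = degrade(gm, sc.missing_rate, sc.depth_mean, sc.gq_mean, seed=sc.seed + 1)
        vcf = out / "cohort.vcf"
        vcfio.write_vcf(gm, vcf)
        truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
        truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False, float_format="%.6g")
        paths = [vcf, out / "truth_samples.tsv", out / "truth_sites.tsv"]
        if truth.markers is not None:
            truth.markers.to_csv(out / "marker_panel.tsv", sep="\t", index=False)
            paths.append(out / "marker_panel.tsv")
        record("simulate", sim_params, paths)
        return gm, truth

    gm, truth = run_stage("simulate", stage_simulate)
    if simulate_only:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest
    lengths = gm.metadata.get("chrom_lengths", {})

    # ---- 2. filter ---------------------------------------------------
    fpar = cfg["filter"]

    def stage_filter():
        g = filters.filter_site_quality(gm, fpar["min_depth"], fpar["min_gq"], fpar["max_missing"])
        g = filters.restrict_chromosomes(g)
        g = filters.filter_biallelic_maf(g, fpar["maf_min"])
        vcf = out / "filtered.vcf"
        vcfio.write_vcf(g, vcf)
        pd.DataFrame(g.metadata.get("filter_log", [])).to_csv(
            out / "filter_log.tsv", sep="\t", index=False
        )
        record("filter", fpar, [vcf, out / "filter_log.tsv"])
        return g

    gm_f = run_stage("filter", stage_filter)

    # ---- 3. strain calling ------------------------------------------
    def stage_strain_call():
        panel = strains.MarkerPanel.from_frame(truth.markers)
        calls = strains.calls_to_frame(strains.call_strains(gm_f, panel))
        grouping = truth.samples.rename(columns={"subpop": "group"})[["sample", "group"]]
        comp = strains.aggregate_composition(calls, grouping)
        calls.to_csv(out / "strain_calls.tsv", sep="\t", index=False)
        comp.to_csv(out / "strain_composition.tsv", sep="\t", index=False)
        record("strain_call", {"n_markers": len(panel.markers)},
               [out / "strain_calls.tsv", out / "strain_composition.tsv"])
        return calls

    calls = run_stage("strain_call", stage_strain_call)

    called = calls.set_index("sample").label
    c_samples = [s for s in gm_f.samples if called.get(s) == "C"]
    r_samples = [s for s in gm_f.samples if called.get(s) == "R"]
    all_samples = list(gm_f.samples)

    # ---- 4. windowed statistics -------------------------------------
    spar = cfg["stats"]

    def stage_stats():
        fst = popstats.wc_fst(gm_f, c_samples, r_samples,
                              window_bp=spar["fst_window_bp"], chrom_lengths=lengths)
        fst.per_site.to_csv(out / "fst_per_site.tsv", sep="\t", index=False, float_format="%.6g")
        fst.windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False, float_format="%.6g")
        paths = [out / "fst_per_site.tsv", out / "fst_windows.tsv"]
        for label, grp in (("all", all_samples), ("C", c_samples), ("R", r_samples)):
            pi = popstats.pi_windowed(gm_f, grp, spar["pi_window_bp"], chrom_lengths=lengths)
            td = popstats.tajimas_d_windowed(gm_f, grp, spar["pi_window_bp"], chrom_lengths=lengths)
            ld = popstats.ld_decay(gm_f, grp)
            for name, df in (("pi", pi), ("tajimas_d", td), ("ld_decay", ld)):
                p = out / f"{name}_{label}.tsv"
                df.to_csv(p, sep="\t", index=False, float_format="%.6g")
                paths.append(p)
        dxy = popstats.dxy_windowed(gm_f, c_samples, r_samples,
                                    spar["dxy_window_bp"], chrom_lengths=lengths)
        dxy.to_csv(out / "dxy_windows.tsv", sep="\t", index=False, float_format="%.6g")
        paths.append(out / "dxy_windows.tsv")
        record("stats", spar, paths)
        return {"weighted_fst": fst.weighted, "dxy": dxy}

    stats_out = run_stage("stats", stage_stats)

    # ---- 5. divergence islands on the Z ------------------------------
    ipar = cfg["islands"]

    def stage_islands():
        dxy_z = stats_out["dxy"]
        dxy_z = dxy_z[dxy_z.chrom == Z_CHROM]
        thr, calls_ = islands.island_permutation_test(
            dxy_z, n_perm=ipar["n_perm"], bandwidth_bp=ipar["bandwidth_bp"], seed=ipar["seed"]
        )
        df = pd.DataFrame([vars(c) for c in calls_])
        df.to_csv(out / "islands.tsv", sep="\t", index=False)
        pd.DataFrame({"chrom": list(thr), "threshold": list(thr.values())}).to_csv(
            out / "island_thresholds.tsv", sep="\t", index=False, float_format="%.6g"
        )
        record("islands", ipar, [out / "islands.tsv", out / "island_thresholds.tsv"])

    run_stage("islands", stage_islands)

    # ---- 6. sweep scans ----------------------------------------------
    wpar = cfg["sweeps"]

    def stage_sweeps():
        paths = []
        populations = {"C": c_samples, "R": r_samples}
        region_rows = []
        for label, grp in populations.items():
            if len(grp) < 4:
                continue
            sfs = sweeps.background_sfs(gm_f, grp)
            grid = sweeps.clr_scan(gm_f, grp, grid_bp=wpar["grid_bp"], sfs=sfs,
                                   chrom_lengths=lengths)
            p = out / f"clr_{label}.tsv"
            grid.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                thr, outliers = sweeps.find_clr_outliers(grid, wpar["outlier_percentile"])
                for _, row in outliers.iterrows():
                    region = sweeps.refine_sweep_region(
                        gm_f, grp, row.chrom, row.pos, fine_bp=wpar["fine_bp"],
                        region_percentile=wpar["region_percentile"], population=label,
                        sfs=sfs, chrom_lengths=lengths,
                    )
                    if region is not None:
                        region_rows.append(vars(region))
            om = sweeps.omega_scan(gm_f, grp, chrom_lengths=lengths)
            p = out / f"omega_{label}.tsv"
            om.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
        pd.DataFrame(region_rows).to_csv(out / "sweep_regions.tsv", sep="\t", index=False)
        paths.append(out / "sweep_regions.tsv")
        record("sweeps", wpar, paths)

    run_stage("sweeps", stage_sweeps)

    # ---- 7. PCA + pairwise group Fst ---------------------------------
    ppar = cfg["pca"]

    def stage_pca():
        paths = []
        auto_mask = gm_f.sites_on(AUTOSOMES)
        datasets = {
            "all": gm_f,
            "autosomes": gm_f.take_sites(np.nonzero(auto_mask)[0]),
            "z": gm_f.take_sites(np.nonzero(~auto_mask)[0]),
        }
        for label, g in datasets.items():
            if g.n_sites == 0:
                continue
            k = min(ppar["k"], g.n_samples - 1)
            res = pca.pca(g, k=k, dataset=label)
            p = out / f"pca_{label}.tsv"
            res.coords.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
        grouping = {"C": c_samples, "R": r_samples}
        table = pca.pairwise_group_fst(gm_f, grouping)
        p = out / "pairwise_fst.tsv"
        table.to_csv(p, sep="\t", float_format="%.6g")
        paths.append(p)
        record("pca", ppar, paths)

    run_stage("pca", stage_pca)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
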
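"""End-to-end driver: simulate -> WMH -> RHI -> connectivity -> voxelwise -> stats.

Every stage writes a JSON report into the run directory; the combined
summary embeds the exact config and its hash so a rerun with the same
config is bit-reproducible (no timestamps are written).  Stage seeds are
derived from the single run seed by fixed offsets.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cs
from . import connseg as cg
from . import io
from . import pat as pr
from . import synthetic as syn
from . import voxelwise as vw
from . import wmh

log = logging.getLogger("endowm.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 7,
    "phantom": {
        "grid_dims": [72, 72, 72],
        "brain_shape": [34.0, 34.0, 34.0],
        "wm_shape": [28.0, 28.0, 28.0],
        "voxel_size": [1.0, 1.0, 1.0],
        "dominant": {"mu": 100.0, "sigma": 10.0},
        "secondary": {"mu": 140.0, "sigma": 15.0},
        "secondary_weight": 0.0,
        "lesions": [
            {"center": [28, 28, 36], "radius": 6.0, "mu": 160.0, "sigma": 8.0},
            {"center": [44, 44, 36], "radius": 5.0, "mu": 160.0, "sigma": 8.0},
        ],
        "frontal_plane": 36,
        "n_bins": 256,
        "k": wmh.WMH_K_DEFAULT,
    },
    "pat": {
        "durations": [60.0, 30.0, 30.0],
        "hyperemia_ratio": 1.73,
        "noise_sd": 0.01,
    },
    "connectivity": {
        "n_subjects": 6,
        "n_seed_voxels": 120,
        "stochastic": True,
        "background_rate": 2.0,
        "targets": [
            {"name": "SFG", "mask_voxel_count": 9000, "mean_count": 60.0, "share": 0.45},
            {"name": "FP", "mask_voxel_count": 6000, "mean_count": 45.0, "share": 0.25},
            {"name": "PrM", "mask_voxel_count": 7000, "mean_count": 35.0, "share": 0.12},
            {"name": "MFG", "mask_voxel_count": 8000, "mean_count": 30.0, "share": 0.08},
            {"name": "IFG", "mask_voxel_count": 5000, "mean_count": 30.0, "share": 0.05},
            {"name": "PrCG", "mask_voxel_count": 7000, "mean_count": 25.0, "share": 0.03},
            {"name": "PoCG", "mask_voxel_count": 7000, "mean_count": 25.0, "share": 0.02},
        ],
        "min_count": 1,
    },
    "voxelwise": {
        "n_voxels": 400,
        "effect_voxels": 40,
        "effect_beta": 0.06,
        "noise_sd": 0.04,
        "n_perm": 500,
        "alpha": 0.05,
        "fa_threshold": vw.SKELETON_FA_THRESHOLD,
    },
    "cohort": {"n": 36},
    "stats": {"outlier_sd": cs.TMT_OUTLIER_SD},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _phantom_spec(cfg: dict, seed: int) -> syn.PhantomSpec:
    return syn.PhantomSpec(
        grid_dims=tuple(cfg["grid_dims"]),
        voxel_size=tuple(cfg["voxel_size"]),
        brain_shape=tuple(cfg["brain_shape"]),
        wm_shape=tuple(cfg["wm_shape"]),
        dominant=syn.GaussianComponent(**cfg["dominant"]),
        secondary=syn.GaussianComponent(**cfg["secondary"]),
        secondary_weight=cfg["secondary_weight"],
        lesions=tuple(
            syn.LesionSpec(tuple(l["center"]), l["radius"], l["mu"], l["sigma"])
            for l in cfg.get("lesions", [])
        ),
        frontal_plane=cfg["frontal_plane"],
        seed=seed,
    )


def run_wmh_stage(cfg: dict, seed: int) -> dict:
    spec = _phantom_spec(cfg, seed)
    phantom = syn.generate_phantom(spec)
    vox_mm3 = io.voxel_volume_mm3(spec.voxel_size)
    hist = wmh.build_histogram(phantom.volume, phantom.wm_mask, n_bins=cfg["n_bins"])
    fit = wmh.fit_two_gaussian(hist)
    thr = wmh.wmh_threshold(fit, k=cfg["k"])
    n_wm = int(phantom.wm_mask.sum())
    res_global = wmh.segment_wmh(
        phantom.volume, phantom.wm_mask, thr, phantom.icv_mm3, vox_mm3
    )
    res_frontal = wmh.segment_wmh(
        phantom.volume, phantom.wm_mask, thr, phantom.icv_mm3, vox_mm3,
        region_mask=phantom.frontal_mask, region_label="frontal",
    )
    return {
        "fit": fit.as_dict(),
        "threshold": thr,
        "icv_mm3": phantom.icv_mm3,
        "global": {
            "voxel_count": res_global.voxel_count,
            "volume_mm3": res_global.volume_mm3,
            "volume_pct_icv": res_global.volume_pct_icv,
            "excess_volume_mm3": wmh.excess_lesion_volume(
                res_global, fit, n_wm, vox_mm3, k=cfg["k"]
            ),
        },
        "frontal": {
            "voxel_count": res_frontal.voxel_count,
            "volume_mm3": res_frontal.volume_mm3,
            "volume_pct_icv": res_frontal.volume_pct_icv,
        },
        "truth_lesion_volume_mm3": phantom.truth_lesion_volume_mm3,
    }


def run_rhi_stage(cfg: dict, seed: int) -> dict:
    spec = syn.PatSpec(
        durations=tuple(cfg["durations"]),
        hyperemia_ratio=cfg["hyperemia_ratio"],
        noise_sd=cfg["noise_sd"],
        seed=seed,
    )
    signal = syn.generate_pat(spec)
    res = pr.compute_rhi(signal)
    out = res.as_dict()
    out["truth_ratio"] = spec.hyperemia_ratio
    return out


def run_connseg_stage(cfg: dict, seed: int) -> dict:
    targets = tuple(
        syn.TargetSpec(t["name"], t["mask_voxel_count"], t["mean_count"])
        for t in cfg["targets"]
    )
    names = [t["name"] for t in cfg["targets"]]
    shares = np.array([t["share"] for t in cfg["targets"]], dtype=float)
    shares = shares / shares.sum()
    rng = np.random.default_rng(seed)

    rows = []
    for s in range(cfg["n_subjects"]):
        truth = tuple(rng.choice(names, size=cfg["n_seed_voxels"], p=shares))
        spec = syn.ConnectivitySpec(
            targets=targets, assignment_truth=truth,
            stochastic=cfg["stochastic"], background_rate=cfg["background_rate"],
            seed=seed + 100 + s,
        )
        conn = syn.generate_connectivity(spec)
        seg = cg.hard_segment(conn, min_count=cfg["min_count"])
        rows.append(cg.normalize_counts(seg))
    per_subject = pd.DataFrame(rows)[names]
    comp = cg.compare_targets(per_subject)
    return {
        "normalized_pct_mean": comp["target_means"],
        "omnibus": comp["omnibus"].as_dict(),
        "pairwise": None if comp["pairwise"] is None else comp["pairwise"].to_dict("records"),
        "n_subjects": cfg["n_subjects"],
    }


def run_voxelwise_stage(cfg: dict, seed: int, cohort_df: pd.DataFrame) -> tuple[dict, vw.ClusterResult]:
    spec = syn.FaDatasetSpec(
        n_subjects=len(cohort_df),
        n_voxels=cfg["n_voxels"],
        effect_voxels=cfg["effect_voxels"],
        effect_beta=cfg["effect_beta"],
        noise_sd=cfg["noise_sd"],
        seed=seed,
    )
    data = syn.generate_fa_dataset(spec, cohort=cohort_df)
    ds = vw.SkeletonDataset.from_fa_dataset(data, fa_threshold=cfg["fa_threshold"])
    result = vw.permutation_fwe(ds, n_perm=cfg["n_perm"], seed=seed)
    cluster = vw.extract_cluster(result, ds, alpha=cfg["alpha"])
    sig = int(cluster.cluster_mask.sum())
    truth = data.truth_effect_mask
    overlap = int((cluster.cluster_mask & truth).sum())
    dice = 2 * overlap / (sig + int(truth.sum())) if (sig + truth.sum()) else 0.0
    report = {
        "n_skeleton_voxels": int(ds.skeleton_mask.sum()),
        "n_significant_voxels": sig,
        "max_abs_t": float(np.nanmax(np.abs(result.t))),
        "min_p_fwe": float(np.nanmin(result.p_fwe)),
        "dice_vs_planted": dice,
        "n_perm": result.n_perm,
    }
    return report, cluster


def run_stats_stage(cfg: dict, cohort_df: pd.DataFrame,
                    cluster_fa: np.ndarray | None = None) -> dict:
    df = cohort_df.copy()
    if cluster_fa is not None:
        df["cluster_fa"] = cluster_fa
    df["tmt_diff_s"] = cs.tmt_score(df["tmt_a_s"], df["tmt_b_s"])
    include = cs.exclude_outliers(df["tmt_diff_s"], sd_cutoff=cfg["outlier_sd"])
    kept = df[include].reset_index(drop=True)

    sex01 = (kept["sex"] == "M").astype(float).to_numpy()
    covs = np.column_stack([kept["age"].to_numpy(), sex01])
    names = ("age", "sex")
    out = {
        "n_total": len(df),
        "n_excluded_outlier": int(len(df) - len(kept)),
        "partial_rhi_tmt": cs.partial_correlation(
            kept["rhi"], kept["tmt_diff_s"], covs, names).as_dict(),
        "partial_fa_tmt": cs.partial_correlation(
            kept["cluster_fa"], kept["tmt_diff_s"], covs, names).as_dict(),
        "partial_rhi_fa": cs.partial_correlation(
            kept["rhi"], kept["cluster_fa"], covs, names).as_dict(),
        "sex_diff_rhi": cs.sex_difference(kept["rhi"], kept["sex"]).as_dict(),
        "summary": cs.summarize_cohort(kept).to_dict("records"),
    }
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/demo") -> dict:
    """Run all stages on synthetic inputs; returns the combined summary.

    ``config`` overrides :data:`DEFAULT_CONFIG` (nested merge).  Per-stage
    JSON reports and the combined ``summary.json`` land in ``out_dir``.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    chash = io.config_hash(cfg)

    summary: dict = {"config": cfg, "config_hash": chash, "seed": seed}

    log.info("stage wmh")
    summary["wmh"] = run_wmh_stage(cfg["phantom"], seed + 1)
    io.write_json(summary["wmh"], out / "wmh.json")

    log.info("stage rhi")
    summary["rhi"] = run_rhi_stage(cfg["pat"], seed + 2)
    io.write_json(summary["rhi"], out / "rhi.json")

    log.info("stage connseg")
    summary["connseg"] = run_connseg_stage(cfg["connectivity"], seed + 3)
    io.write_json(summary["connseg"], out / "connseg.json")

    log.info("stage cohort + voxelwise")
    cohort_df = syn.generate_cohort(syn.CohortSpec(n=cfg["cohort"]["n"], seed=seed + 4))
    io.write_table(cohort_df, out / "cohort.csv")
    summary["voxelwise"], cluster = run_voxelwise_stage(cfg["voxelwise"], seed + 5, cohort_df)
    io.write_json(summary["voxelwise"], out / "voxelwise.json")

    log.info("stage stats")
    summary["stats"] = run_stats_stage(
        cfg["stats"], cohort_df,
        cluster_fa=None if cluster.empty else cluster.subject_mean_fa,
    )
    io.write_json(summary["stats"], out / "stats.json")

    io.write_json(summary, out / "summary.json")
    return summary
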
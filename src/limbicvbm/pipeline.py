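"""End-to-end orchestration: data -> VBM -> covariance -> age -> clinical.

One config (YAML-serialisable) drives every stage; all randomness flows
from a single master seed expanded per stage with numpy's SeedSequence, and
each stage's parameters, seeds and outputs land in a machine-readable JSON
report. Outputs are uncompressed .nii / CSV / JSON so a fixed-seed run is
byte-identical when repeated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age as age_mod
from . import clinical as clin_mod
from . import covariance as cov_mod
from .glm import build_design_matrix, median_split, permutation_cluster_fwe, \
    uncorrected_tmap
from .synthetic import SyntheticConfig, generate_cohort
from .volumes import AtlasLabelMap, BrainMask, extract_roi_mean, load_cohort

logger = logging.getLogger(__name__)

STAGES = ("vbm", "covariance", "age", "clinical")


def _default_stages() -> dict:
    return {name: True for name in STAGES}


@dataclass
class PipelineConfig:
    """Everything needed to (re)run the full analysis."""

    out_dir: str
    mode: str = "synthetic"                   # synthetic | manifest
    master_seed: int = 0
    stages: dict = field(default_factory=_default_stages)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # manifest mode inputs
    manifest_path: str | None = None
    mask_path: str | None = None
    atlas_path: str | None = None
    atlas_lookup_path: str | None = None
    seed_roi_path: str | None = None
    visits_path: str | None = None
    # stage parameters
    vbm: dict = field(default_factory=lambda: dict(
        cluster_forming_t=4.0, n_perm=5000, connectivity=26, alpha=0.05,
        tail="greater", direction="pd_lt_control",
        uncorrected_t=2.8, uncorrected_p=0.005,
        median_split_score="updrs3", median_split_threshold=21.0))
    covariance: dict = field(default_factory=lambda: dict(
        p_cutoff=6e-8, n_repeats=100, correction="fdr", q=0.05,
        cluster_forming_t=4.0, n_perm=1000, connectivity=26))
    age: dict = field(default_factory=lambda: dict(
        cutoff=0.002, min_cluster=20, connectivity=26, q=0.05))
    clinical: dict = field(default_factory=lambda: dict(
        group="pd", scores=["hvlt", "scopa_aut", "stai_state", "updrs1"]))

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["synthetic"]["shape"] = list(doc["synthetic"]["shape"])
        for reg in doc["synthetic"]["regions"]:
            reg["center"] = list(reg["center"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        syn = doc.get("synthetic")
        if isinstance(syn, dict):
            syn = dict(syn)
            syn["shape"] = tuple(syn.get("shape", (32, 32, 32)))
            from .synthetic import ClinicalScoreSpec, RegionSpec
            syn["regions"] = [
                RegionSpec(name=r["name"], center=tuple(r["center"]),
                           radius=r["radius"], role=r["role"])
                for r in syn.get("regions", [])]
            syn["clinical_scores"] = [ClinicalScoreSpec(**s)
                                      for s in syn.get("clinical_scores", [])]
            doc["synthetic"] = SyntheticConfig(**syn)
        return cls(**doc)


def _stage_seeds(master_seed: int) -> dict:
    """One sub-2^31 integer seed per stochastic stage."""
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(len(STAGES) + 1, dtype=np.uint32)
    names = ("data",) + STAGES
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in order; returns the report dict.

    Any stage failure aborts with the stage name attached to the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    report: dict = {"config_mode": config.mode, "master_seed":
                    config.master_seed, "stage_seeds": seeds, "stages": {}}

    stage = "data"
    try:
        stack, atlas, seed_roi, visits, truth = _load_data(config, seeds, out)
        report["stages"]["data"] = {
            "n_subjects": stack.n_subjects,
            "n_control": int((stack.subjects["group"] == "control").sum()),
            "n_pd": int((stack.subjects["group"] == "pd").sum()),
            "n_voxels": stack.n_voxels,
        }
        groups = (stack.subjects["group"] == "pd").to_numpy().astype(int)
        ages = stack.subjects["age"].to_numpy(dtype=float)

        if config.stages.get("vbm", True):
            stage = "vbm"
            report["stages"]["vbm"] = _run_vbm(config, stack, atlas,
                                               seeds["vbm"], out)
        if config.stages.get("covariance", True):
            stage = "covariance"
            report["stages"]["covariance"] = _run_covariance(
                config, stack, groups, seed_roi, atlas,
                seeds["covariance"], out)
        if config.stages.get("age", True):
            stage = "age"
            report["stages"]["age"] = _run_age(config, stack, ages, groups,
                                               atlas, truth, out)
        if config.stages.get("clinical", True):
            stage = "clinical"
            report["stages"]["clinical"] = _run_clinical(config, stack,
                                                         seed_roi, visits,
                                                         out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "report.json")
    return report


def _load_data(config, seeds, out):
    if config.mode == "synthetic":
        syn = dataclasses.replace(config.synthetic, seed=seeds["data"])
        cohort = generate_cohort(syn, out_dir=out / "data")
        stack = cohort.stack()
        atlas = cohort.atlas()
        seed_regions = [r.name for r in syn.regions if r.role == "seed"]
        seed_roi = cohort.region_mask(seed_regions[0]) if seed_regions \
            else None
        return stack, atlas, seed_roi, cohort.visits, cohort.truth
    if config.mode == "manifest":
        mask = BrainMask.load(config.mask_path)
        manifest = pd.read_csv(config.manifest_path)
        stack = load_cohort(manifest, mask)
        atlas = None
        if config.atlas_path and config.atlas_lookup_path:
            atlas = AtlasLabelMap.load(config.atlas_path,
                                       config.atlas_lookup_path)
        seed_roi = BrainMask.load(config.seed_roi_path) \
            if config.seed_roi_path else None
        visits = pd.read_csv(config.visits_path,
                             parse_dates=["visit_date"]) \
            if config.visits_path else None
        return stack, atlas, seed_roi, visits, None
    raise ValueError(f"unknown input mode {config.mode!r}")


def _run_vbm(config, stack, atlas, seed, out):
    p = config.vbm
    design = build_design_matrix(stack.subjects, covariates=("age", "sex"))
    perm = permutation_cluster_fwe(
        stack, design, cluster_forming_t=p["cluster_forming_t"],
        n_perm=p["n_perm"], connectivity=p["connectivity"],
        alpha=p["alpha"], tail=p["tail"], direction=p["direction"],
        seed=seed, atlas=atlas)
    perm.tmap.save(out / "vbm_tmap.nii")
    perm.cluster_table.to_csv(out / "vbm_clusters.csv", index=False)
    with open(out / "vbm_permutation.json", "w") as fh:
        json.dump(perm.to_dict(), fh, indent=2, sort_keys=True)
    unc_map, unc_table = uncorrected_tmap(
        stack, design, t_threshold=p["uncorrected_t"],
        p_threshold=p["uncorrected_p"], connectivity=p["connectivity"],
        atlas=atlas)
    unc_map.save(out / "vbm_uncorrected_tmap.nii")
    unc_table.to_csv(out / "vbm_uncorrected_clusters.csv", index=False)
    pd_subjects = stack.subjects[stack.subjects["group"] == "pd"]
    split_sizes = {}
    if p["median_split_score"] in pd_subjects.columns:
        mild, moderate = median_split(pd_subjects, p["median_split_score"],
                                      p["median_split_threshold"])
        split_sizes = {"mild": len(mild), "moderate": len(moderate)}
    return {
        "params": {k: p[k] for k in ("cluster_forming_t", "n_perm",
                                     "connectivity", "alpha", "tail",
                                     "direction")},
        "seed": seed,
        "clusters": perm.cluster_table.to_dict(orient="records"),
        "n_significant": int(len(perm.significant)),
        "significant_voxels": int(perm.significant["size"].sum())
        if len(perm.significant) else 0,
        "uncorrected_clusters": unc_table.to_dict(orient="records"),
        "median_split": split_sizes,
    }


def _run_covariance(config, stack, groups, seed_roi, atlas, seed, out):
    if seed_roi is None:
        raise ValueError("covariance stage needs a seed ROI")
    p = config.covariance
    seed_vals = extract_roi_mean(stack, seed_roi)
    ctrl = stack.subset(np.flatnonzero(groups == 0))
    pdg = stack.subset(np.flatnonzero(groups == 1))
    cov_ctrl = cov_mod.seed_covariance_map(ctrl, seed_vals[groups == 0],
                                           p_cutoff=p["p_cutoff"])
    cov_ctrl.r.save(out / "cov_control_r.nii")
    n_target = min(ctrl.n_subjects, pdg.n_subjects)
    cov_pd = cov_mod.averaged_seed_covariance(
        pdg, seed_vals[groups == 1], n_target=n_target,
        n_repeats=p["n_repeats"], seed=seed, p_cutoff=p["p_cutoff"])
    cov_pd.r.save(out / "cov_pd_r_mean.nii")
    tmap, table, extras = cov_mod.interaction_difference_map(
        stack, seed_vals, groups, correction=p["correction"], q=p["q"],
        cluster_forming_t=p["cluster_forming_t"], n_perm=p["n_perm"],
        connectivity=p["connectivity"], seed=seed, atlas=atlas)
    tmap.save(out / "cov_interaction_td.nii")
    table.to_csv(out / "cov_interaction_clusters.csv", index=False)
    return {
        "params": {k: p[k] for k in ("p_cutoff", "n_repeats", "correction",
                                     "q")},
        "seed": seed,
        "n_balanced": n_target,
        "clusters": table.to_dict(orient="records"),
        "n_sig_control_voxels": int(np.sum(cov_ctrl.significant))
        if cov_ctrl.significant is not None else None,
    }


def _run_age(config, stack, ages, groups, atlas, truth, out):
    p = config.age
    ctrl = stack.subset(np.flatnonzero(groups == 0))
    pdg = stack.subset(np.flatnonzero(groups == 1))
    s_ctrl = age_mod.age_slope_map(ctrl, ages[groups == 0])
    s_pd = age_mod.age_slope_map(pdg, ages[groups == 1])
    s_ctrl.save(out / "age_slope_control.nii")
    s_pd.save(out / "age_slope_pd.nii")
    dmap, table = age_mod.slope_difference_map(
        s_pd, s_ctrl, cutoff=p["cutoff"], min_cluster=p["min_cluster"],
        connectivity=p["connectivity"], atlas=atlas)
    dmap.save(out / "age_slope_difference.nii")
    table.to_csv(out / "age_difference_clusters.csv", index=False)
    # ROI post-hoc comparison over atlas-named planted regions when known
    rois = {}
    if truth is not None:
        from .volumes import BrainMask as _BM
        for name, m in truth["region_masks"].items():
            rois[name] = _BM(np.asarray(m), stack.mask.affine)
    roi_table = age_mod.roi_slope_comparison(stack, ages, groups, rois) \
        if rois else pd.DataFrame()
    if len(roi_table):
        roi_table.to_csv(out / "age_roi_slopes.csv", index=False)
    tmap, reject, extras = age_mod.age_interaction_test(stack, ages, groups,
                                                        q=p["q"])
    tmap.save(out / "age_interaction_td.nii")
    return {
        "params": dict(p),
        "clusters": table.to_dict(orient="records"),
        "roi_slopes": roi_table.to_dict(orient="records"),
        "n_fdr_significant": int(reject.sum()),
    }


def _run_clinical(config, stack, seed_roi, visits, out):
    if seed_roi is None or visits is None:
        raise ValueError("clinical stage needs a seed ROI and a visit table")
    p = config.clinical
    subjects = stack.subjects
    sel = subjects["group"] == p["group"] if p["group"] != "all" \
        else pd.Series(True, index=subjects.index)
    roi_means = pd.Series(extract_roi_mean(stack, seed_roi),
                          index=subjects["subject_id"])
    roi_means = roi_means[sel.to_numpy()]
    scan_dates = subjects.loc[sel, ["subject_id", "scan_date"]] \
        .set_index("subject_id")["scan_date"]
    matched = clin_mod.match_nearest_visit(
        visits[visits["subject_id"].isin(scan_dates.index)], scan_dates,
        scores=p["scores"])
    matched.to_csv(out / "clinical_matched.csv", index=False)
    rows = []
    sub = subjects.set_index("subject_id").loc[roi_means.index]
    for score in p["scores"]:
        r, pv, n = clin_mod.correlate_roi_score(roi_means, matched, score)
        msel = matched[(matched["score"] == score) &
                       (matched["provenance"] != "missing")]
        msel = msel[msel["subject_id"].isin(roi_means.index)]
        ids = msel["subject_id"]
        t_adj, p_adj, coef = clin_mod.adjusted_association(
            roi_means.loc[ids].to_numpy(),
            msel["value"].to_numpy(dtype=float),
            sub.loc[ids, "age"].to_numpy(),
            sub.loc[ids, "sex"].to_numpy())
        rows.append({"score": score, "r": r, "p": pv, "n": n,
                     "t_adjusted": t_adj, "p_adjusted": p_adj,
                     "coef_adjusted": coef})
    table = pd.DataFrame(rows)
    table.to_csv(out / "clinical_associations.csv", index=False)
    return {"group": p["group"],
            "associations": table.to_dict(orient="records")}
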
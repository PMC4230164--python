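"""End-to-end pipelines binding simulation, GLM, decoding and inference.

``PipelineConfig`` is a flat, fully serializable description of a complete
analysis: cohort, acquisition, GLM, searchlight, and inference parameters,
with defaults matching the study design the package emulates (8 runs,
16-s blocks, 4-mm FWHM, 128-s high-pass, 10-mm searchlight, alpha 0.05).
``run_all`` executes dataset -> betas -> accuracy maps -> group and
univariate inference, caching subject-level intermediates keyed by a config
checksum so interrupted runs resume without recomputation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as rio
from .design import make_design
from .inference import PermutationScheme, permutation_correct
from .searchlight import SearchlightConfig, searchlight_map
from .simulate import CohortSpec, NoiseParams, default_ground_truth, simulate_cohort
from .univariate import (SensitivityReport, group_univariate_contrast,
                         sensitivity_experiment, subject_betas)
from .glm import per_run_contrast

logger = logging.getLogger(__name__)

# the five category pairs analyzed (body vs body_part is not)
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("face", "object"), ("face", "body"), ("face", "body_part"),
    ("object", "body"), ("object", "body_part"))

ALL_PAIRS: tuple[tuple[str, str], ...] = DEFAULT_PAIRS + (("body", "body_part"),)


@dataclass
class PipelineConfig:
    # cohort
    n_controls: int = 10
    n_cps: int = 7
    seed: int = 0
    mean_amplitude: float = 2.0
    pattern_sd: float = 0.5
    cp_separability_factor: float = 0.3
    cp_amplitude_factor: float = 1.0
    face_amplitude_offset: float = 0.0
    white_sd: float = 1.0
    drift_amplitude: float = 1.0
    ar1_coefficient: float = 0.3
    # acquisition / design
    grid_dims: tuple[int, int, int] = (24, 28, 16)
    voxel_size_mm: tuple[float, float, float] = (1.4, 1.4, 2.0)
    tr_s: float = 3.0
    n_volumes_per_run: int = 112
    n_runs: int = 8
    block_duration_s: float = 16.0
    # GLM
    fwhm_mm: float = 4.0
    double_smooth: bool = False
    cutoff_s: float = 128.0
    # searchlight
    radius_mm: float = 10.0
    svm_cost: float = 1.0
    min_sphere_voxels: int = 2
    # inference
    n_permutations: int = 1000
    cluster_forming_p: float = 0.001
    alpha: float = 0.05
    connectivity: int = 18
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["pairs"] = [list(p) for p in self.pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_dims", "voxel_size_mm"):
            if key in d:
                d[key] = tuple(d[key])
        if "pairs" in d:
            d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        return cls(**d)

    def checksum(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def make_design(self):
        return make_design({
            "grid_dims": self.grid_dims, "voxel_size_mm": self.voxel_size_mm,
            "tr_s": self.tr_s, "n_volumes_per_run": self.n_volumes_per_run,
            "n_runs": self.n_runs, "block_duration_s": self.block_duration_s})

    def cohort_spec(self) -> CohortSpec:
        design = self.make_design()
        offsets = {"face": self.face_amplitude_offset} \
            if self.face_amplitude_offset else None
        truth = default_ground_truth(
            design, seed=self.seed, mean_amplitude=self.mean_amplitude,
            pattern_sd=self.pattern_sd,
            cp_separability_factor=self.cp_separability_factor,
            cp_amplitude_factor=self.cp_amplitude_factor,
            category_amplitude_offsets=offsets)
        noise = NoiseParams(self.white_sd, self.drift_amplitude,
                            self.ar1_coefficient, self.seed)
        return CohortSpec(self.n_controls, self.n_cps, design, truth, noise)

    def searchlight_config(self) -> SearchlightConfig:
        return SearchlightConfig(radius_mm=self.radius_mm,
                                 svm_cost=self.svm_cost,
                                 min_sphere_voxels=self.min_sphere_voxels)


def cmd_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate and write the synthetic cohort; logs seed and layout."""
    spec = config.cohort_spec()
    logger.info("simulating cohort: %d controls + %d CPs, seed %d",
                spec.n_controls, spec.n_cps, config.seed)
    root = simulate_cohort(spec, out_dir)
    rio.dump_config(config.to_dict(), Path(root) / "pipeline_config.yaml")
    return root


def run_all(config: PipelineConfig, dataset_dir: str | Path,
            out_dir: str | Path) -> dict:
    """Full analysis tree from an on-disk cohort.

    Per subject: smoothed GLM betas, then one accuracy map per category pair;
    group level: within-group one-sample (vs 50% chance) and between-group
    two-sample cluster tables per pair; univariate arm: Welch group test on
    face-minus-object contrasts; finally the sensitivity report and a
    provenance JSON from which every output can be regenerated.
    """
    dataset_dir, out = Path(dataset_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = rio.load_manifest(dataset_dir)
    design = config.make_design()
    geom = design.geometry
    affine = geom.affine()
    mask, _ = rio.load_nifti(dataset_dir / "brain_mask.nii.gz")
    mask = mask.astype(bool)
    slcfg = config.searchlight_config()
    checksum = config.checksum()
    cache = out / "cache"
    cache.mkdir(exist_ok=True)

    logger.info("run-all: radius %.1f mm, FWHM %.1f mm, cutoff %.0f s, "
                "alpha %.2f, %d permutations", config.radius_mm,
                config.fwhm_mm, config.cutoff_s, config.alpha,
                config.n_permutations)

    acc_maps: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in config.pairs}
    contrasts, groups = [], []
    for sub, runs in rio.iter_subject_runs(dataset_dir):
        sid = sub["id"]
        cpath = cache / f"{sid}_{checksum}.npz"
        if cpath.exists():
            blob = np.load(cpath)
            beta_stack = blob["betas"]
            acc_stack = {tuple(p.split("__")): blob[p] for p in blob.files
                         if "__" in p}
        else:
            betas = subject_betas(runs, design, mask, config.fwhm_mm,
                                  config.double_smooth, config.cutoff_s)
            beta_stack = betas.data
            acc_stack = {}
            for pair in config.pairs:
                am = searchlight_map(betas, pair, mask=mask, config=slcfg,
                                     subject_id=sid)
                acc_stack[pair] = am.data
            np.savez_compressed(
                cpath, betas=beta_stack,
                **{f"{a}__{b}": m for (a, b), m in acc_stack.items()})
        from .glm import BetaImages
        betas = BetaImages(beta_stack, tuple(design.condition_names), mask,
                           voxel_size_mm=geom.voxel_size_mm)
        for pair in config.pairs:
            key = tuple(sorted(pair))
            acc_maps[pair].append(acc_stack[key if key in acc_stack else pair])
            rio.save_nifti(acc_maps[pair][-1], affine,
                           out / "accuracy" / f"{sid}_{pair[0]}-{pair[1]}.nii.gz",
                           sidecar={"subject": sid, "pair": list(pair),
                                    "radius_mm": config.radius_mm,
                                    "classifier": "linear_svm",
                                    "svm_cost": config.svm_cost,
                                    "folds": geom.n_runs})
        contrasts.append(per_run_contrast(betas, ("face", "object")).mean(axis=0))
        groups.append(sub["group"])

    results: dict = {"pairs": {}, "config": config.to_dict()}
    for pair in config.pairs:
        name = f"{pair[0]}-{pair[1]}"
        acc = np.asarray(acc_maps[pair])
        is_ctrl = np.array([g == "control" for g in groups])
        tables = {}
        for gname, sel in (("control", is_ctrl), ("cp", ~is_ctrl)):
            stat, thr, table = permutation_correct(
                acc[sel], PermutationScheme(config.n_permutations,
                                            config.seed + 7, "sign_flip"),
                config.cluster_forming_p, config.alpha, null_value=0.5,
                mask=mask, connectivity=config.connectivity, affine=affine)
            rio.save_nifti(stat.data, affine,
                           out / "group" / f"{name}_{gname}_tmap.nii.gz",
                           sidecar={"df": stat.df, "tail": stat.tail,
                                    "test": stat.test, "null_value": 0.5,
                                    "voxel_fwe_threshold": thr})
            rio.write_cluster_table(
                table, out / "group" / f"{name}_{gname}_clusters.tsv")
            tables[gname] = {"voxel_fwe_threshold": thr,
                             "n_clusters": int(len(table))}
        stat, thr, table = permutation_correct(
            acc[is_ctrl], PermutationScheme(config.n_permutations,
                                            config.seed + 11, "label_shuffle"),
            config.cluster_forming_p, config.alpha, maps_b=acc[~is_ctrl],
            mask=mask, equal_variance=True, connectivity=config.connectivity,
            affine=affine)
        rio.save_nifti(stat.data, affine,
                       out / "group" / f"{name}_between_tmap.nii.gz",
                       sidecar={"df": stat.df, "tail": stat.tail,
                                "test": stat.test,
                                "voxel_fwe_threshold": thr})
        rio.write_cluster_table(table,
                                out / "group" / f"{name}_between_clusters.tsv")
        min_p = float(table["p_corrected"].min()) if len(table) else 1.0
        tables["between"] = {"voxel_fwe_threshold": thr,
                             "n_clusters": int(len(table)),
                             "min_corrected_p": min_p}
        results["pairs"][name] = tables

    uni_stat, uni_thr, uni_table = group_univariate_contrast(
        np.asarray(contrasts), groups,
        PermutationScheme(config.n_permutations, config.seed + 13,
                          "label_shuffle"),
        config.cluster_forming_p, config.alpha, mask=mask,
        connectivity=config.connectivity, affine=affine)
    rio.save_nifti(uni_stat.data, affine,
                   out / "univariate" / "face-object_between_tmap.nii.gz",
                   sidecar={"df": "welch_per_voxel", "tail": uni_stat.tail,
                            "test": uni_stat.test,
                            "voxel_fwe_threshold": uni_thr})
    rio.write_cluster_table(uni_table,
                            out / "univariate" / "face-object_between_clusters.tsv")
    uni_p = float(uni_table["p_corrected"].min()) if len(uni_table) else 1.0

    mvpa_fo = results["pairs"].get("face-object", {}).get("between", {})
    mvpa_p = mvpa_fo.get("min_corrected_p", 1.0)
    report = SensitivityReport(
        mvpa_min_p=mvpa_p, mvpa_detected=mvpa_p <= config.alpha,
        univariate_min_p=uni_p, univariate_detected=uni_p <= config.alpha,
        alpha=config.alpha, config=config.to_dict())
    (out / "sensitivity_report.json").write_text(report.to_json(indent=2))
    (out / "sensitivity_report.txt").write_text(report.summary() + "\n")
    results["sensitivity"] = json.loads(report.to_json())

    provenance = {"config": config.to_dict(), "config_checksum": checksum,
                  "dataset_manifest": manifest}
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=rio._jsonable))
    return results
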
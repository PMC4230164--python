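"""Synthetic two-group block-design fMRI cohorts with known ground truth.

The generator emulates the study design downstream stages are built for:
two groups (10 controls, 7 congenital-prosopagnosia-like "CP" subjects),
8 runs of 112 volumes (TR 3 s), four stimulus categories in 16-s blocks, on
an anisotropic 1.4 x 1.4 x 2.0 mm voxel grid. Category-specific multivoxel
patterns are implanted in spherical "informative" regions; the group effect
is a reduction of the face-vs-object *pattern* separability in the CP group
at matched mean amplitude, so a purely amplitude-based (univariate) analysis
carries no group signal by construction.

Voxel time series follow
    baseline + sum_blocks(pattern weight x boxcar (*) HRF) + drift + AR(1) noise,
with cosine drift confined to periods above the analysis high-pass cutoff.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .design import ExperimentDesign, make_design
from .glm import build_design_matrix
from .hrf import HrfParams

BASELINE = 100.0  # arbitrary raw-signal units


@dataclass(frozen=True)
class NoiseParams:
    white_sd: float = 1.0
    drift_amplitude: float = 1.0
    ar1_coefficient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite([self.white_sd, self.drift_amplitude,
                            self.ar1_coefficient]).all():
            raise ValueError("noise parameters must be finite")
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


_PATTERN_STREAM = 104729  # salt separating pattern RNG from noise RNG


@dataclass
class GroundTruth:
    """Implanted informative regions and their generative parameters.

    ``patterns[name][category]`` holds the mean-centered template multivoxel
    pattern over that ROI's voxels; the full weight map for a voxel is
    ``mean_amplitude + pattern``. CP subjects shrink the face and object
    patterns toward their common mean by ``cp_separability_factor`` (1 = no
    group effect, 0 = identical face/object patterns) and scale the common
    amplitude by ``cp_amplitude_factor`` (1 = amplitude-matched groups).

    With ``subject_specific_patterns`` (the default) each subject's pattern
    is an independent draw from the same distribution — same ROIs, same
    ``pattern_sd``, same shrinkage — emulating the between-subject
    variability of pattern topography in real cohorts. Decoding accuracy is
    then spatially aligned across subjects (the ROIs are shared) while the
    voxelwise group-mean of any contrast cancels, which is what renders a
    mean-amplitude analysis blind to the pattern effect. Setting the flag
    False makes every subject use the stored template.
    """

    roi_masks: dict[str, np.ndarray]
    patterns: dict[str, dict[str, np.ndarray]]
    mean_amplitude: float
    pattern_sd: float = 0.0
    cp_separability_factor: float = 1.0
    cp_amplitude_factor: float = 1.0
    # extra mean response per category (e.g. a face-selective amplitude
    # bonus); nonzero offsets break the amplitude matching on purpose and
    # give the univariate contrast something to detect
    category_amplitude_offsets: dict[str, float] = field(default_factory=dict)
    subject_specific_patterns: bool = True
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.cp_separability_factor <= 1:
            raise ValueError("cp_separability_factor must lie in [0, 1]")
        if self.brain_mask is not None:
            for name, m in self.roi_masks.items():
                if np.any(m & ~self.brain_mask):
                    raise ValueError(f"ROI {name!r} extends outside the brain mask")

    def subject_patterns(self, categories: Sequence[str],
                         subject_seed: int | None) -> dict[str, dict[str, np.ndarray]]:
        """This subject's mean-centered per-ROI patterns (control parameterization)."""
        if subject_seed is None or not self.subject_specific_patterns:
            return {name: {c: self.patterns[name][c].copy() for c in categories}
                    for name in self.roi_masks}
        rng = np.random.default_rng(
            np.random.SeedSequence([int(subject_seed), _PATTERN_STREAM]))
        out: dict[str, dict[str, np.ndarray]] = {}
        for name, mask in self.roi_masks.items():
            n = int(mask.sum())
            pats = {}
            for c in categories:
                p = rng.normal(0.0, self.pattern_sd, size=n)
                pats[c] = p - p.mean()
            out[name] = pats
        return out

    def weight_maps(self, group: str, categories: Sequence[str],
                    subject_seed: int | None = None) -> np.ndarray:
        """Per-category voxelwise weights, shape (n_categories, nx, ny, nz)."""
        if group not in ("control", "cp"):
            raise ValueError(f"unknown group {group!r}")
        grid = next(iter(self.roi_masks.values())).shape if self.roi_masks else None
        if grid is None:
            raise ValueError("ground truth has no ROIs")
        amp = self.mean_amplitude
        if group == "cp":
            amp *= self.cp_amplitude_factor
        out = np.zeros((len(categories),) + grid)
        subject_pats = self.subject_patterns(categories, subject_seed)
        for name, mask in self.roi_masks.items():
            pats = subject_pats[name]
            if group == "cp" and self.cp_separability_factor != 1.0:
                f = self.cp_separability_factor
                m = 0.5 * (pats["face"] + pats["object"])
                pats["face"] = m + f * (pats["face"] - m)
                pats["object"] = m + f * (pats["object"] - m)
            for ci, c in enumerate(categories):
                off = self.category_amplitude_offsets.get(c, 0.0)
                if group == "cp":
                    off *= self.cp_amplitude_factor
                out[ci][mask] = amp + off + pats[c]
        return out


@dataclass
class CohortSpec:
    n_controls: int = 10
    n_cps: int = 7
    design: ExperimentDesign = field(default_factory=make_design)
    truth: GroundTruth | None = None
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_cps < 2:
            raise ValueError("need >= 2 subjects per group for group statistics")
        if self.truth is None:
            self.truth = default_ground_truth(self.design, seed=self.noise.seed)

    @property
    def groups(self) -> list[str]:
        return ["control"] * self.n_controls + ["cp"] * self.n_cps

    def subject_seed(self, index: int) -> int:
        ss = np.random.SeedSequence([int(self.noise.seed), int(index)])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def ellipsoid_brain_mask(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """The inscribed ellipsoid of the grid — a desk-scale brain-mask stand-in."""
    axes = [(np.arange(d) - (d - 1) / 2) / (d / 2) for d in grid_dims]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx ** 2 + yy ** 2 + zz ** 2 <= 1.0


def make_ground_truth(geometry, roi_specs: Sequence[tuple[str, tuple[int, int, int], float]],
                      mean_amplitude: float = 2.0, pattern_sd: float = 0.5,
                      cp_separability_factor: float = 1.0,
                      cp_amplitude_factor: float = 1.0,
                      category_amplitude_offsets: Mapping[str, float] | None = None,
                      seed: int = 0,
                      subject_specific_patterns: bool = True,
                      brain_mask: np.ndarray | None = None,
                      categories: Sequence[str] | None = None) -> GroundTruth:
    """Implant spherical informative regions with reproducible random patterns.

    ``roi_specs`` is a list of (name, center voxel index, radius in mm).
    Patterns are drawn N(0, pattern_sd) per voxel and category, then
    mean-centered within each ROI, so every category's ROI-mean response
    equals ``mean_amplitude`` exactly — amplitude matching by construction.
    """
    from .design import STIMULUS_CATEGORIES

    categories = tuple(categories or STIMULUS_CATEGORIES)
    dims = geometry.grid_dims
    vox = np.asarray(geometry.voxel_size_mm)
    if brain_mask is None:
        brain_mask = ellipsoid_brain_mask(dims)
    rng = np.random.default_rng(seed)
    roi_masks: dict[str, np.ndarray] = {}
    patterns: dict[str, dict[str, np.ndarray]] = {}
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    claimed = np.zeros(dims, dtype=bool)
    for name, center, radius_mm in roi_specs:
        if any(not 0 <= c < d for c, d in zip(center, dims)):
            raise ValueError(f"ROI {name!r} center {center} outside grid {dims}")
        d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, vox))
        # ROIs are kept disjoint (earlier specs claim shared voxels) so that
        # per-ROI mean-centering — hence amplitude matching — holds exactly
        mask = (d2 <= radius_mm ** 2) & brain_mask & ~claimed
        claimed |= mask
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} is empty")
        roi_masks[name] = mask
        pats = {}
        for c in categories:
            p = rng.normal(0.0, pattern_sd, size=n)
            pats[c] = p - p.mean()
        patterns[name] = pats
    return GroundTruth(roi_masks=roi_masks, patterns=patterns,
                       mean_amplitude=mean_amplitude, pattern_sd=pattern_sd,
                       cp_separability_factor=cp_separability_factor,
                       cp_amplitude_factor=cp_amplitude_factor,
                       category_amplitude_offsets=dict(category_amplitude_offsets or {}),
                       subject_specific_patterns=subject_specific_patterns,
                       brain_mask=brain_mask)


def default_roi_specs(grid_dims: tuple[int, int, int]):
    """Two 6-mm spheres standing in for lateral-occipital / fusiform face areas."""
    nx, ny, nz = grid_dims
    return [
        ("roi_OFA_like", (int(nx * 0.3), int(ny * 0.33), nz // 2), 6.0),
        ("roi_FFA_like", (int(nx * 0.67), int(ny * 0.64), nz // 2), 6.0),
    ]


def default_ground_truth(design: ExperimentDesign, seed: int = 0,
                         **kwargs) -> GroundTruth:
    geom = design.geometry
    return make_ground_truth(geom, default_roi_specs(geom.grid_dims),
                             seed=seed, categories=design.condition_names,
                             **kwargs)


def condition_regressors(design: ExperimentDesign,
                         hrf: HrfParams | None = None) -> np.ndarray:
    """HRF-convolved block regressors, shape (n_runs, n_categories, n_scans)."""
    X = build_design_matrix(design, hrf)
    geom = design.geometry
    n = geom.n_volumes_per_run
    out = np.zeros((geom.n_runs, len(design.condition_names), n))
    for run in range(geom.n_runs):
        for ci, cond in enumerate(design.condition_names):
            col = X.values[:, X.column_index(cond, run)]
            out[run, ci] = col[run * n:(run + 1) * n]
    return out


def simulate_subject(design: ExperimentDesign, truth: GroundTruth, group: str,
                     noise: NoiseParams, subject_seed: int,
                     hrf: HrfParams | None = None) -> list[np.ndarray]:
    """Simulate one subject: a list of (nx, ny, nz, n_scans) run volumes.

    Identical seeds reproduce the volumes bit for bit.
    """
    geom = design.geometry
    weights = truth.weight_maps(group, design.condition_names, subject_seed)
    regs = condition_regressors(design, hrf)
    rng = np.random.default_rng(subject_seed)
    dims = geom.grid_dims
    n_vox = int(np.prod(dims))
    n_scans = geom.n_volumes_per_run
    drift_basis = _drift_basis(n_scans, geom.tr_s)
    W = weights.reshape(len(design.condition_names), n_vox)

    runs = []
    for run in range(geom.n_runs):
        signal = W.T @ regs[run]  # (n_vox, n_scans)
        signal += BASELINE
        if noise.drift_amplitude > 0 and drift_basis.shape[1] > 0:
            coefs = rng.normal(0.0, noise.drift_amplitude,
                               size=(n_vox, drift_basis.shape[1]))
            signal += coefs @ drift_basis.T
        if noise.white_sd > 0:
            a = noise.ar1_coefficient
            w = rng.normal(0.0, noise.white_sd * np.sqrt(1 - a ** 2),
                           size=(n_vox, n_scans))
            if a > 0:
                # stationary AR(1): e_t = a e_{t-1} + w_t
                w[:, 0] /= np.sqrt(1 - a ** 2)
                signal += lfilter([1.0], [1.0, -a], w, axis=1)
            else:
                signal += w
        runs.append(np.ascontiguousarray(signal.reshape(dims + (n_scans,))))
    return runs


def _drift_basis(n_scans: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Unit-norm cosine drift components with period > cutoff_s (no constant)."""
    from .preprocess import dct_highpass_basis

    basis = dct_highpass_basis(n_scans, tr_s, cutoff_s)
    return basis[:, 1:] * np.sqrt(n_scans / 2.0)


def simulate_cohort(spec: CohortSpec, out_dir: str | Path,
                    hrf: HrfParams | None = None) -> Path:
    """Write a BIDS-flavoured cohort to disk and return its root.

    Layout: ``sub-XX/func/sub-XX_task-blocks_run-RR_bold.nii.gz`` with a
    matching ``..._events.tsv`` per run, a brain-mask NIfTI, a ground-truth
    bundle (ROI masks + generative parameters), and ``manifest.json`` with
    group membership and per-subject seeds. Partial output is removed on
    failure.
    """
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = False
    try:
        geom = spec.design.geometry
        affine = geom.affine()
        truth = spec.truth
        brain = truth.brain_mask if truth.brain_mask is not None \
            else ellipsoid_brain_mask(geom.grid_dims)
        _save_nifti(brain.astype(np.uint8), affine, out / "brain_mask.nii.gz")

        gt_dir = out / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        for name, m in truth.roi_masks.items():
            _save_nifti(m.astype(np.uint8), affine, gt_dir / f"{name}_mask.nii.gz")
        for group in ("control", "cp"):
            wm = truth.weight_maps(group, spec.design.condition_names)
            for ci, cond in enumerate(spec.design.condition_names):
                _save_nifti(wm[ci], affine,
                            gt_dir / f"group-{group}_cond-{cond}_template_weights.nii.gz")
        (gt_dir / "params.json").write_text(json.dumps({
            "mean_amplitude": truth.mean_amplitude,
            "pattern_sd": truth.pattern_sd,
            "subject_specific_patterns": truth.subject_specific_patterns,
            "cp_separability_factor": truth.cp_separability_factor,
            "cp_amplitude_factor": truth.cp_amplitude_factor,
            "rois": sorted(truth.roi_masks),
        }, indent=2))

        subjects = []
        for idx, group in enumerate(spec.groups):
            sub = f"sub-{idx + 1:02d}"
            func = out / sub / "func"
            func.mkdir(parents=True, exist_ok=True)
            seed = spec.subject_seed(idx)
            vols = simulate_subject(spec.design, truth, group, spec.noise,
                                    seed, hrf)
            run_files = []
            for run, vol in enumerate(vols):
                stem = f"{sub}_task-blocks_run-{run + 1:02d}"
                _save_nifti(vol.astype(np.float32), affine,
                            func / f"{stem}_bold.nii.gz")
                evs = pd.DataFrame(
                    [{"onset": e.onset_s, "duration": e.duration_s,
                      "trial_type": e.condition}
                     for e in sorted(spec.design.run_events(run),
                                     key=lambda e: e.onset_s)])
                evs.to_csv(func / f"{stem}_events.tsv", sep="\t", index=False)
                run_files.append(str(Path(sub) / "func" / f"{stem}_bold.nii.gz"))
            subjects.append({"id": sub, "group": group, "seed": seed,
                             "runs": run_files})
        manifest = {
            "n_controls": spec.n_controls,
            "n_cps": spec.n_cps,
            "tr_s": geom.tr_s,
            "grid_dims": list(geom.grid_dims),
            "voxel_size_mm": list(geom.voxel_size_mm),
            "master_seed": spec.noise.seed,
            "noise": {"white_sd": spec.noise.white_sd,
                      "drift_amplitude": spec.noise.drift_amplitude,
                      "ar1_coefficient": spec.noise.ar1_coefficient},
            "subjects": subjects,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        created = True
        return out
    finally:
        if not created:
            shutil.rmtree(out, ignore_errors=True)


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data), affine)
    # mtime=0 in the gzip header keeps regenerated files byte-identical
    nib.save(img, str(path))
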
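"""Mass-univariate comparison arm and the MVPA-vs-univariate sensitivity experiment.

The univariate path asks the classical question — where is the *mean* BOLD
response to faces larger than to objects? — at the single-subject level
(t over the 8 per-run contrast values per voxel, FWE-corrected) and at the
group level (two-sample Welch t on subject contrast images with permutation
cluster correction). Because the synthetic group effect is a pure pattern-
separability change at matched mean amplitude, the univariate group
comparison is blind to it in expectation, while the searchlight decoding
path is not; ``sensitivity_experiment`` runs both paths on the same cohort
and reports which detects the group difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import ExperimentDesign
from .glm import BetaImages, build_design_matrix, fit_glm, per_run_contrast
from .hrf import HrfParams
from .inference import (PermutationScheme, StatMap, critical_t,
                        one_sample_t_map, permutation_correct)
from .preprocess import gaussian_smooth
from .searchlight import SearchlightConfig, searchlight_map
from .simulate import CohortSpec, ellipsoid_brain_mask, simulate_subject


@dataclass
class RegionPresence:
    """Supra-threshold presence of named regions in one subject's contrast map."""

    subject_id: str | None
    regions: dict[str, tuple[bool, float]]  # name -> (present, peak t inside)

    def present(self, name: str) -> bool:
        return self.regions[name][0]


@dataclass
class SensitivityReport:
    mvpa_min_p: float
    mvpa_detected: bool
    univariate_min_p: float
    univariate_detected: bool
    alpha: float
    config: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "mvpa_group_difference": {"min_corrected_p": self.mvpa_min_p,
                                      "detected": self.mvpa_detected},
            "univariate_group_difference": {
                "min_corrected_p": self.univariate_min_p,
                "detected": self.univariate_detected},
            "alpha": self.alpha,
            "config": self.config,
        }, **kwargs)

    def summary(self) -> str:
        def line(name, p, det):
            verdict = "DETECTED" if det else "not detected"
            return f"  {name:<28s} min corrected p = {p:.4f}  -> {verdict}"
        return "\n".join([
            f"Group difference at alpha = {self.alpha}:",
            line("searchlight MVPA", self.mvpa_min_p, self.mvpa_detected),
            line("mass-univariate contrast", self.univariate_min_p,
                 self.univariate_detected),
        ])


def subject_betas(runs: Sequence[np.ndarray], design: ExperimentDesign,
                  mask: np.ndarray | None = None, fwhm_mm: float = 4.0,
                  double_smooth: bool = False, cutoff_s: float = 128.0,
                  hrf: HrfParams | None = None) -> BetaImages:
    """Preprocess (Gaussian smooth) and fit the block GLM for one subject.

    ``double_smooth`` applies the 4-mm kernel a second time, mimicking the
    reading that decoding ran on preprocessed images smoothed once more.
    """
    geom = design.geometry
    if mask is None:
        mask = ellipsoid_brain_mask(geom.grid_dims)
    passes = (2 if double_smooth else 1) if fwhm_mm > 0 else 0
    smoothed = []
    for vol in runs:
        v = np.asarray(vol, dtype=float)
        for _ in range(passes):
            v = gaussian_smooth(v, fwhm_mm, geom.voxel_size_mm)
        smoothed.append(v)
    X = build_design_matrix(design, hrf)
    return fit_glm(smoothed, X, mask, geom.tr_s, cutoff_s,
                   voxel_size_mm=geom.voxel_size_mm)


def single_subject_contrast_test(runs: Sequence[np.ndarray],
                                 design: ExperimentDesign,
                                 pair: tuple[str, str] = ("face", "object"),
                                 alpha_fwe: float = 0.05,
                                 region_masks: Mapping[str, np.ndarray] | None = None,
                                 mask: np.ndarray | None = None,
                                 fwhm_mm: float = 4.0,
                                 cutoff_s: float = 128.0,
                                 seed: int = 0,
                                 betas: BetaImages | None = None
                                 ) -> tuple[StatMap, RegionPresence, float]:
    """Single-subject face-vs-object test: t over per-run contrasts, FWE-corrected.

    The per-voxel statistic is a one-sample t across the ``n_runs`` per-run
    (pair[0] - pair[1]) beta values. FWE control is by sign-flip permutation
    over runs (exhaustive when 2**n_runs is small) or Bonferroni for fewer
    than 6 runs. A region is "present" when >= 1 supra-threshold voxel falls
    inside its mask. Returns (stat map, region presence, FWE threshold).
    """
    if region_masks is None:
        raise ValueError("region_masks are required to score presence")
    geom = design.geometry
    if mask is None:
        mask = ellipsoid_brain_mask(geom.grid_dims)
    if betas is None:
        betas = subject_betas(runs, design, mask, fwhm_mm, cutoff_s=cutoff_s)
    diffs = per_run_contrast(betas, pair)  # (n_runs, nx, ny, nz)
    n_runs = diffs.shape[0]
    if n_runs < 2:
        raise ValueError("need >= 2 runs")
    statmap = one_sample_t_map(diffs, 0.0, tail="one_sided_greater")

    finite = np.isfinite(statmap.data) & mask
    if n_runs >= 6:
        thr = _signflip_fwe_threshold(diffs, finite, alpha_fwe, seed)
    else:
        thr = float(critical_t(alpha_fwe / max(int(finite.sum()), 1),
                               n_runs - 1))
    regions = {}
    for name, rmask in region_masks.items():
        inside = finite & np.asarray(rmask, dtype=bool)
        peak = float(np.nanmax(statmap.data[inside])) if inside.any() else np.nan
        regions[name] = (bool(np.any(statmap.data[inside] > thr)), peak)
    return statmap, RegionPresence(subject_id=None, regions=regions), thr


def _signflip_fwe_threshold(diffs: np.ndarray, finite: np.ndarray,
                            alpha: float, seed: int,
                            max_exhaustive: int = 4096) -> float:
    """Max-t sign-flip null over runs; exhaustive when 2**n_runs is small."""
    n = diffs.shape[0]
    X = diffs.reshape(n, -1)[:, finite.ravel()]
    sq = (X ** 2).sum(axis=0)
    if 2 ** n <= max_exhaustive:
        bits = np.arange(2 ** n)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)[None]) & 1)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(1023, n))
        signs = np.vstack([np.ones(n), signs])  # identity included
    m = signs @ X / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sq[None] - n * m ** 2) / (n - 1)
        t = m / np.sqrt(var / n)
    max_null = np.nanmax(t, axis=1)
    k = max(int(np.ceil(alpha * len(max_null))), 1)
    return float(np.sort(max_null)[-k])


def group_univariate_contrast(contrasts, groups: Sequence[str],
                              scheme: PermutationScheme | None = None,
                              cluster_forming_p: float = 0.001,
                              alpha: float = 0.05,
                              mask: np.ndarray | None = None,
                              connectivity: int = 18,
                              affine: np.ndarray | None = None):
    """Between-group (controls minus CPs) Welch test on contrast images.

    ``contrasts`` is a per-subject stack of 3-D face-minus-object maps;
    ``groups`` the matching labels ("control"/"cp"). Delegates to the
    permutation machinery with the label-shuffle scheme and unequal-variance
    t, the convention the mass-univariate analysis uses. Returns
    (StatMap, voxel FWE threshold, cluster table).
    """
    contrasts = np.asarray(contrasts, dtype=float)
    groups = list(groups)
    a = contrasts[[g == "control" for g in groups]]
    b = contrasts[[g == "cp" for g in groups]]
    scheme = scheme or PermutationScheme(scheme="label_shuffle")
    if scheme.scheme != "label_shuffle":
        raise ValueError("group comparison requires the label_shuffle scheme")
    return permutation_correct(a, scheme, cluster_forming_p, alpha, maps_b=b,
                               mask=mask, equal_variance=False,
                               tail="one_sided_greater",
                               connectivity=connectivity, affine=affine)


def sensitivity_experiment(spec: CohortSpec,
                           pair: tuple[str, str] = ("face", "object"),
                           sl_config: SearchlightConfig | None = None,
                           n_permutations: int = 1000,
                           cluster_forming_p: float = 0.001,
                           alpha: float = 0.05,
                           fwhm_mm: float = 4.0,
                           double_smooth: bool = False,
                           cutoff_s: float = 128.0,
                           connectivity: int = 18,
                           mask: np.ndarray | None = None,
                           perm_seed: int | None = None) -> SensitivityReport:
    """Run the decoding and univariate group comparisons on one cohort.

    Simulates the cohort in memory, fits each subject's GLM, computes the
    face-vs-object searchlight accuracy map and contrast image, then tests
    controls minus CPs along both routes with cluster-level permutation
    correction. Deterministic given the spec's seeds.
    """
    sl_config = sl_config or SearchlightConfig()
    geom = spec.design.geometry
    if mask is None:
        mask = spec.truth.brain_mask if spec.truth.brain_mask is not None \
            else ellipsoid_brain_mask(geom.grid_dims)
    if perm_seed is None:
        perm_seed = spec.noise.seed + 1

    acc_maps, contrasts, groups = [], [], []
    for idx, group in enumerate(spec.groups):
        runs = simulate_subject(spec.design, spec.truth, group, spec.noise,
                                spec.subject_seed(idx))
        betas = subject_betas(runs, spec.design, mask, fwhm_mm, double_smooth,
                              cutoff_s)
        am = searchlight_map(betas, pair, mask=mask, config=sl_config)
        acc_maps.append(am.data)
        contrasts.append(per_run_contrast(betas, pair).mean(axis=0))
        groups.append(group)

    acc = np.asarray(acc_maps)
    ctrl = acc[[g == "control" for g in groups]]
    cp = acc[[g == "cp" for g in groups]]
    _, _, mvpa_table = permutation_correct(
        ctrl, PermutationScheme(n_permutations, perm_seed, "label_shuffle"),
        cluster_forming_p, alpha, maps_b=cp, mask=mask, equal_variance=True,
        tail="one_sided_greater", connectivity=connectivity)
    _, _, uni_table = group_univariate_contrast(
        np.asarray(contrasts), groups,
        PermutationScheme(n_permutations, perm_seed + 1, "label_shuffle"),
        cluster_forming_p, alpha, mask=mask, connectivity=connectivity)

    mvpa_p = float(mvpa_table["p_corrected"].min()) if len(mvpa_table) else 1.0
    uni_p = float(uni_table["p_corrected"].min()) if len(uni_table) else 1.0
    return SensitivityReport(
        mvpa_min_p=mvpa_p, mvpa_detected=mvpa_p <= alpha,
        univariate_min_p=uni_p, univariate_detected=uni_p <= alpha,
        alpha=alpha,
        config={
            "pair": list(pair), "radius_mm": sl_config.radius_mm,
            "svm_cost": sl_config.svm_cost, "fwhm_mm": fwhm_mm,
            "cutoff_s": cutoff_s, "n_permutations": n_permutations,
            "cluster_forming_p": cluster_forming_p,
            "cp_separability_factor": spec.truth.cp_separability_factor,
            "cp_amplitude_factor": spec.truth.cp_amplitude_factor,
            "master_seed": spec.noise.seed,
        })
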
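"""General linear model for block-design runs.

Each stimulus block is modeled as a 16-s boxcar convolved with the canonical
HRF; one regressor per (category, run) plus one constant per run to absorb
run means. Fixation blocks are unmodeled baseline, so fitted betas measure
response relative to fixation. Both data and condition regressors are
high-pass filtered (128-s DCT projection by default) before ordinary least
squares, which is equivalent to including the drift basis as confounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design import ExperimentDesign
from .hrf import HrfParams, canonical_hrf
from .preprocess import dct_highpass_project


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray  # (n_scans_total, n_regressors)
    column_labels: tuple[tuple[str, int], ...]  # (condition, run); run means labeled ("mean", run)
    frame_times_s: np.ndarray  # (n_scans_total,), times within the session
    n_runs: int
    n_scans_per_run: int

    @property
    def condition_columns(self) -> list[int]:
        return [i for i, (c, _) in enumerate(self.column_labels) if c != "mean"]

    def column_index(self, condition: str, run: int) -> int:
        return self.column_labels.index((condition, run))


@dataclass
class BetaImages:
    """One 3-D coefficient map per (category, run) on the acquisition grid."""

    data: np.ndarray  # (n_categories, n_runs, nx, ny, nz)
    categories: tuple[str, ...]
    mask: np.ndarray  # boolean (nx, ny, nz)
    voxel_size_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[2:] != self.mask.shape:
            raise ValueError("beta grid and mask shapes differ")
        inside = self.data[:, :, self.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError("non-finite betas inside mask")

    @property
    def n_runs(self) -> int:
        return self.data.shape[1]

    def get(self, category: str, run: int) -> np.ndarray:
        return self.data[self.categories.index(category), run]

    def pair_vectors(self, pair: tuple[str, str]) -> np.ndarray:
        """In-mask feature matrix for a category pair.

        Returns shape (2, n_runs, n_mask_voxels): rows ordered as ``pair``.
        """
        ia, ib = (self.categories.index(c) for c in pair)
        return self.data[[ia, ib]][:, :, self.mask]


@dataclass(frozen=True)
class ContrastImage:
    data: np.ndarray  # 3-D
    weights: Mapping[str, float]
    mask: np.ndarray


def build_design_matrix(design: ExperimentDesign,
                        hrf: HrfParams | None = None) -> DesignMatrix:
    """HRF-convolved boxcar regressors, one per (category, run), plus run means.

    Each condition column lives only on its own run's rows; boxcar indicator
    functions are built on the HRF's fine time grid, convolved, and sampled at
    the scan acquisition times.
    """
    hrf = hrf or HrfParams()
    geom = design.geometry
    kernel = canonical_hrf(hrf)
    n_scans = geom.n_volumes_per_run
    n_fine = int(np.ceil(geom.run_length_s / hrf.dt_s)) + 1
    fine_t = np.arange(n_fine) * hrf.dt_s
    scan_idx = np.round(geom.frame_times_s / hrf.dt_s).astype(int)

    for e in design.events:
        if e.run_index >= geom.n_runs:
            raise ValueError(f"event references run {e.run_index} outside geometry")

    cols: list[np.ndarray] = []
    labels: list[tuple[str, int]] = []
    total = n_scans * geom.n_runs
    for run in range(geom.n_runs):
        for cond in design.condition_names:
            box = np.zeros(n_fine)
            for e in design.run_events(run):
                if e.condition == cond:
                    box[(fine_t >= e.onset_s) & (fine_t < e.onset_s + e.duration_s)] = 1.0
            conv = np.convolve(box, kernel)[:n_fine] * hrf.dt_s
            col = np.zeros(total)
            col[run * n_scans:(run + 1) * n_scans] = conv[scan_idx]
            cols.append(col)
            labels.append((cond, run))
    for run in range(geom.n_runs):
        col = np.zeros(total)
        col[run * n_scans:(run + 1) * n_scans] = 1.0
        cols.append(col)
        labels.append(("mean", run))

    frame_times = np.concatenate(
        [geom.frame_times_s + run * geom.run_length_s for run in range(geom.n_runs)])
    return DesignMatrix(values=np.column_stack(cols), column_labels=tuple(labels),
                        frame_times_s=frame_times, n_runs=geom.n_runs,
                        n_scans_per_run=n_scans)


def fit_glm(runs: Sequence[np.ndarray], X: DesignMatrix, mask: np.ndarray,
            tr_s: float, cutoff_s: float = 128.0,
            voxel_size_mm: tuple[float, float, float] | None = None
            ) -> BetaImages:
    """Voxelwise OLS of high-pass-filtered data on filtered condition regressors.

    ``runs`` is one (nx, ny, nz, n_scans) array per run. The DCT drift basis
    (period > ``cutoff_s``) is projected out of both data and regressors per
    run; the run-mean constants lie inside that basis, so the fit is over
    condition columns only. Returns one beta map per (category, run).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_scans = X.n_scans_per_run
    if len(runs) != X.n_runs or any(r.shape[-1] != n_scans for r in runs):
        raise ValueError("scan count of runs does not match design matrix")

    cond_idx = X.condition_columns
    Xc = X.values[:, cond_idx]
    Xf = np.empty_like(Xc)
    Yf = np.empty((Xc.shape[0], int(mask.sum())))
    for run, vol in enumerate(runs):
        rows = slice(run * n_scans, (run + 1) * n_scans)
        Xf[rows] = dct_highpass_project(Xc[rows], tr_s, cutoff_s)
        Yf[rows] = dct_highpass_project(vol[mask].T, tr_s, cutoff_s)

    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        bad = _deficient_columns(Xf)
        names = [X.column_labels[cond_idx[i]] for i in bad]
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank}/{Xf.shape[1]}); offending columns: {names}")

    coefs, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)

    categories = tuple(dict.fromkeys(c for c, _ in X.column_labels if c != "mean"))
    grid = mask.shape
    data = np.zeros((len(categories), X.n_runs) + grid)
    for j, col in enumerate(cond_idx):
        cond, run = X.column_labels[col]
        img = np.zeros(grid)
        img[mask] = coefs[j]
        data[categories.index(cond), run] = img
    return BetaImages(data=data, categories=categories, mask=mask,
                      voxel_size_mm=voxel_size_mm)


def _deficient_columns(M: np.ndarray) -> list[int]:
    # columns whose residual norm against the others is ~0
    bad = []
    for j in range(M.shape[1]):
        others = np.delete(M, j, axis=1)
        resid = M[:, j] - others @ np.linalg.lstsq(others, M[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(M[:, j]), 1e-30):
            bad.append(j)
    return bad


def compute_contrast(betas: BetaImages, weights: Mapping[str, float]) -> ContrastImage:
    """Voxelwise sum over categories of weight x mean-over-runs beta."""
    missing = set(betas.categories) - set(weights)
    if missing:
        raise ValueError(f"missing contrast weights for {sorted(missing)}")
    mean_betas = betas.data.mean(axis=1)  # (n_cat, nx, ny, nz)
    w = np.array([weights[c] for c in betas.categories])
    data = np.tensordot(w, mean_betas, axes=1)
    return ContrastImage(data=data, weights=dict(weights), mask=betas.mask)


def per_run_contrast(betas: BetaImages, pair: tuple[str, str]) -> np.ndarray:
    """Per-run (pair[0] - pair[1]) beta difference, shape (n_runs, nx, ny, nz)."""
    ia, ib = (betas.categories.index(c) for c in pair)
    return betas.data[ia] - betas.data[ib]
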
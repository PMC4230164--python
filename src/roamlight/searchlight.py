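"""Roaming spherical searchlight decoding.

For every brain voxel, the multivoxel pattern of beta values inside a sphere
(default radius 10 mm, truncated at the mask) is extracted for each of the
2 categories x 8 runs, and a linear SVM is trained and tested under
leave-one-run-out cross-validation; the mean accuracy over folds is assigned
to the sphere's center voxel, yielding a whole-brain information map.

Implementation note: with a linear kernel the classifier depends on the
sphere's features only through the 16 x 16 Gram matrix, and each sphere Gram
is the sum of voxelwise products over the sphere. All sphere Grams are
therefore assembled simultaneously by convolving the 136 pairwise product
volumes with the sphere indicator; zeroing non-mask voxels makes the
mask-truncation of edge spheres fall out for free. The per-fold SVM problems
are then solved by the batched solver in :mod:`roamlight.svm`. Results are
identical to a naive per-voxel loop (a test asserts this voxel for voxel) and
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .glm import BetaImages
from .svm import decision_values, solve_csvc


@dataclass(frozen=True)
class SearchlightConfig:
    radius_mm: float = 10.0
    classifier: str = "linear_svm"
    svm_cost: float = 1.0
    min_sphere_voxels: int = 2
    standardize: bool = False  # optional per-fold z-scoring (sensitivity analysis)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.classifier != "linear_svm":
            raise ValueError(f"unsupported classifier {self.classifier!r}")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be > 0")
        if self.min_sphere_voxels < 1:
            raise ValueError("min_sphere_voxels must be >= 1")


@dataclass(frozen=True)
class FoldSplit:
    """Leave-one-run-out folds: each run is the test set exactly once."""

    folds: tuple[tuple[tuple[int, ...], int], ...]

    def __post_init__(self) -> None:
        tests = [t for _, t in self.folds]
        if sorted(tests) != sorted(set(tests)):
            raise ValueError("every run must appear as test exactly once")
        for train, test in self.folds:
            if test in train:
                raise ValueError("train and test runs must be disjoint")

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class AccuracyMap:
    data: np.ndarray  # 3-D, values in [0, 1] inside mask, NaN outside
    mask: np.ndarray
    pair: tuple[str, str]
    config: SearchlightConfig
    subject_id: str | None = None

    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.data))


def sphere_offsets(radius_mm: float,
                   voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Integer voxel offsets within ``radius_mm`` of the center, in mm metric.

    Anisotropic voxel sizes make the voxel-space neighborhood an ellipsoid;
    the set always contains (0,0,0) and is symmetric under negation.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    vox = np.asarray(voxel_size_mm, dtype=float)
    bound = np.floor(radius_mm / vox).astype(int)
    axes = [np.arange(-b, b + 1) for b in bound]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    d2 = (ii * vox[0]) ** 2 + (jj * vox[1]) ** 2 + (kk * vox[2]) ** 2
    keep = d2 <= radius_mm ** 2 + 1e-9
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def sphere_kernel(radius_mm: float,
                  voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Binary sphere indicator as an odd-sized convolution kernel."""
    offs = sphere_offsets(radius_mm, voxel_size_mm)
    bound = np.abs(offs).max(axis=0)
    kern = np.zeros(tuple(2 * bound + 1))
    kern[tuple((offs + bound).T)] = 1.0
    return kern


def leave_one_run_out_folds(run_ids: Sequence[int]) -> FoldSplit:
    """All n folds holding out one run each, in sorted deterministic order."""
    runs = sorted(run_ids)
    if len(runs) < 2:
        raise ValueError("need >= 2 runs for leave-one-run-out CV")
    folds = tuple(
        (tuple(r for r in runs if r != test), test) for test in runs)
    return FoldSplit(folds=folds)


def _pair_labels(pair: tuple[str, str]) -> tuple[str, str]:
    """Lexicographically first category maps to label -1 (the tie winner)."""
    a, b = sorted(pair)
    return a, b


def classify_pair_cv(vectors: Mapping[tuple[int, str], np.ndarray],
                     folds: FoldSplit,
                     config: SearchlightConfig | None = None) -> float:
    """Mean leave-one-run-out SVM accuracy for one sphere's feature vectors.

    ``vectors`` maps (run_id, category) to a feature vector; exactly one
    vector per (run, category) pair, all of a common dimension. Each fold
    trains a soft-margin linear SVM on the training runs' vectors and scores
    the two held-out vectors, so per-fold accuracy is 0, 0.5, or 1; the mean
    over folds is returned.
    """
    config = config or SearchlightConfig()
    cats = sorted({c for _, c in vectors})
    if len(cats) != 2:
        raise ValueError(f"expected exactly 2 categories, got {cats}")
    runs = sorted({r for r, _ in vectors})
    if len(vectors) != 2 * len(runs):
        raise ValueError("expected exactly one vector per (run, category)")
    dims = {np.asarray(v).shape for v in vectors.values()}
    if len(dims) != 1:
        raise ValueError(f"feature dimension mismatch: {dims}")
    X = np.array([[np.atleast_1d(np.asarray(vectors[(r, c)], dtype=float))
                   for r in runs] for c in cats])  # (2, n_runs, p)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    run_index = {r: i for i, r in enumerate(runs)}
    accs = []
    for train, test in folds.folds:
        tr = [run_index[r] for r in train]
        te = run_index[test]
        Xtr = np.concatenate([X[0, tr], X[1, tr]])  # class -1 rows then +1
        Xte = np.stack([X[0, te], X[1, te]])
        y = np.concatenate([-np.ones(len(tr)), np.ones(len(tr))])
        if config.standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        alpha, rho = solve_csvc(Xtr @ Xtr.T, y, C=config.svm_cost)
        f = decision_values((Xte @ Xtr.T)[None], alpha[None], y,
                            np.atleast_1d(rho))[0]
        pred = np.where(f > 0, 1.0, -1.0)
        accs.append(np.mean(pred == np.array([-1.0, 1.0])))
    return float(np.mean(accs))


def searchlight_map(betas: BetaImages, pair: tuple[str, str],
                    mask: np.ndarray | None = None,
                    config: SearchlightConfig | None = None,
                    subject_id: str | None = None,
                    voxel_size_mm: tuple[float, float, float] | None = None
                    ) -> AccuracyMap:
    """Whole-brain cross-validated accuracy map for one category pair.

    Spheres are intersected with the mask; centers retaining fewer than
    ``min_sphere_voxels`` voxels (and all out-of-mask voxels) are NaN.
    """
    config = config or SearchlightConfig()
    mask = betas.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    cat_a, cat_b = _pair_labels(pair)
    voxel_size = voxel_size_mm or _voxel_size_from_betas(betas)
    n_runs = betas.n_runs
    folds = leave_one_run_out_folds(range(n_runs))

    # sample order: cat_a's runs (label -1) then cat_b's runs (label +1)
    vols = np.concatenate([
        betas.data[betas.categories.index(cat_a)],
        betas.data[betas.categories.index(cat_b)],
    ])  # (2 * n_runs, nx, ny, nz)
    vols = np.where(mask[None], vols, 0.0)
    y = np.concatenate([-np.ones(n_runs), np.ones(n_runs)])
    n = 2 * n_runs

    if config.standardize:
        return _searchlight_slow(vols, y, mask, folds, config, voxel_size,
                                 (cat_a, cat_b), subject_id)

    kern = sphere_kernel(config.radius_mm, voxel_size)
    counts = fftconvolve(mask.astype(float), kern, mode="same")
    counts = np.rint(counts).astype(int)
    valid = mask & (counts >= config.min_sphere_voxels)
    centers = np.flatnonzero(valid.ravel())
    iu, ju = np.triu_indices(n)
    prods = vols[iu] * vols[ju]  # (n*(n+1)/2, nx, ny, nz)
    gram_fields = fftconvolve(prods, kern[None], mode="same", axes=(1, 2, 3))
    gram_flat = gram_fields.reshape(len(iu), -1)[:, centers]  # (n_pairs, V)
    K = np.empty((centers.size, n, n))
    K[:, iu, ju] = gram_flat.T
    K[:, ju, iu] = gram_flat.T

    acc = np.zeros(centers.size)
    for train, test in folds.folds:
        tr = np.array([r for r in train] + [r + n_runs for r in train])
        te = np.array([test, test + n_runs])
        alpha, rho = solve_csvc(K[:, tr[:, None], tr[None, :]], y[tr],
                                C=config.svm_cost)
        f = decision_values(K[:, te[:, None], tr[None, :]], alpha, y[tr], rho)
        pred = np.where(f > 0, 1.0, -1.0)
        acc += (pred == y[te][None]).mean(axis=1)
    acc /= len(folds)

    data = np.full(mask.shape, np.nan)
    data.ravel()[centers] = acc
    return AccuracyMap(data=data, mask=mask, pair=(cat_a, cat_b),
                       config=config, subject_id=subject_id)


def _searchlight_slow(vols: np.ndarray, y: np.ndarray, mask: np.ndarray,
                      folds: FoldSplit, config: SearchlightConfig,
                      voxel_size, pair, subject_id) -> AccuracyMap:
    """Per-voxel gather path (needed when per-fold standardization is on)."""
    offs = sphere_offsets(config.radius_mm, voxel_size)
    dims = mask.shape
    n_runs = len(folds)
    data = np.full(dims, np.nan)
    for center in np.argwhere(mask):
        pos = center[None, :] + offs
        ok = np.all((pos >= 0) & (pos < np.array(dims)[None]), axis=1)
        pos = pos[ok]
        inm = mask[pos[:, 0], pos[:, 1], pos[:, 2]]
        pos = pos[inm]
        if len(pos) < config.min_sphere_voxels:
            continue
        feats = vols[:, pos[:, 0], pos[:, 1], pos[:, 2]]
        vectors = {(r, pair[0]): feats[r] for r in range(n_runs)}
        vectors.update({(r, pair[1]): feats[r + n_runs] for r in range(n_runs)})
        data[tuple(center)] = classify_pair_cv(vectors, folds, config)
    return AccuracyMap(data=data, mask=mask, pair=pair, config=config,
                       subject_id=subject_id)


def _voxel_size_from_betas(betas: BetaImages) -> tuple[float, float, float]:
    vs = getattr(betas, "voxel_size_mm", None)
    if vs is None:
        raise ValueError("BetaImages lacks voxel_size_mm; set the attribute "
                         "or pass betas produced by the pipeline")
    return tuple(vs)
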
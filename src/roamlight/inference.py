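"""Group-level inference on subject maps.

Voxelwise one-sample t-tests (e.g., accuracy vs the 50% two-class chance
level) and two-sample group comparisons (pooled-variance or Welch), with
familywise-error control by max-statistic permutation and cluster-level
correction by max-cluster-extent permutation. Sign-flipping is the
exchangeability scheme for one-sample tests, group-label shuffling for
two-sample tests; the identity permutation is always counted, so corrected
p-values are bounded below by 1/(1 + n_permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    data: np.ndarray  # 3-D t values, NaN outside mask / at zero-variance voxels
    df: float | np.ndarray  # scalar, or per-voxel map for Welch tests
    tail: str  # one_sided_greater | two_sided
    test: str  # one_sample_vs_chance | two_sample_diff
    mask: np.ndarray | None = None
    n_zero_variance: int = 0


@dataclass
class PermutationScheme:
    n_permutations: int = 1000
    seed: int = 0
    scheme: str = "sign_flip"  # sign_flip (one-sample) | label_shuffle (two-sample)

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need >= 100 permutations")
        if self.scheme not in ("sign_flip", "label_shuffle"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _stack(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3-D subject maps")
    return arr


def one_sample_t_map(maps, null_value: float = 0.0,
                     tail: str = "one_sided_greater") -> StatMap:
    """Voxelwise t = (mean - null) / (sd / sqrt(n)), df = n - 1.

    Zero-variance voxels become NaN (their count is logged, not raised):
    constant background inside a generous mask is expected.
    """
    arr = _stack(maps)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - null_value) / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    t[zero_var] = np.nan
    nzv = int(zero_var.sum())
    if nzv:
        logger.info("one_sample_t_map: %d zero-variance voxels set to NaN", nzv)
    return StatMap(data=t, df=float(n - 1), tail=tail,
                   test="one_sample_vs_chance", n_zero_variance=nzv)


def two_sample_t_map(maps_a, maps_b, equal_variance: bool = True,
                     tail: str = "one_sided_greater") -> StatMap:
    """Two-sample t map, sign convention group A minus group B.

    Pooled variance with df = n_a + n_b - 2, or Welch with voxelwise
    Welch-Satterthwaite df when ``equal_variance`` is False.
    """
    a, b = _stack(maps_a), _stack(maps_b)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_variance:
            pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            df: float | np.ndarray = float(na + nb - 2)
        else:
            se = np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / se
    zero_var = (se == 0) & np.isfinite(ma - mb)
    t[zero_var] = np.nan
    nzv = int(zero_var.sum())
    if nzv:
        logger.info("two_sample_t_map: %d zero-variance voxels set to NaN", nzv)
    return StatMap(data=t, df=df, tail=tail, test="two_sample_diff",
                   n_zero_variance=nzv)


def critical_t(p: float, df, tail: str = "one_sided_greater"):
    """Upper-tail Student-t quantile: the t exceeded with probability p."""
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if tail == "two_sided":
        return stats.t.isf(p / 2.0, df)
    return stats.t.isf(p, df)


def extract_clusters(statmap: StatMap, threshold: float,
                     connectivity: int = 18,
                     affine: np.ndarray | None = None) -> pd.DataFrame:
    """Connected supra-threshold clusters, sorted by peak statistic.

    Columns: label, i, j, k, x_mm, y_mm, z_mm, t_value (peak), KE (extent in
    voxels), p_corrected (NaN until a permutation scheme fills it in).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = np.nan_to_num(statmap.data, nan=-np.inf)
    return _cluster_table(data, data > threshold, connectivity, affine)


def _cluster_table(values: np.ndarray, supra: np.ndarray, connectivity: int,
                   affine: np.ndarray | None) -> pd.DataFrame:
    structure = ndimage.generate_binary_structure(3, _connectivity_rank(connectivity))
    labels, n = ndimage.label(supra, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = values[tuple(idx.T)]
        peak = idx[np.argmax(vals)]
        world = peak.astype(float)
        if affine is not None:
            world = (affine @ np.append(peak, 1.0))[:3]
        rows.append({"label": lab, "i": int(peak[0]), "j": int(peak[1]),
                     "k": int(peak[2]), "x_mm": world[0], "y_mm": world[1],
                     "z_mm": world[2], "t_value": float(vals.max()),
                     "KE": int(len(idx)), "p_corrected": np.nan})
    cols = ["label", "i", "j", "k", "x_mm", "y_mm", "z_mm", "t_value", "KE",
            "p_corrected"]
    table = pd.DataFrame(rows, columns=cols)
    return table.sort_values("t_value", ascending=False, ignore_index=True)


def _connectivity_rank(connectivity: int) -> int:
    try:
        return _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")


def permutation_correct(maps_a, scheme: PermutationScheme,
                        cluster_forming_p: float = 0.001, alpha: float = 0.05,
                        maps_b=None, null_value: float = 0.0,
                        mask: np.ndarray | None = None,
                        equal_variance: bool = True,
                        tail: str = "one_sided_greater",
                        connectivity: int = 18,
                        affine: np.ndarray | None = None):
    """Permutation FWE correction: max-statistic (voxel) and max-extent (cluster).

    For ``sign_flip`` the subject maps in ``maps_a`` are tested against
    ``null_value`` (one-sample); for ``label_shuffle`` ``maps_a`` vs
    ``maps_b`` (two-sample, A minus B). Returns
    ``(statmap, voxel_fwe_threshold, cluster_table)`` where the table carries
    corrected cluster p-values computed as
    (1 + #{permutation max extent >= observed extent}) / (1 + n_permutations).
    """
    if not 0 < cluster_forming_p < 1:
        raise ValueError("cluster_forming_p must lie in (0, 1)")
    rng = np.random.default_rng(scheme.seed)
    a = _stack(maps_a)
    if scheme.scheme == "sign_flip":
        if maps_b is not None:
            raise ValueError("sign_flip is a one-sample scheme; maps_b given")
        observed = one_sample_t_map(a, null_value, tail)
        perm_t = _signflip_t_null(a - null_value, scheme.n_permutations, rng)
    else:
        if maps_b is None:
            raise ValueError("label_shuffle requires maps_b")
        b = _stack(maps_b)
        observed = two_sample_t_map(a, b, equal_variance, tail)
        perm_t = _shuffle_t_null(a, b, scheme.n_permutations, rng,
                                 equal_variance)

    finite = np.isfinite(observed.data)
    if mask is not None:
        finite &= np.asarray(mask, dtype=bool)
    flat_mask = finite.reshape(-1)
    two_sided = tail == "two_sided"

    stat = np.abs if two_sided else (lambda x: x)
    perm_flat = perm_t.reshape(scheme.n_permutations, -1)[:, flat_mask]
    # zero-variance voxels under a permutation come out infinite; drop them
    perm_flat = np.where(np.isfinite(perm_flat), perm_flat, np.nan)
    with np.errstate(invalid="ignore"):
        max_null = np.nanmax(stat(perm_flat), axis=1)
    obs_max = np.nanmax(stat(observed.data[finite]))
    max_null_all = np.append(max_null, obs_max)  # identity/observed included
    voxel_fwe_threshold = float(np.nanquantile(max_null_all, 1.0 - alpha))

    # cluster-forming threshold; a per-voxel map when df is voxelwise (Welch)
    t_form = critical_t(cluster_forming_p, observed.df, tail)
    thr_map = np.asarray(t_form) if np.ndim(t_form) \
        else np.full(observed.data.shape, t_form)
    obs_vals = np.nan_to_num(observed.data, nan=-np.inf)
    obs_supra = finite & (stat(obs_vals) > thr_map)
    table = _cluster_table(stat(obs_vals), obs_supra, connectivity, affine)

    structure = ndimage.generate_binary_structure(3, _connectivity_rank(connectivity))
    null_extents = np.zeros(scheme.n_permutations, dtype=int)
    for p in range(scheme.n_permutations):
        tmap = perm_t[p]
        supra = finite & np.isfinite(tmap) & (stat(tmap) > thr_map)
        if supra.any():
            labels, n = ndimage.label(supra, structure=structure)
            if n:
                null_extents[p] = np.bincount(labels.ravel())[1:].max()
    null_extents_all = null_extents
    ps = []
    for ke in table["KE"]:
        ps.append((1 + int(np.sum(null_extents_all >= ke)))
                  / (1 + scheme.n_permutations))
    table = table.assign(p_corrected=ps)
    return observed, voxel_fwe_threshold, table


def _signflip_t_null(centered: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Sign-flip null t maps; subjectwise sums of squares are flip-invariant."""
    n = centered.shape[0]
    X = centered.reshape(n, -1)
    sq = (X ** 2).sum(axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    m = signs @ X / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (sq[None] - n * m ** 2) / (n - 1)
        t = m / np.sqrt(var / n)
    return t.reshape((n_perm,) + centered.shape[1:])


def _shuffle_t_null(a: np.ndarray, b: np.ndarray, n_perm: int, rng,
                    equal_variance: bool) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    X = np.concatenate([a, b]).reshape(na + nb, -1)
    X2 = X ** 2
    total, total2 = X.sum(axis=0), X2.sum(axis=0)
    out = np.empty((n_perm, X.shape[1]))
    for p in range(n_perm):
        idx = rng.permutation(na + nb)
        ia = idx[:na]
        sa, sa2 = X[ia].sum(axis=0), X2[ia].sum(axis=0)
        sb, sb2 = total - sa, total2 - sa2
        ma, mb = sa / na, sb / nb
        va = (sa2 - na * ma ** 2) / (na - 1)
        vb = (sb2 - nb * mb ** 2) / (nb - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if equal_variance:
                pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            else:
                se = np.sqrt(va / na + vb / nb)
            out[p] = (ma - mb) / se
    return out.reshape((n_perm,) + a.shape[1:])
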
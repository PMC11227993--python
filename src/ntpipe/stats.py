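"""Univariate and voxelwise group inference.

* Two-sample tests use the pooled-variance Student t (df = n_a + n_b - 2),
  the form identified by the degrees of freedom reported for the source
  cohort, with effect size eta^2 = t^2 / (t^2 + df).
* Correlation significance uses a non-parametric pairs bootstrap: resample
  subject pairs with replacement, and take the two-tailed sign-crossing
  fraction of the bootstrap correlation distribution, floored at 1/n_boot.
* Voxelwise group comparison fits, per voxel, the linear model
  [intercept, group, age, sex] and reports the group-contrast t (a
  mass-univariate random-effects analysis).
* Cluster-level family-wise error is controlled by permutation: supra-
  threshold clusters of |t| (two-tailed cluster-forming threshold,
  p < 0.001 by default) are labelled by face connectivity, and each
  observed cluster's p_FWE is the permutation probability that the maximal
  cluster size under group-label exchange reaches its size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats as sps

from .core import AtlasGeometry, IntMap


@dataclass(frozen=True)
class GroupTestResult:
    t: float
    df: int
    p: float
    eta2: float

    def __post_init__(self) -> None:
        expect = self.t**2 / (self.t**2 + self.df)
        if abs(self.eta2 - expect) > 1e-12:
            raise ValueError("eta2 must equal t^2/(t^2+df)")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_boot: float
    n: int
    n_boot: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


@dataclass(frozen=True)
class ClusterResult:
    cluster_size_voxels: int
    peak_coord_mm: tuple[float, float, float]
    peak_t: float
    p_fwe: float

    def __post_init__(self) -> None:
        if self.cluster_size_voxels < 1:
            raise ValueError("cluster size must be >= 1")


def eta_squared_from_t(t: float, df: int) -> float:
    """Effect size eta^2 = t^2 / (t^2 + df) for a two-sample t statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    t = float(t)
    return t * t / (t * t + df)


def two_sample_t(a, b) -> GroupTestResult:
    """Pooled-variance Student two-sample t-test (two-tailed) with eta^2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if not (sp2 > 0):
        raise ValueError("pooled variance is zero; t is undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = 2 * sps.t.sf(abs(t), df)
    return GroupTestResult(t=float(t), df=df, p=float(p), eta2=eta_squared_from_t(t, df))


def pearson_bootstrap(x, y, n_boot: int = 10_000, seed=0) -> CorrelationResult:
    """Pearson r with a two-tailed pairs-bootstrap p-value.

    p = 2 * min(frac of bootstrap r <= 0, frac >= 0), floored at 1/n_boot
    and capped at 1.  Invariant to swapping x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r = float(sps.pearsonr(x, y).statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(int(n_boot), n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rb = (xc * yc).sum(axis=1) / denom
    rb = rb[np.isfinite(rb)]  # drop degenerate resamples (constant draw)
    frac_le = np.mean(rb <= 0)
    frac_ge = np.mean(rb >= 0)
    p = 2 * min(frac_le, frac_ge)
    p = float(min(1.0, max(p, 1.0 / n_boot)))
    return CorrelationResult(r=r, p_boot=p, n=n, n_boot=int(n_boot))


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p; used to gate how results are reported
    (the bootstrap p is computed regardless)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def bonferroni_correct(p: float, m: int) -> float:
    """min(1, m * p)."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# Voxelwise GLM and permutation cluster correction


def _encode_design(group: Sequence, age: Sequence, sex: Sequence) -> np.ndarray:
    g = np.asarray([1.0 if v in ("AD", 1, True) else 0.0 for v in group])
    a = np.asarray(age, dtype=float)
    s = np.asarray([1.0 if v in ("M", 1, True) else 0.0 for v in sex])
    return np.column_stack([np.ones(len(g)), g, a, s])


def _glm_t(Y: np.ndarray, X: np.ndarray, col: int = 1) -> np.ndarray:
    """t statistics for one coefficient of Y = X beta + eps, vectorized
    over the columns of Y ((S, V))."""
    S, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T  # (p, S)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    dof = S - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[col, col], 1e-300))
    return beta[col] / se


def stack_maps(int_maps: Sequence[IntMap]) -> tuple[np.ndarray, np.ndarray]:
    """(S, V) data matrix over the voxels defined in *every* subject,
    plus the common 3D mask."""
    if len(int_maps) == 0:
        raise ValueError("no maps supplied")
    common = np.logical_and.reduce([m.mask for m in int_maps])
    if not common.any():
        raise ValueError("no voxel is defined in every subject")
    Y = np.stack([m.values[common] for m in int_maps], axis=0)
    return Y, common


def voxelwise_glm_t(
    int_maps: Sequence[IntMap], group: Sequence, age: Sequence, sex: Sequence,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Group-contrast t-map (AD minus CN) adjusted for age and sex.

    Returns ``(t_map, mask, df)``; ``t_map`` is NaN outside the common
    mask.  Voxels undefined in any subject are excluded.
    """
    X = _encode_design(group, age, sex)
    counts = np.bincount(X[:, 1].astype(int), minlength=2)
    if counts.min() < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y, mask = stack_maps(int_maps)
    t = _glm_t(Y, X)
    t_map = np.full(mask.shape, np.nan)
    t_map[mask] = t
    return t_map, mask, X.shape[0] - X.shape[1]


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


def _cluster_sizes(supra: np.ndarray, structure: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n, sizes


def cluster_fwe_perm(
    int_maps: Sequence[IntMap],
    group: Sequence,
    age: Sequence,
    sex: Sequence,
    geometry: AtlasGeometry,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    seed=0,
    connectivity: int = 6,
) -> list[ClusterResult]:
    """Permutation cluster-level FWE for the voxelwise group comparison.

    Group labels are permuted (covariates fixed), the t-map recomputed, and
    the maximal supra-threshold cluster size recorded; each observed
    cluster's p_FWE is (1 + #{perm max >= size}) / (1 + n_perm).  An empty
    cluster list is a valid outcome.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = _encode_design(group, age, sex)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Y, mask = stack_maps(int_maps)
    df = X.shape[0] - X.shape[1]
    t_crit = sps.t.isf(cluster_forming_p / 2.0, df)
    structure = _connectivity_structure(connectivity)

    t_obs = _glm_t(Y, X)
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = np.abs(t_obs) > t_crit
    labels, n_clusters, sizes = _cluster_sizes(supra, structure)
    if n_clusters == 0:
        return []

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = X[:, 1].copy()
    max_sizes = np.zeros(n_perm, dtype=int)
    Xp = X.copy()
    for i in range(n_perm):
        Xp[:, 1] = rng.permutation(g)
        tp = _glm_t(Y, Xp)
        sp = np.zeros(mask.shape, dtype=bool)
        sp[mask] = np.abs(tp) > t_crit
        _, _, psizes = _cluster_sizes(sp, structure)
        max_sizes[i] = psizes.max() if psizes.size else 0

    t_map = np.full(mask.shape, np.nan)
    t_map[mask] = t_obs
    results = []
    for k in range(1, n_clusters + 1):
        members = np.argwhere(labels == k)
        tvals = t_map[members[:, 0], members[:, 1], members[:, 2]]
        peak_idx = members[np.argmax(np.abs(tvals))]
        size = int(sizes[k - 1])
        p_fwe = (1 + int(np.sum(max_sizes >= size))) / (1 + n_perm)
        results.append(ClusterResult(
            cluster_size_voxels=size,
            peak_coord_mm=tuple(np.round(geometry.voxel_to_mm(peak_idx), 6)),
            peak_t=float(tvals[np.argmax(np.abs(tvals))]),
            p_fwe=float(p_fwe),
        ))
    results.sort(key=lambda c: c.cluster_size_voxels, reverse=True)
    return results
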
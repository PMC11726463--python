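"""Hypervolume and niche overlap statistics.

Trait overlap between two groups is quantified with dynamic range
boxes: for a ladder of nested central quantile intervals per variable,
the "port" of A in B is the mean fraction of A's interval covered by
B's, aggregated across variables by product. The statistic is
asymmetric; differentiation is 1 minus the larger of the two ports.
Climatic niche overlap uses Schoener's D between normalized suitability
surfaces, with a permutation identity test and a pluggable suitability
model (built-in baseline: Gaussian Mahalanobis envelope on the first
three principal components of the bioclimatic space).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_BOXES = 51


def _quantile_boxes(x: np.ndarray, levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper bounds of the nested central quantile intervals
    [Q(s), Q(1-s)] for each level s (type-7 empirical quantiles)."""
    lo = np.quantile(x, levels)
    hi = np.quantile(x, 1.0 - levels)
    return lo, hi


def _port_1d(lo_a, hi_a, lo_b, hi_b) -> np.ndarray:
    """Fraction of interval A covered by interval B, per level.

    Degenerate A (zero width): 1 if A's point lies inside B, else 0.
    """
    inter = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
    width = hi_a - lo_a
    out = np.where(width > 0, np.clip(inter, 0.0, None) / np.where(width > 0, width, 1.0), 0.0)
    degenerate = width <= 0
    inside = (lo_a >= lo_b) & (lo_a <= hi_b)
    out = np.where(degenerate, np.where(inside, 1.0, 0.0), out)
    return out


def drb_port(
    a: np.ndarray | pd.DataFrame,
    b: np.ndarray | pd.DataFrame,
    n_boxes: int = DEFAULT_N_BOXES,
    aggregation: str = "product",
) -> float:
    """Dynamic-range-box port of sample A within sample B.

    For levels s_k = 0.5*k/(n_boxes-1), k = 0..n_boxes-1, each variable
    contributes the mean over levels of |box_A ∩ box_B| / |box_A|;
    variables aggregate by product (or mean). Rows with a missing value
    in a variable are excluded for that variable.
    """
    if n_boxes < 2:
        raise ValueError("n_boxes must be >= 2")
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    if A.shape[0] == 1 and A.shape[1] > 1 and np.asarray(a).ndim == 1:
        A = A.T
    if B.shape[0] == 1 and B.shape[1] > 1 and np.asarray(b).ndim == 1:
        B = B.T
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the same variables")
    if A.shape[1] == 0:
        raise ValueError("no shared variable")
    levels = 0.5 * np.arange(n_boxes) / (n_boxes - 1)
    dims = []
    for d in range(A.shape[1]):
        xa = A[:, d][np.isfinite(A[:, d])]
        xb = B[:, d][np.isfinite(B[:, d])]
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"variable {d} has no finite values in one group")
        lo_a, hi_a = _quantile_boxes(xa, levels)
        lo_b, hi_b = _quantile_boxes(xb, levels)
        dims.append(float(np.mean(_port_1d(lo_a, hi_a, lo_b, hi_b))))
    if aggregation == "product":
        return float(np.prod(dims))
    if aggregation == "mean":
        return float(np.mean(dims))
    raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass
class OverlapResult:
    groups: tuple[str, str]
    port_ab: float  # A within B
    port_ba: float
    max_overlap: float
    differentiation: float  # 1 - max_overlap
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_reps: int = 0
    seed: int | None = None


def differentiation_ci(
    a: np.ndarray,
    b: np.ndarray,
    groups: tuple[str, str] = ("A", "B"),
    n_boxes: int = DEFAULT_N_BOXES,
    resample_frac: float = 0.9,
    n_reps: int = 100,
    seed: int = 0,
) -> OverlapResult:
    """Differentiation (1 - max asymmetric port) with a jackknife CI
    from resampling 90% of individuals per group, 100 times."""
    A = np.atleast_2d(np.asarray(a, dtype=float))
    B = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = A.shape[0], B.shape[0]
    ka, kb = max(1, int(round(resample_frac * na))), max(1, int(round(resample_frac * nb)))
    if min(ka, kb) < 3:
        raise ValueError("groups too small for jackknife resampling (need >= 3 retained)")
    pab = drb_port(A, B, n_boxes)
    pba = drb_port(B, A, n_boxes)
    full = 1.0 - max(pab, pba)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        ia = rng.choice(na, size=ka, replace=False)
        ib = rng.choice(nb, size=kb, replace=False)
        qab = drb_port(A[ia], B[ib], n_boxes)
        qba = drb_port(B[ib], A[ia], n_boxes)
        reps[r] = 1.0 - max(qab, qba)
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return OverlapResult(
        groups=groups,
        port_ab=pab,
        port_ba=pba,
        max_overlap=max(pab, pba),
        differentiation=full,
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Climatic niche
# ---------------------------------------------------------------------------


@dataclass
class NicheSurface:
    """Suitability values over the cells of an environmental grid."""

    values: np.ndarray
    normalized: bool = False

    def normalize(self) -> "NicheSurface":
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("suitability values must be non-negative")
        s = v.sum()
        if s <= 0:
            raise ValueError("surface sums to zero; cannot normalize")
        return NicheSurface(v / s, normalized=True)


def schoeners_d(p: NicheSurface, q: NicheSurface) -> float:
    """D = 1 - 0.5 * sum |p_i - q_i| over matching normalized grids."""
    pv = np.asarray(p.values, dtype=float)
    qv = np.asarray(q.values, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"grid mismatch: {pv.shape} vs {qv.shape}")
    for surf, v in (("first", pv), ("second", qv)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{surf} surface is not normalized (sum {v.sum():.6g})")
    return float(1.0 - 0.5 * np.abs(pv - qv).sum())


def niche_pca(bioclim: pd.DataFrame | np.ndarray, n_components: int = 3):
    """Centered, unit-variance PCA of a bioclimatic table.

    Returns (scores, fitted sklearn PCA, scaler-like tuple of mean/sd).
    Constant columns are dropped with a warning.
    """
    import warnings

    from sklearn.decomposition import PCA

    X = np.asarray(bioclim, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need at least 4 complete records for PCA")
    if not np.all(np.isfinite(X)):
        raise ValueError("bioclimatic table contains missing values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2)
    X = X[:, keep]
    mu, sdk = X.mean(axis=0), X.std(axis=0, ddof=1)
    Z = (X - mu) / sdk
    pca = PCA(n_components=min(n_components, Z.shape[1]))
    scores = pca.fit_transform(Z)
    return scores, pca, (mu, sdk, keep)


@dataclass
class SuitabilityModel:
    """Gaussian Mahalanobis envelope in the leading PC space.

    Suitability of a cell is exp(-m^2/2) where m is the Mahalanobis
    distance of the cell's PC scores from the occurrence centroid.
    Serves as a simple, fully pluggable stand-in for any external niche
    model producing a per-cell suitability surface.
    """

    mean: np.ndarray
    cov_inv: np.ndarray
    pca: object
    scaler: tuple

    def predict(self, env: pd.DataFrame | np.ndarray, normalize: bool = True) -> NicheSurface:
        mu, sdk, keep = self.scaler
        X = np.asarray(env, dtype=float)[:, keep]
        Z = (X - mu) / sdk
        scores = self.pca.transform(Z)
        d = scores - self.mean
        m2 = np.einsum("ij,jk,ik->i", d, self.cov_inv, d)
        surf = NicheSurface(np.exp(-0.5 * m2))
        return surf.normalize() if normalize else surf


def fit_suitability(
    occ_env: pd.DataFrame | np.ndarray,
    env_grid: pd.DataFrame | np.ndarray,
    n_components: int = 3,
    ridge: float = 1e-8,
) -> SuitabilityModel:
    """Fit the baseline envelope model from occurrence-cell bioclim rows.

    PCA axes are estimated from the full environmental grid so the two
    compared species share one niche space; a small ridge keeps the
    occurrence covariance invertible for tight clusters.
    """
    import warnings

    occ = np.asarray(occ_env, dtype=float)
    if occ.shape[0] < 5:
        raise ValueError("need at least 5 occurrences")
    _, pca, scaler = niche_pca(env_grid, n_components)
    mu, sdk, keep = scaler
    Z = (occ[:, keep] - mu) / sdk
    scores = pca.transform(Z)
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    cov = np.atleast_2d(cov)
    # near-singular covariances (tight clusters, collinear PCs) get a
    # trace-scaled ridge; a hard singularity additionally warns
    if np.linalg.cond(cov) > 1e10:
        cov = cov + ridge * max(np.trace(cov), 1.0) * np.eye(cov.shape[0])
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular occurrence covariance; ridge-regularizing", stacklevel=2)
        cov_inv = np.linalg.inv(cov + max(np.trace(cov), 1.0) * 1e-6 * np.eye(cov.shape[0]))
    return SuitabilityModel(center, cov_inv, pca, scaler)


def identity_test(
    occ_a: pd.DataFrame | np.ndarray,
    occ_b: pd.DataFrame | np.ndarray,
    env_grid: pd.DataFrame | np.ndarray,
    n_perm: int = 99,
    seed: int = 0,
    fit=fit_suitability,
) -> dict:
    """Niche identity permutation test on Schoener's D.

    The null distribution refits suitability surfaces after pooling the
    two occurrence sets and permuting species labels; the p-value is
    the fraction of null D values at or below the observed D (small p:
    niches more distinct than exchangeable samples).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A = np.asarray(occ_a, dtype=float)
    B = np.asarray(occ_b, dtype=float)
    d_obs = schoeners_d(
        fit(A, env_grid).predict(env_grid), fit(B, env_grid).predict(env_grid)
    )
    pooled = np.vstack([A, B])
    na = A.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        null[i] = schoeners_d(
            fit(pa, env_grid).predict(env_grid), fit(pb, env_grid).predict(env_grid)
        )
    p = (1 + int(np.sum(null <= d_obs))) / (n_perm + 1)
    return {"d_observed": d_obs, "p_value": p, "null": null, "seed": seed}
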
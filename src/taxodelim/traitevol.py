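"""Trait-evolution model fitting and the age-overlap rejection test.

Species trait means on an ultrametric phylogeny are modelled as a
multivariate Gaussian whose among-species covariance follows one of
three processes:

* BM  — Brownian motion (neutral drift): cov(i,j) = t_ij * R, with
  t_ij the shared path length from the root and R the evolutionary
  rate/covariance matrix among traits.
* EB  — early burst: the BM rate decays as exp(r*t) with r <= 0, so
  cov(i,j) = (exp(r*t_ij) - 1)/r * R.
* OU  — a single-optimum Ornstein-Uhlenbeck process with scalar pull
  alpha, at stationarity: cov(i,j) = exp(-alpha*d_ij) * R/(2*alpha)
  with d_ij the patristic distance. The root equals the optimum (they
  are not separately identifiable on ultrametric trees).

Per-species squared standard errors enter the likelihood as diagonal
measurement-error variance. Model comparison uses AICc. Because the
quantity of biological interest is how trait-space overlap between
species decays with divergence time, the fitted models are additionally
screened by a simulation-based rejection test on the Spearman
correlation between node age and nested-average overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from taxodelim.overlap import DEFAULT_N_BOXES

logger = logging.getLogger(__name__)

MODELS = ("BM", "EB", "OU")
_LOG2PI = math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------


@dataclass
class UltrametricTree:
    """Rooted ultrametric tree flattened for covariance computations."""

    tips: list[str]
    shared_time: np.ndarray  # (n, n): shared path length from root; diag = depth
    patristic: np.ndarray  # (n, n) tip-to-tip distances
    depth: float
    # internal nodes in postorder: (age, children), children as lists of tip
    # index sets per child clade, plus a recursive structure for nesting
    node_children: list[list["int | tuple"]] = field(default_factory=list)
    node_ages: np.ndarray = field(default_factory=lambda: np.array([]))
    _nodes: list = field(default_factory=list, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tips)


def tree_from_newick(newick: str, check_ultrametric: bool = True, tol: float = 1e-6):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree_info(tree, check_ultrametric=check_ultrametric, tol=tol)


def tree_info(tree, check_ultrametric: bool = True, tol: float = 1e-6) -> UltrametricTree:
    """Extract tip order, shared-time and patristic matrices, and the
    internal-node nesting structure from a dendropy tree."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    tips = [lf.taxon.label for lf in leaves]
    n = len(tips)
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    depths = np.array([lf.root_distance for lf in leaves])
    depth = float(depths.max())
    if check_ultrametric and np.any(np.abs(depths - depth) > tol * max(1.0, depth)):
        raise ValueError(
            "tree is not ultrametric: root-to-tip path lengths differ by "
            f"{float(depths.max() - depths.min()):.3g}"
        )
    shared = np.zeros((n, n))
    pat = np.zeros((n, n))
    # shared time of i,j = root distance of their MRCA
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        shared[i, i] = depths[i]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
            pat[i, j] = pat[j, i] = d
            # on an ultrametric tree: shared = depth - d/2; general: use mrca
            mrca = pdm.mrca(taxa[tips[i]], taxa[tips[j]])
            shared[i, j] = shared[j, i] = float(mrca.root_distance)
    # internal-node structure (postorder) for nested averaging
    nodes = []
    ages = []

    def clade(node):
        if node.is_leaf():
            return idx[id(node)]
        return tuple(clade(c) for c in node.child_nodes())

    for node in tree.postorder_internal_node_iter():
        children = [clade(c) for c in node.child_nodes()]
        age = depth - float(node.root_distance)
        nodes.append(children)
        ages.append(age)
    return UltrametricTree(
        tips=tips,
        shared_time=shared,
        patristic=pat,
        depth=depth,
        node_children=nodes,
        node_ages=np.asarray(ages),
    )


# ---------------------------------------------------------------------------
# Model covariance structures
# ---------------------------------------------------------------------------


def _phylo_cov(tree: UltrametricTree, model: str, param: float | None) -> np.ndarray:
    """Unit-rate among-species covariance for one trait."""
    C = tree.shared_time
    if model == "BM":
        return C
    if model == "EB":
        r = param
        if r is None or r > 1e-12:
            raise ValueError("EB requires r <= 0")
        if abs(r) < 1e-12:
            return C
        return (np.exp(r * C) - 1.0) / r
    if model == "OU":
        alpha = param
        if alpha is None or alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        return np.exp(-alpha * tree.patristic) / (2.0 * alpha)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class EvolFit:
    model: str
    R: np.ndarray  # (p, p) trait rate/covariance matrix
    root: np.ndarray  # (p,) root state (OU: optimum)
    alpha: float | None
    r: float | None
    log_likelihood: float
    k: int
    aicc: float
    converged: bool
    traits: list[str]
    tree: UltrametricTree = field(repr=False, default=None)
    se2: np.ndarray | None = field(repr=False, default=None)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """AICc = AIC + 2k(k+1)/(n-k-1); infinite when n <= k+1."""
    aic = -2.0 * log_likelihood + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _stack(means: np.ndarray) -> np.ndarray:
    # trait-major stacking: [trait0 over species, trait1 over species, ...]
    return means.T.reshape(-1)


def _loglik(
    y: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    se2_vec: np.ndarray,
    return_root: bool = False,
    reml: bool = False,
):
    """Gaussian log-likelihood with GLS-profiled root/optimum.

    V = kron(R, C) + diag(se2); mean = kron(I_p, 1) @ root. With
    `reml=True` the restricted likelihood (contrast space; the
    independent-contrasts likelihood for BM) is returned instead: the
    usual -0.5*log|X' V^-1 X| correction is added, so the univariate BM
    rate maximizes at the unbiased sum(pic^2)/(n-1).
    """
    n = C.shape[0]
    p = R.shape[0]
    V = np.kron(R, C) + np.diag(se2_vec)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return (-math.inf, None) if return_root else -math.inf
    X = np.kron(np.eye(p), np.ones((n, 1)))
    from scipy.linalg import solve_triangular

    Ly = solve_triangular(L, y, lower=True)
    LX = solve_triangular(L, X, lower=True)
    XtVX = LX.T @ LX
    XtVy = LX.T @ Ly
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return (-math.inf, None) if return_root else -math.inf
    resid = Ly - LX @ beta
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    n_eff = n * p
    ll = -0.5 * (resid @ resid + logdet + n_eff * _LOG2PI)
    if reml:
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return (-math.inf, None) if return_root else -math.inf
        ll += -0.5 * logdet_x + 0.5 * p * _LOG2PI
    if return_root:
        return float(ll), beta
    return float(ll)


def _chol_unpack(params: np.ndarray, p: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from packed params (log diag)."""
    L = np.zeros((p, p))
    k = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                L[i, j] = math.exp(params[k])
            else:
                L[i, j] = params[k]
            k += 1
    return L


def _chol_pack(R: np.ndarray) -> np.ndarray:
    p = R.shape[0]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(p))
    out = []
    for i in range(p):
        for j in range(i + 1):
            out.append(math.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.asarray(out)


def fit_model(
    means: pd.DataFrame,
    tree: UltrametricTree,
    model: str,
    se2: pd.DataFrame | None = None,
    n_starts: int = 3,
    seed: int = 0,
    reml: bool = False,
) -> EvolFit:
    """Maximum-likelihood fit of BM, EB or OU to species trait means.

    `means` is a species x traits table indexed by tip label; `se2`
    gives per-species squared standard errors (measurement error),
    zeros when omitted. The root (OU: optimum) is profiled out by GLS
    at each step; R is optimized through its Cholesky factor, and the
    EB rate r (<= 0) or OU pull alpha (> 0, log scale) jointly.

    With `reml=True` the restricted (contrast) likelihood is maximized:
    for univariate BM without measurement error the rate estimate then
    equals the unbiased independent-contrasts value sum(pic^2)/(n-1).
    Model comparison by AICc uses the default `reml=False`.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 species")
    means = means.loc[tree.tips]
    Y = means.to_numpy(dtype=float)
    n, p = Y.shape
    if se2 is not None:
        E2 = se2.loc[tree.tips].to_numpy(dtype=float)
    else:
        E2 = np.zeros_like(Y)
    se2_vec = _stack(E2)
    y = _stack(Y)
    C_bm = tree.shared_time

    # analytic BM start: GLS root + profiled R under zero measurement error
    Ci = np.linalg.inv(C_bm)
    one = np.ones(n)
    w = (one @ Ci) / (one @ Ci @ one)
    root0 = w @ Y
    Eres = Y - root0
    R0 = (Eres.T @ Ci @ Eres) / n
    R0 = R0 + 1e-8 * np.trace(R0 + 1e-12 * np.eye(p)) / p * np.eye(p)

    n_extra = 0 if model == "BM" else 1
    rng = np.random.default_rng(seed)

    def unpack(params):
        Lf = _chol_unpack(params[: params.size - n_extra], p)
        R = Lf @ Lf.T
        extra = params[-1] if n_extra else None
        if model == "EB":
            param = -math.exp(extra)  # r = -exp(u) <= 0
        elif model == "OU":
            param = math.exp(extra)  # alpha > 0
        else:
            param = None
        return R, param

    def neg_ll(params):
        R, param = unpack(params)
        try:
            C = _phylo_cov(tree, model, param)
        except ValueError:
            return 1e10
        ll = _loglik(y, R, C, se2_vec, reml=reml)
        return 1e10 if not math.isfinite(ll) else -ll

    base = _chol_pack(R0)
    starts = [np.concatenate([base, [math.log(0.5 / tree.depth)]])[: base.size + n_extra]]
    for _ in range(n_starts - 1):
        jitter = base + rng.normal(0, 0.5, size=base.size)
        extra = [rng.normal(math.log(1.0 / tree.depth), 1.0)] if n_extra else []
        starts.append(np.concatenate([jitter, extra]))

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_ll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    R, param = unpack(best.x)
    boundary_eb = False
    if model == "EB":
        # the boundary r=0 (BM) is inside EB's parameter space; take it
        # whenever the interior search does not beat the BM profile fit
        def neg_ll_bm(params):
            Rb = _chol_unpack(params, p) @ _chol_unpack(params, p).T
            ll = _loglik(y, Rb, C_bm, se2_vec, reml=reml)
            return 1e10 if not math.isfinite(ll) else -ll

        res_bm = optimize.minimize(neg_ll_bm, base, method="L-BFGS-B")
        if res_bm.fun <= best.fun or param > -1e-8:
            Lb = _chol_unpack(res_bm.x, p)
            R, param = Lb @ Lb.T, 0.0
            boundary_eb = True
    C = _phylo_cov(tree, "BM", None) if boundary_eb else _phylo_cov(tree, model, param)
    ll, beta = _loglik(y, R, C, se2_vec, return_root=True, reml=reml)
    converged = bool(best.success) and math.isfinite(ll)
    r_hat = param if model == "EB" else None
    alpha_hat = param if model == "OU" else None
    k = p * (p + 1) // 2 + p + n_extra
    fit = EvolFit(
        model=model,
        R=R,
        root=np.asarray(beta).ravel(),
        alpha=alpha_hat,
        r=r_hat,
        log_likelihood=float(ll),
        k=k,
        aicc=aicc(float(ll), k, n),
        converged=converged,
        traits=list(means.columns),
        tree=tree,
        se2=E2,
    )
    if not converged:
        logger.warning("fit of %s flagged: optimizer did not converge cleanly", model)
    return fit


def model_cov(fit: EvolFit) -> np.ndarray:
    """Among-species covariance kron(R, C_model) implied by a fit."""
    param = fit.alpha if fit.model == "OU" else fit.r
    C = _phylo_cov(fit.tree, fit.model, param)
    return np.kron(fit.R, C)


def simulate_species_means(
    fit: EvolFit,
    n_sims: int,
    seed: int = 0,
    add_measurement_error: bool = True,
    require_positive: bool = True,
    max_retries: int = 1000,
) -> np.ndarray:
    """Draw replicate species-mean datasets from a fitted model.

    Returns an array (n_sims, n_species, n_traits). Datasets containing
    a non-positive trait mean are redrawn (bounded retries) so the
    simulated traits stay in the positive domain of real measurements.
    """
    tree = fit.tree
    n, p = tree.n_tips, len(fit.traits)
    V = model_cov(fit)
    if add_measurement_error and fit.se2 is not None:
        V = V + np.diag(_stack(fit.se2))
    L = np.linalg.cholesky(V + 1e-12 * np.trace(V) / V.shape[0] * np.eye(V.shape[0]))
    mean = np.kron(np.eye(p), np.ones((n, 1))) @ fit.root
    rng = np.random.default_rng(seed)
    out = np.empty((n_sims, n, p))
    for s in range(n_sims):
        for attempt in range(max_retries):
            y = mean + L @ rng.standard_normal(n * p)
            data = y.reshape(p, n).T
            if not require_positive or np.all(data > 0):
                out[s] = data
                break
        else:
            raise RuntimeError(
                "positivity rejection exhausted retries; review model parameters"
            )
    return out


def sample_individuals(
    mean: np.ndarray,
    within_cov: np.ndarray,
    n: int,
    lower_bound: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100_000,
) -> np.ndarray:
    """Rejection-sample individuals from an MVN truncated below.

    Draws from N(mean, within_cov) and keeps vectors with all
    components above `lower_bound`; errors out if the acceptance rate
    collapses below 1e-4.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(within_cov, dtype=float))
    p = mean.size
    if np.allclose(cov, 0):
        if np.any(mean < lower_bound):
            raise ValueError("mean below truncation bound with zero covariance")
        return np.tile(mean, (n, 1))
    L = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / p * np.eye(p))
    out = np.empty((n, p))
    got, tried = 0, 0
    while got < n:
        batch = max(n - got, 64)
        draws = mean + rng.standard_normal((batch, p)) @ L.T
        ok = draws[np.all(draws >= lower_bound, axis=1)]
        take = min(len(ok), n - got)
        out[got : got + take] = ok[:take]
        got += take
        tried += batch
        if tried > max_tries and got / max(tried, 1) < 1e-4:
            raise RuntimeError("truncated-normal acceptance rate below 1e-4")
    return out


# ---------------------------------------------------------------------------
# Nested node-overlap profile and the age-overlap rejection test
# ---------------------------------------------------------------------------


def node_overlap_profile(
    tree: UltrametricTree, overlap: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nested-average overlap per internal node, plus Spearman r_s of
    (node age, overlap).

    The nested average of two clades is the mean over their children's
    cross-combinations, recursing down to pairwise tip overlaps; it
    summarizes the average overlap at each node without reconstructing
    ancestral states.
    """
    O = np.asarray(overlap, dtype=float)
    n = tree.n_tips
    if O.shape != (n, n):
        raise ValueError("overlap matrix shape must be (n_tips, n_tips)")
    if np.any(~np.isfinite(O[np.triu_indices(n, 1)])):
        raise ValueError("overlap missing for at least one species pair")

    def v(x, y):
        x_leaf, y_leaf = isinstance(x, int), isinstance(y, int)
        if x_leaf and y_leaf:
            return O[x, y]
        if x_leaf:
            return float(np.mean([v(x, c) for c in y]))
        return float(np.mean([v(c, y) for c in x]))

    values = []
    for children in tree.node_children:
        if len(children) != 2:
            raise ValueError("nested averaging assumes a binary tree")
        values.append(v(children[0], children[1]))
    values = np.asarray(values)
    if len(values) < 3:
        rs = math.nan
    else:
        rs = float(stats.spearmanr(tree.node_ages, values).statistic)
    return tree.node_ages.copy(), values, rs


def _overlap_matrix_fast(
    samples: list[np.ndarray], n_boxes: int = DEFAULT_N_BOXES
) -> np.ndarray:
    """Pairwise max asymmetric dynamic-range-box overlap across species.

    Computes each species' quantile boxes once, then evaluates all
    pairs by vectorized interval arithmetic (equivalent to drb_port on
    each pair).
    """
    levels = 0.5 * np.arange(n_boxes) / (n_boxes - 1)
    n = len(samples)
    p = samples[0].shape[1]
    lo = np.empty((n, p, n_boxes))
    hi = np.empty((n, p, n_boxes))
    for i, x in enumerate(samples):
        q_lo = np.quantile(x, levels, axis=0)  # (n_boxes, p)
        q_hi = np.quantile(x, 1 - levels, axis=0)
        lo[i] = q_lo.T
        hi[i] = q_hi.T
    O = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pij = 1.0
            pji = 1.0
            for d in range(p):
                inter = np.minimum(hi[i, d], hi[j, d]) - np.maximum(lo[i, d], lo[j, d])
                inter = np.clip(inter, 0.0, None)
                wi = hi[i, d] - lo[i, d]
                wj = hi[j, d] - lo[j, d]
                pi_d = np.where(
                    wi > 0,
                    inter / np.where(wi > 0, wi, 1.0),
                    ((lo[i, d] >= lo[j, d]) & (lo[i, d] <= hi[j, d])).astype(float),
                )
                pj_d = np.where(
                    wj > 0,
                    inter / np.where(wj > 0, wj, 1.0),
                    ((lo[j, d] >= lo[i, d]) & (lo[j, d] <= hi[i, d])).astype(float),
                )
                pij *= float(np.mean(pi_d))
                pji *= float(np.mean(pj_d))
            O[i, j] = O[j, i] = max(pij, pji)
    return O


def age_overlap_rs(
    datasets: np.ndarray,
    tree: UltrametricTree,
    within_cov: np.ndarray,
    n_per_species: np.ndarray | int,
    rng: np.random.Generator,
    n_boxes: int = DEFAULT_N_BOXES,
) -> np.ndarray:
    """Spearman r_s of (node age, nested overlap) for each simulated
    species-mean dataset, sampling individuals around each mean."""
    n_sp = tree.n_tips
    if np.isscalar(n_per_species):
        n_per_species = np.full(n_sp, int(n_per_species))
    out = np.empty(len(datasets))
    for s, data in enumerate(datasets):
        samples = [
            sample_individuals(data[i], within_cov, int(n_per_species[i]), seed=rng)
            for i in range(n_sp)
        ]
        O = _overlap_matrix_fast(samples, n_boxes)
        _, _, rs = node_overlap_profile(tree, O)
        out[s] = rs
    return out


def age_overlap_test(
    observed_rs: float,
    fit: EvolFit,
    within_cov: np.ndarray,
    n_per_species: np.ndarray | int,
    n_sims: int = 1000,
    seed: int = 0,
    n_boxes: int = DEFAULT_N_BOXES,
) -> dict:
    """Simulation-based rejection test of a fitted model.

    The model is rejected when the observed r_s lies above the 0.95 or
    below the 0.05 quantile of the r_s distribution simulated under the
    fit (two 5% tails, nominal level 0.10).
    """
    rng = np.random.default_rng(seed)
    datasets = simulate_species_means(fit, n_sims, seed=int(rng.integers(2**31)))
    sims = age_overlap_rs(datasets, fit.tree, within_cov, n_per_species, rng, n_boxes)
    sims = sims[np.isfinite(sims)]
    q05, q95 = np.quantile(sims, [0.05, 0.95])
    reject = bool(observed_rs > q95 or observed_rs < q05)
    return {
        "model": fit.model,
        "observed_rs": observed_rs,
        "q05": float(q05),
        "q95": float(q95),
        "reject": reject,
        "simulated_rs": sims,
        "seed": seed,
    }


def cross_validation(
    fits: dict[str, EvolFit],
    within_cov: np.ndarray,
    n_per_species: np.ndarray | int,
    n_datasets: int = 100,
    n_sims: int = 500,
    seed: int = 0,
    n_boxes: int = DEFAULT_N_BOXES,
) -> dict:
    """Rejection-power cross-validation between BM and OU generators.

    For each generating model, `n_datasets` replicate datasets are
    simulated, each refit under both models and screened by the
    age-overlap rejection rule (null r_s distributions of `n_sims`
    simulations each); outcomes are tallied into the four categories
    reject-BM / reject-OU / reject-both / reject-neither, alongside the
    frequency with which AICc picks the generating model.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(seed)
    results: dict[str, dict] = {}
    for gen_name, gen_fit in fits.items():
        tree = gen_fit.tree
        datasets = simulate_species_means(gen_fit, n_datasets, seed=int(rng.integers(2**31)))
        cats = {"reject_BM": 0, "reject_OU": 0, "reject_both": 0, "reject_neither": 0}
        aicc_correct = 0
        for d in range(n_datasets):
            obs = pd.DataFrame(datasets[d], index=tree.tips, columns=gen_fit.traits)
            # observed statistic from individuals sampled around the means
            obs_samples = [
                sample_individuals(datasets[d][i], within_cov, _n_of(n_per_species, i), seed=rng)
                for i in range(tree.n_tips)
            ]
            _, _, obs_rs = node_overlap_profile(tree, _overlap_matrix_fast(obs_samples, n_boxes))
            rejected = {}
            fits_d = {}
            for m in ("BM", "OU"):
                f = fit_model(obs, tree, m, seed=int(rng.integers(2**31)), n_starts=2)
                fits_d[m] = f
                res = age_overlap_test(
                    obs_rs, f, within_cov, n_per_species,
                    n_sims=n_sims, seed=int(rng.integers(2**31)), n_boxes=n_boxes,
                )
                rejected[m] = res["reject"]
            if rejected["BM"] and rejected["OU"]:
                cats["reject_both"] += 1
            elif rejected["BM"]:
                cats["reject_BM"] += 1
            elif rejected["OU"]:
                cats["reject_OU"] += 1
            else:
                cats["reject_neither"] += 1
            picked = min(fits_d, key=lambda m: fits_d[m].aicc)
            if picked == gen_name:
                aicc_correct += 1
        results[gen_name] = {
            "categories": {k: v / n_datasets for k, v in cats.items()},
            "aicc_correct_rate": aicc_correct / n_datasets,
            "n_datasets": n_datasets,
        }
    return results


def _n_of(n_per_species, i: int) -> int:
    return int(n_per_species) if np.isscalar(n_per_species) else int(n_per_species[i])


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------


def blomberg_k(trait: np.ndarray | pd.Series, tree: UltrametricTree) -> float:
    """Blomberg's K: observed MSE0/MSE over its BM expectation.

    K = 1 for traits evolving by BM on the tree; K < 1 for less signal
    than BM, K > 1 for more.
    """
    y = _align_trait(trait, tree)
    n = tree.n_tips
    if n < 4:
        raise ValueError("need at least 4 species")
    C = tree.shared_time
    if np.allclose(C[~np.eye(n, dtype=bool)], 0):
        raise ValueError("star tree: K undefined")
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a_hat = (one @ Ci @ y) / (one @ Ci @ one)
    dev = y - a_hat
    mse0 = dev @ dev / (n - 1)
    mse = dev @ Ci @ dev / (n - 1)
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return float((mse0 / mse) / expected)


def pagels_lambda(
    trait: np.ndarray | pd.Series, tree: UltrametricTree
) -> tuple[float, float]:
    """ML estimate of Pagel's lambda in [0, 1] and its log-likelihood.

    lambda scales the off-diagonal (shared) covariance; 0 = no signal
    (iid tips), 1 = BM covariance.
    """
    y = _align_trait(trait, tree)
    n = tree.n_tips
    C = tree.shared_time
    diag = np.diag(np.diag(C))

    def neg_ll(lam):
        Cl = lam * (C - diag) + diag
        try:
            L = np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError:
            return 1e10
        from scipy.linalg import cho_solve

        Ci_y = cho_solve((L, True), y)
        Ci_1 = cho_solve((L, True), np.ones(n))
        a = (np.ones(n) @ Ci_y) / (np.ones(n) @ Ci_1)
        dev = y - a
        Ci_dev = cho_solve((L, True), dev)
        s2 = dev @ Ci_dev / n
        if s2 <= 0:
            return 1e10
        logdet = 2 * np.sum(np.log(np.diag(L)))
        return 0.5 * (n * math.log(s2) + logdet + n * (1 + _LOG2PI))

    res = optimize.minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded")
    return float(res.x), float(-res.fun)


def _align_trait(trait, tree: UltrametricTree) -> np.ndarray:
    if isinstance(trait, pd.Series):
        return trait.loc[tree.tips].to_numpy(dtype=float)
    return np.asarray(trait, dtype=float)
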
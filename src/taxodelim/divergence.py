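"""Genealogical divergence index, divergence-time conversion, and
cladistic checks on candidate pairs.

The gdi maps a pair's multispecies-coalescent divergence time tau
(expected substitutions per site) and the relevant population mutation
parameter theta (4*Ne*mu per site) onto [0, 1):

    gdi = 1 - exp(-2 * tau / theta)

gdi ~ 0 for a single panmictic population and -> 1 for long-isolated
lineages; values below 0.2 are taken as evidence to synonymize (the
index is never used on its own to confirm a split). Posterior traces of
tau and theta give the gdi posterior mean and 95% HPD interval.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

GDI_SYNONYMY_THRESHOLD = 0.2
DEFAULT_MU = 1.236e-8  # mutations / site / generation
DEFAULT_GEN_TIME = 3.5  # years / generation


def gdi(tau: float, theta: float) -> float:
    """gdi = 1 - exp(-2 tau / theta); strictly increasing in tau,
    decreasing in theta."""
    tau = np.asarray(tau, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    out = 1.0 - np.exp(-2.0 * tau / theta)
    return float(out) if out.ndim == 0 else out


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `mass` of the draws (ties -> lowest
    start)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no draws")
    k = max(1, int(math.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 + np.arange(n - k + 1)] - x[: n - k + 1]
    wmin = widths.min()
    # lowest start among numerically tied widths
    i = int(np.flatnonzero(widths <= wmin + 1e-12 * max(1.0, abs(wmin)))[0])
    return float(x[i]), float(x[i + k - 1])


@dataclass
class GdiEstimate:
    pair: tuple[str, str]
    theta_source: str
    mean: float
    hpd_low: float
    hpd_high: float
    n_draws: int

    def synonymy_indicated(self, threshold: float = GDI_SYNONYMY_THRESHOLD) -> bool:
        return self.mean < threshold


def read_trace(path: str, burn_in: float = 0.2) -> pd.DataFrame:
    """Read a BPP A00-style whitespace-delimited posterior trace.

    Column names are kept verbatim; the leading `burn_in` fraction of
    rows is discarded (pass 0.0 for pre-thinned traces).
    """
    t = pd.read_csv(path, sep=r"\s+")
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    start = int(len(t) * burn_in)
    return t.iloc[start:].reset_index(drop=True)


def trace_columns(trace: pd.DataFrame, prefix: str) -> list[str]:
    pat = re.compile(rf"^{re.escape(prefix)}", re.IGNORECASE)
    return [c for c in trace.columns if pat.search(c)]


def gdi_posterior(
    trace: pd.DataFrame,
    tau_col: str,
    theta_col: str,
    pair: tuple[str, str] = ("A", "B"),
    min_draws: int = 100,
) -> GdiEstimate:
    """Per-draw gdi with posterior mean and shortest 95% HPD interval."""
    for col in (tau_col, theta_col):
        if col not in trace.columns:
            raise KeyError(
                f"column {col!r} not in trace; available: {list(trace.columns)}"
            )
    if len(trace) < min_draws:
        raise ValueError(f"only {len(trace)} post-burn-in draws; need >= {min_draws}")
    vals = gdi(trace[tau_col].to_numpy(), trace[theta_col].to_numpy())
    lo, hi = hpd_interval(vals, 0.95)
    return GdiEstimate(
        pair=pair,
        theta_source=theta_col,
        mean=float(np.mean(vals)),
        hpd_low=lo,
        hpd_high=hi,
        n_draws=len(vals),
    )


@dataclass
class TimeCalibration:
    """Mutation-rate / generation-time calibration for tau -> years.

    When `mu_sd` and `g_log_sd` are given, uncertainty is propagated by
    Monte Carlo with mu ~ Gamma(mean=mu, sd=mu_sd) and
    g ~ Lognormal(log-mean=log(g), log-sd=g_log_sd).
    """

    mu: float = DEFAULT_MU
    g: float = DEFAULT_GEN_TIME
    mu_sd: float | None = None
    g_log_sd: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.g <= 0:
            raise ValueError("mu and g must be positive")


def tau_to_years(
    tau: float,
    calib: TimeCalibration | None = None,
    n_draws: int = 0,
    seed: int = 0,
) -> dict:
    """Convert tau (expected substitutions/site) to calendar years.

    Point estimate: tau / mu * g generations-to-years. With calibration
    distributions supplied and n_draws > 0, a seeded Monte-Carlo 95%
    interval is added.
    """
    calib = calib or TimeCalibration()
    point = tau / calib.mu * calib.g
    out = {"years": float(point)}
    if n_draws > 0 and (calib.mu_sd is not None or calib.g_log_sd is not None):
        rng = np.random.default_rng(seed)
        if calib.mu_sd is not None:
            shape = (calib.mu / calib.mu_sd) ** 2
            scale = calib.mu_sd**2 / calib.mu
            mu = rng.gamma(shape, scale, size=n_draws)
        else:
            mu = np.full(n_draws, calib.mu)
        if calib.g_log_sd is not None:
            g = rng.lognormal(math.log(calib.g), calib.g_log_sd, size=n_draws)
        else:
            g = np.full(n_draws, calib.g)
        draws = tau / mu * g
        lo, hi = np.quantile(draws, [0.025, 0.975])
        out.update({"ci_low": float(lo), "ci_high": float(hi), "n_draws": n_draws})
    return out


def reciprocal_monophyly(
    tree, tip_to_candidate: dict[str, str], pair: tuple[str, str]
) -> dict:
    """Monophyly of each candidate and jointly, on a rooted dendropy tree.

    A candidate is monophyletic iff the MRCA of its tips has no tip of
    the other candidate among its descendants.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("expected a dendropy.Tree")
    root = tree.seed_node
    if len(root.child_nodes()) > 2 and not tree.is_rooted:
        raise ValueError(
            "tree appears unrooted; root it with an outgroup before testing monophyly"
        )
    labels_in_tree = {lf.taxon.label for lf in tree.leaf_node_iter()}
    tips = {
        c: {t for t, cc in tip_to_candidate.items() if cc == c} & labels_in_tree
        for c in pair
    }
    for c in pair:
        if not tips[c]:
            raise ValueError(f"no tips of candidate {c!r} present in the tree")
    result = {}
    for c in pair:
        other = pair[1] if c == pair[0] else pair[0]
        mrca = tree.mrca(taxon_labels=list(tips[c]))
        desc = {lf.taxon.label for lf in mrca.leaf_iter()}
        result[c] = len(desc & tips[other]) == 0
    result["joint"] = result[pair[0]] and result[pair[1]]
    return result


def admixture_flags(
    q_matrix: np.ndarray,
    sample_ids: list[str] | None = None,
    threshold: float = 0.9,
    tol: float = 1e-6,
) -> list[str] | list[int]:
    """Individuals whose maximum ancestry proportion falls below
    `threshold` (putatively admixed)."""
    q = np.asarray(q_matrix, dtype=float)
    if q.ndim != 2 or q.shape[1] < 2:
        raise ValueError("Q matrix must be individuals x K with K >= 2")
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
        raise ValueError(f"Q rows do not sum to 1: rows {bad.tolist()}")
    flagged = np.flatnonzero(q.max(axis=1) < threshold)
    if sample_ids is not None:
        return [sample_ids[i] for i in flagged]
    return flagged.tolist()
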
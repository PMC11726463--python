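"""The 4-step NRMSE isolation-by-distance heuristic.

For each genomic window, an ordinary least-squares cline of pairwise pi
on log10 geographic distance is fitted within each candidate (step 2).
Between-candidate pairs are then scored by how far their observed pi
deviates from the focal candidate's cline prediction, as a root mean
square error normalized by the within-candidate pi standard deviation
(step 3). The resulting per-window NRMSE distributions are compared to
empirical null distributions built from benchmark taxa with
well-characterized intraspecific structure (step 4): the intraspecific
clinal model is rejected when the 0.05 quantiles of both candidates'
NRMSE distributions exceed the benchmark 0.95 quantiles, and the pair
is called congruent with intraspecific structure when at least one
candidate's 0.95 quantile falls below them.

A morphometric variant replaces genomic windows with resampled
combinations of trait variables.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from taxodelim.gendist import DistanceRecords, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class IBDCline:
    """Within-candidate OLS cline of pi on log10 distance for one window."""

    candidate: str
    window: int
    slope: float
    intercept: float
    n_pairs: int
    within_sd: float  # sample sd of the within-candidate pi values

    def predict(self, log_geo: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_geo, dtype=float)


@dataclass
class NRMSEDist:
    """Per-window NRMSE values for a candidate pair from one focal cline."""

    pair: tuple[str, str]
    focal: str
    values: np.ndarray

    @property
    def q05(self) -> float:
        return float(np.quantile(self.values, 0.05))

    @property
    def q50(self) -> float:
        return float(np.quantile(self.values, 0.50))

    @property
    def q95(self) -> float:
        return float(np.quantile(self.values, 0.95))


@dataclass
class ReferenceNull:
    """Empirical benchmark NRMSE distribution treated as a null."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[np.isfinite(self.values)]
        if len(self.values) == 0:
            raise ValueError("reference null has no finite NRMSE values")

    @property
    def q95(self) -> float:
        return float(np.quantile(self.values, 0.95))

    def to_dict(self) -> dict:
        return {"label": self.label, "values": self.values.tolist(), "q95": self.q95}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceNull":
        return cls(d["label"], np.asarray(d["values"], dtype=float))


@dataclass
class IBDVerdict:
    verdict: str  # reject_intraspecific | congruent_intraspecific | inconclusive
    q05_a: float
    q05_b: float
    q95_a: float
    q95_b: float
    ref_q95: list[float]
    mode: str = "all"


def fit_ibd_cline(
    log_geo: np.ndarray,
    pi: np.ndarray,
    candidate: str = "",
    window: int = -1,
    min_pairs: int = 3,
) -> IBDCline | None:
    """OLS fit of pi on log10 distance over within-candidate pairs.

    Returns None (window skipped) with fewer than `min_pairs` usable
    pairs. `within_sd` is the sample standard deviation (ddof=1) of the
    pi values entering the fit; it normalizes the NRMSE downstream.
    """
    log_geo = np.asarray(log_geo, dtype=float)
    pi = np.asarray(pi, dtype=float)
    ok = np.isfinite(log_geo) & np.isfinite(pi)
    if ok.sum() < min_pairs:
        logger.warning(
            "window %s of %s skipped: %d usable pairs < %d",
            window, candidate, int(ok.sum()), min_pairs,
        )
        return None
    x, y = log_geo[ok], pi[ok]
    slope, intercept = np.polyfit(x, y, 1)
    return IBDCline(
        candidate=candidate,
        window=window,
        slope=float(slope),
        intercept=float(intercept),
        n_pairs=int(ok.sum()),
        within_sd=float(np.std(y, ddof=1)),
    )


def nrmse_window(log_geo: np.ndarray, pi: np.ndarray, cline: IBDCline) -> float:
    """RMSE of between-candidate pi around the cline prediction, over
    the within-candidate pi standard deviation.

    Missing when the within sd is zero (no within-candidate variation to
    normalize by) or no between-candidate pair is usable.
    """
    log_geo = np.asarray(log_geo, dtype=float)
    pi = np.asarray(pi, dtype=float)
    ok = np.isfinite(log_geo) & np.isfinite(pi)
    if not ok.any() or cline.within_sd == 0 or not math.isfinite(cline.within_sd):
        return math.nan
    resid = pi[ok] - cline.predict(log_geo[ok])
    return float(np.sqrt(np.mean(resid**2)) / cline.within_sd)


def _pair_arrays(
    dist: DistanceRecords,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    window: int,
    within: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """log10 distance and pi vectors for pairs within one group (within=True)
    or across two groups; zero-distance pairs are dropped (log undefined)."""
    if within:
        ii, jj = np.triu_indices(len(idx_a), k=1)
        rows, cols = idx_a[ii], idx_a[jj]
    else:
        rows = np.repeat(idx_a, len(idx_b))
        cols = np.tile(idx_b, len(idx_a))
    geo = dist.geo_km[rows, cols]
    pi = dist.pi[rows, cols, window]
    keep = geo > 0
    with np.errstate(divide="ignore"):
        return np.log10(geo[keep]), pi[keep]


def nrmse_distributions(
    dist: DistanceRecords,
    samples: SampleTable,
    pair: tuple[str, str],
    min_pairs: int = 3,
) -> tuple[NRMSEDist, NRMSEDist]:
    """Per-window NRMSE distributions for a candidate pair, one per focal
    candidate's within cline."""
    cand = samples.candidate_of()
    ids = dist.sample_ids
    idx = {
        c: np.array([k for k, s in enumerate(ids) if cand.get(s) == c], dtype=int)
        for c in pair
    }
    for c in pair:
        if len(idx[c]) < 3:
            raise ValueError(f"candidate {c!r} has fewer than 3 genotyped individuals")
    n_windows = dist.pi.shape[2]
    out: dict[str, list[float]] = {pair[0]: [], pair[1]: []}
    for w in range(n_windows):
        bx, by = _pair_arrays(dist, idx[pair[0]], idx[pair[1]], w, within=False)
        for focal in pair:
            wx, wy = _pair_arrays(dist, idx[focal], idx[focal], w, within=True)
            cline = fit_ibd_cline(wx, wy, candidate=focal, window=w, min_pairs=min_pairs)
            if cline is None:
                continue
            val = nrmse_window(bx, by, cline)
            if math.isfinite(val):
                out[focal].append(val)
    return (
        NRMSEDist(pair, pair[0], np.asarray(out[pair[0]])),
        NRMSEDist(pair, pair[1], np.asarray(out[pair[1]])),
    )


def ibd_decision(
    nrmse_a: NRMSEDist,
    nrmse_b: NRMSEDist,
    refs: list[ReferenceNull],
    mode: str = "all",
) -> IBDVerdict:
    """Quantile decision rule against benchmark nulls.

    reject_intraspecific: the 0.05 quantiles of both candidates' NRMSE
    distributions lie above the benchmark 0.95 quantiles. congruent:
    the 0.95 quantile of at least one candidate distribution lies below
    them. `mode` controls how multiple references combine: "all"
    (conservative; reject needs to exceed every reference, congruence to
    undercut every reference) or "any".
    """
    if not refs:
        raise ValueError("at least one reference null is required")
    if len(nrmse_a.values) == 0 or len(nrmse_b.values) == 0:
        raise ValueError("empty NRMSE distribution")
    if mode not in {"all", "any"}:
        raise ValueError(f"unknown reference mode {mode!r}")
    ref_q95 = [r.q95 for r in refs]
    reject_bar = max(ref_q95) if mode == "all" else min(ref_q95)
    congruent_bar = min(ref_q95) if mode == "all" else max(ref_q95)
    verdict = "inconclusive"
    if nrmse_a.q05 > reject_bar and nrmse_b.q05 > reject_bar:
        verdict = "reject_intraspecific"
    elif nrmse_a.q95 < congruent_bar or nrmse_b.q95 < congruent_bar:
        verdict = "congruent_intraspecific"
    return IBDVerdict(
        verdict=verdict,
        q05_a=nrmse_a.q05,
        q05_b=nrmse_b.q05,
        q95_a=nrmse_a.q95,
        q95_b=nrmse_b.q95,
        ref_q95=ref_q95,
        mode=mode,
    )


def build_reference_null(
    dist: DistanceRecords,
    group_of: dict[str, str],
    within_groups: list[str],
    between_groups: list[tuple[str, str]],
    label: str = "benchmark",
    min_pairs: int = 3,
) -> ReferenceNull:
    """Pool per-window NRMSE values from a benchmark taxon.

    Within-group pairs of each listed group fit the clines; pairs across
    each listed group tuple provide the "between" deviations, emulating
    fragmented-vs-continuous population comparisons.
    """
    ids = dist.sample_ids
    idx = {
        g: np.array([k for k, s in enumerate(ids) if group_of.get(s) == g], dtype=int)
        for g in set(group_of.values())
    }
    if not between_groups:
        raise ValueError("at least one between-group pair is required")
    values: list[float] = []
    n_windows = dist.pi.shape[2]
    for w in range(n_windows):
        clines = {}
        for g in within_groups:
            if len(idx[g]) < 3:
                logger.warning("benchmark group %s excluded: < 3 individuals", g)
                continue
            wx, wy = _pair_arrays(dist, idx[g], idx[g], w, within=True)
            c = fit_ibd_cline(wx, wy, candidate=g, window=w, min_pairs=min_pairs)
            if c is not None:
                clines[g] = c
        for ga, gb in between_groups:
            bx, by = _pair_arrays(dist, idx[ga], idx[gb], w, within=False)
            for g in (ga, gb):
                if g in clines:
                    val = nrmse_window(bx, by, clines[g])
                    if math.isfinite(val):
                        values.append(val)
    return ReferenceNull(label, np.asarray(values))


# ---------------------------------------------------------------------------
# Morphometric variant
# ---------------------------------------------------------------------------


@dataclass
class MorphoIBDResult:
    classification: str  # not_at_IBD | fits_intraspecific_IBD | inconclusive | insufficient_data
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    nrmse: dict[str, np.ndarray] = field(default_factory=dict)
    n_replicates: int = 0
    seed: int | None = None
    note: str = ""

    @property
    def p_q95(self) -> float:
        vals = self.p_values[np.isfinite(self.p_values)]
        return float(np.quantile(vals, 0.95)) if len(vals) else math.nan


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _euclidean_nan(x: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance on rows, averaging over shared
    non-missing variables (scaled back to full dimensionality)."""
    n, p = x.shape
    d = np.zeros((n, n))
    mask = np.isfinite(x)
    for i in range(n):
        diff = x - x[i]
        ok = mask & mask[i]
        sq = np.where(ok, diff**2, 0.0)
        cnt = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.sqrt(np.where(cnt > 0, sq.sum(axis=1) * p / np.maximum(cnt, 1), np.nan))
    return d


def _spearman_perm_p(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator, n_perm: int = 999
) -> float:
    """Permutation p-value (one-sided, positive association) of the
    Spearman correlation between two pairwise-distance vectors."""
    if np.all(y == y[0]) or np.all(x == x[0]):
        return math.nan
    r_obs = stats.spearmanr(x, y).statistic
    if not math.isfinite(r_obs):
        return math.nan
    count = 0
    for _ in range(n_perm):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if r >= r_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def morpho_ibd_test(
    traits: pd.DataFrame,
    samples: SampleTable,
    pair: tuple[str, str],
    ref: ReferenceNull,
    n_reps: int = 200,
    min_records: int = 5,
    max_missing_frac: float = 0.7,
    n_perm: int = 199,
    seed: int = 0,
    max_group_size: int = 150,
) -> MorphoIBDResult:
    """Test whether morphometric variation fits an intraspecific IBD cline.

    `traits` columns: id, then numeric variables. Replicates resample
    variable combinations (maximizing the number of variables; falling
    back to individual resampling when fewer than 50 combinations
    exist). Each replicate yields the permutation p-value of the
    Spearman correlation between pairwise geographic and morphometric
    distances, plus a per-focal-candidate NRMSE computed exactly as in
    the genomic procedure. Classification: not_at_IBD when the 0.95
    quantile of the p-values exceeds 0.05; fits_intraspecific_IBD when
    at least one candidate's NRMSE median is below the reference 0.95
    quantile; otherwise inconclusive.
    """
    rng = np.random.default_rng(seed)
    cand = samples.candidate_of()
    coords = samples.coords_of()
    t = traits.set_index(traits.columns[0])
    t = t.loc[[i for i in t.index if cand.get(i) in pair]]
    var_cols = list(t.columns)

    # drop variables entirely missing in either candidate
    keep_vars = []
    for v in var_cols:
        ok = True
        for c in pair:
            sub = t.loc[[i for i in t.index if cand[i] == c], v]
            if not np.isfinite(sub.astype(float)).any():
                ok = False
        if ok:
            keep_vars.append(v)
    t = t[keep_vars].astype(float)
    # drop individuals with > 70% missing
    frac_missing = (~np.isfinite(t.values)).mean(axis=1)
    t = t.loc[frac_missing <= max_missing_frac]

    sizes = {c: sum(1 for i in t.index if cand[i] == c) for c in pair}
    if min(sizes.values()) < min_records:
        return MorphoIBDResult(
            "insufficient_data",
            note=f"candidate record counts {sizes} below minimum {min_records}",
            seed=seed,
        )

    # down-sample very large candidates once per replicate below
    n_vars = len(keep_vars)
    combos = None
    for k in range(n_vars, 0, -1):
        n_comb = math.comb(n_vars, k)
        if n_comb >= 50:
            combos = list(itertools.combinations(range(n_vars), k))
            break
    resample_individuals = combos is None
    if combos is not None and len(combos) > n_reps:
        sel = rng.choice(len(combos), size=n_reps, replace=False)
        combos = [combos[int(s)] for s in sel]

    ids = list(t.index)
    geo = np.array(
        [
            [
                _haversine_pair(coords[a], coords[b])
                for b in ids
            ]
            for a in ids
        ]
    )
    cand_idx = {c: np.array([k for k, i in enumerate(ids) if cand[i] == c]) for c in pair}
    x_full = t.values

    n_actual = len(combos) if combos is not None else n_reps
    p_values = np.full(n_actual, np.nan)
    nrmse: dict[str, list[float]] = {pair[0]: [], pair[1]: []}
    iu = np.triu_indices(len(ids), k=1)
    for r in range(n_actual):
        if resample_individuals:
            sub = np.sort(
                rng.choice(len(ids), size=max(min_records * 2, int(0.8 * len(ids))), replace=False)
            )
            x = x_full[sub]
            g = geo[np.ix_(sub, sub)]
            groups = {c: np.flatnonzero(np.isin(sub, cand_idx[c])) for c in pair}
        else:
            cols = list(combos[r])
            x = x_full[:, cols]
            g = geo
            groups = cand_idx
        for c in pair:
            if len(groups[c]) > max_group_size:
                keep = np.sort(rng.choice(groups[c], size=max_group_size, replace=False))
                groups = {**groups, c: keep}
        md = _euclidean_nan(_zscore(x))
        keep_rows = np.sort(np.concatenate([groups[pair[0]], groups[pair[1]]]))
        sub_iu = np.triu_indices(len(keep_rows), k=1)
        gsub = g[np.ix_(keep_rows, keep_rows)]
        msub = md[np.ix_(keep_rows, keep_rows)]
        gv, mv = gsub[sub_iu], msub[sub_iu]
        ok = np.isfinite(gv) & np.isfinite(mv) & (gv > 0)
        p_values[r] = _spearman_perm_p(gv[ok], mv[ok], rng, n_perm=n_perm)
        # NRMSE exactly as in the genomic procedure, per focal candidate
        pos = {v: k for k, v in enumerate(keep_rows)}
        for focal in pair:
            fi = np.array([pos[v] for v in groups[focal]])
            oi = np.array([pos[v] for v in groups[pair[1] if focal == pair[0] else pair[0]]])
            wi, wj = np.triu_indices(len(fi), k=1)
            wgeo, wpi = gsub[fi[wi], fi[wj]], msub[fi[wi], fi[wj]]
            wok = np.isfinite(wgeo) & np.isfinite(wpi) & (wgeo > 0)
            cline = fit_ibd_cline(np.log10(wgeo[wok]), wpi[wok], candidate=focal, window=r)
            if cline is None:
                continue
            bi = np.repeat(fi, len(oi))
            bj = np.tile(oi, len(fi))
            bgeo, bpi = gsub[bi, bj], msub[bi, bj]
            bok = np.isfinite(bgeo) & np.isfinite(bpi) & (bgeo > 0)
            val = nrmse_window(np.log10(bgeo[bok]), bpi[bok], cline)
            if math.isfinite(val):
                nrmse[focal].append(val)

    nrmse_arr = {c: np.asarray(v) for c, v in nrmse.items()}
    finite_p = p_values[np.isfinite(p_values)]
    if len(finite_p) == 0:
        return MorphoIBDResult(
            "not_at_IBD",
            p_values=p_values,
            nrmse=nrmse_arr,
            n_replicates=n_actual,
            seed=seed,
            note="degenerate traits: correlations undefined",
        )
    p_q95 = float(np.quantile(finite_p, 0.95))
    if p_q95 > 0.05:
        cls = "not_at_IBD"
    else:
        medians = [
            float(np.quantile(v, 0.5)) for v in nrmse_arr.values() if len(v) > 0
        ]
        if medians and min(medians) < ref.q95:
            cls = "fits_intraspecific_IBD"
        else:
            cls = "inconclusive"
    return MorphoIBDResult(
        cls,
        p_values=p_values,
        nrmse=nrmse_arr,
        n_replicates=n_actual,
        seed=seed,
    )


def _haversine_pair(a: tuple[float, float], b: tuple[float, float]) -> float:
    from taxodelim.gendist import haversine_km

    return haversine_km(a[0], a[1], b[0], b[1])
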
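"""Synthetic data generators for every pipeline input.

The spatial genotype simulator is a one-dimensional stepping-stone
surrogate: per SNP, deme allele-frequency deviations from an ancestral
frequency form a stationary, mean-reverting AR(1) chain along a line of
demes, with the chain decorrelated at the labelled candidate boundary.
This produces exactly the two features the NRMSE-IBD test consumes —
distance decay of genetic similarity within candidates and an optional
discontinuity between them — at O(n) cost without coalescent machinery.
(Mean reversion matters: pi is bilinear in the two allele frequencies,
so a pure random walk yields no expected distance decay at all.)

Companion generators produce spatial trait clines, lognormal
pseudo-posterior tau/theta traces, environmental occurrence scatters,
and pure-birth ultrametric trees. All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from taxodelim.gendist import (
    GenotypeWindowSet,
    SampleTable,
    window_partition,
)


@dataclass
class SpatialSimConfig:
    """Stepping-stone genotype simulation settings.

    Defaults are desk-scale: 8 demes spaced 20 km apart with 4 diploids
    each, split into two equal candidates at the middle, and 20 windows
    of 250 SNPs. Per SNP, deme allele-frequency deviations from the
    ancestral frequency follow a stationary AR(1) chain along the deme
    line (retained per-step correlation `phi`, innovation sd
    sigma_step), so genetic similarity decays with distance — the IBD
    signal a pure random walk cannot produce, because pi is bilinear in
    the two frequencies and a martingale leaves E[p_i p_j] independent
    of distance. sigma_div is the sd of an extra independent innovation
    injected at the candidate boundary, which decorrelates the two
    candidates' deviations (0 = one continuous population; >> the
    stationary sd = essentially independent frequency fields).
    """

    n_demes: int = 8
    deme_spacing_km: float = 20.0
    individuals_per_deme: int = 4
    n_windows: int = 20
    snps_per_window: int = 250
    sigma_step: float = 0.12
    sigma_div: float = 0.0
    phi: float = 0.9
    seed: int = 0
    candidate_labels: tuple[str, str] = ("A", "B")
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_demes, self.individuals_per_deme, self.n_windows, self.snps_per_window) < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma_step < 0 or self.sigma_div < 0:
            raise ValueError("step/divergence sds must be >= 0")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")


def deep_split_config(**overrides) -> SpatialSimConfig:
    """Preset for a strongly diverged candidate pair (deep split): the
    boundary innovation dwarfs the stationary sd, so the candidates'
    frequency fields are nearly independent."""
    cfg = SpatialSimConfig(sigma_div=0.5)
    return replace(cfg, **overrides)


def simulate_spatial_genotypes(
    cfg: SpatialSimConfig,
) -> tuple[GenotypeWindowSet, SampleTable]:
    """Simulate windowed genotypes and metadata under the stepping-stone
    surrogate described in the module docstring."""
    rng = np.random.default_rng(cfg.seed)
    n_snps = cfg.n_windows * cfg.snps_per_window
    n_demes = cfg.n_demes
    boundary = n_demes // 2  # first deme of the second candidate
    anc = rng.uniform(0.1, 0.9, size=n_snps)
    # stationary AR(1) deviations: sd s, per-step correlation phi;
    # the boundary step retains correlation phi * exp(-sigma_div^2 / 2 s^2)
    s = cfg.sigma_step / math.sqrt(1.0 - cfg.phi**2) if cfg.phi > 0 else cfg.sigma_step
    u = np.empty((n_demes, n_snps))
    u[0] = rng.normal(0.0, s, size=n_snps) if s > 0 else 0.0
    for d in range(1, n_demes):
        c = cfg.phi
        if d == boundary and s > 0:
            c = cfg.phi * math.exp(-0.5 * (cfg.sigma_div / s) ** 2)
        innov_sd = s * math.sqrt(max(0.0, 1.0 - c**2))
        u[d] = c * u[d - 1] + rng.normal(0.0, innov_sd, size=n_snps)
    freqs = np.clip(anc + u, 0.0, 1.0)
    n_ind = n_demes * cfg.individuals_per_deme
    geno = np.empty((n_ind, n_snps), dtype=np.int8)
    ids, cands, lats, lons = [], [], [], []
    km_per_deg = 111.19492664455873  # equatorial degree of latitude, R=6371
    k = 0
    for d in range(n_demes):
        for i in range(cfg.individuals_per_deme):
            geno[k] = rng.binomial(2, freqs[d]).astype(np.int8)
            ids.append(f"ind_{d:02d}_{i:02d}")
            cands.append(cfg.candidate_labels[0] if d < boundary else cfg.candidate_labels[1])
            lats.append(d * cfg.deme_spacing_km / km_per_deg)
            lons.append(0.0)
            k += 1
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno[mask] = -1
    sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n_snps + 1)})
    widx = window_partition(sites, cfg.snps_per_window)
    gws = GenotypeWindowSet(sites, geno, ids, widx, cfg.snps_per_window)
    meta = SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "candidate": cands,
                "latitude": lats,
                "longitude": lons,
                "population": [f"deme_{d:02d}" for d in range(n_demes) for _ in range(cfg.individuals_per_deme)],
            }
        )
    )
    return gws, meta


def write_vcf(gws: GenotypeWindowSet, path: str) -> None:
    """Write the genotype set as a minimal plain-text VCF (GT only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in gws.sites["chrom"].unique():
            n = int(gws.sites.loc[gws.sites["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gws.sample_ids)
            + "\n"
        )
        for s in range(len(gws.sites)):
            row = gws.sites.iloc[s]
            gts = "\t".join(gt_str[int(g)] for g in gws.genotypes[:, s])
            fh.write(f"{row.chrom}\t{row.pos}\tsnp{s}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_trait_cline(
    samples: SampleTable,
    n_traits: int = 4,
    slope_per_km: float = 0.0,
    noise_sd: float = 1.0,
    candidate_offset: float = 0.0,
    intercept: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Traits as linear spatial clines with optional between-candidate
    offset and Gaussian noise; position is distance (km) from the
    southernmost individual along the latitude axis."""
    from taxodelim.gendist import haversine_km

    rng = np.random.default_rng(seed)
    t = samples.table
    lat0, lon0 = t["latitude"].min(), float(t.loc[t["latitude"].idxmin(), "longitude"])
    pos = np.array(
        [haversine_km(lat0, lon0, r.latitude, r.longitude) for r in t.itertuples()]
    )
    cands = sorted(t["candidate"].unique())
    offs = {c: (0.0 if i == 0 else candidate_offset) for i, c in enumerate(cands)}
    data = {"id": t["sample_id"].tolist()}
    for v in range(n_traits):
        base = intercept + slope_per_km * pos
        base = base + np.array([offs[c] for c in t["candidate"]])
        data[f"trait_{v}"] = base + rng.normal(0, noise_sd, size=len(t))
    return pd.DataFrame(data)


def simulate_posterior(
    tau_mean: float,
    theta_mean: float,
    cv: float = 0.1,
    n_draws: int = 1000,
    seed: int = 0,
    tau_col: str = "tau_root",
    theta_col: str = "theta_A",
) -> pd.DataFrame:
    """Independent lognormal pseudo-posterior draws of tau and theta
    with the given means and coefficient of variation."""
    rng = np.random.default_rng(seed)

    def ln(mean, n):
        if cv == 0:
            return np.full(n, mean)
        s2 = math.log(1 + cv**2)
        mu = math.log(mean) - s2 / 2
        return rng.lognormal(mu, math.sqrt(s2), size=n)

    if n_draws < 100:
        import warnings

        warnings.warn(f"only {n_draws} draws; downstream HPDs will be coarse", stacklevel=2)
    return pd.DataFrame({tau_col: ln(tau_mean, n_draws), theta_col: ln(theta_mean, n_draws)})


def make_env_grid(
    n_cells: int = 400, n_vars: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Synthetic bioclimatic grid: correlated Gaussian fields over a
    square cell lattice, columns lon, lat, bio1..bio{n_vars}."""
    rng = np.random.default_rng(seed)
    side = int(math.sqrt(n_cells))
    lon, lat = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    lon, lat = lon.ravel(), lat.ravel()
    base1 = lon / side
    base2 = lat / side
    cols = {"lon": lon, "lat": lat}
    for v in range(n_vars):
        w = rng.normal(size=2)
        cols[f"bio{v + 1}"] = (
            10 * (w[0] * base1 + w[1] * base2) + rng.normal(0, 1, size=len(lon))
        )
    return pd.DataFrame(cols)


def simulate_occurrences(
    env_grid: pd.DataFrame,
    center: np.ndarray | list[float],
    spread: float,
    n: int,
    seed: int = 0,
    species: str = "sp",
) -> pd.DataFrame:
    """Occurrences drawn by environmental suitability: cells are sampled
    with probability proportional to a Gaussian kernel (sd = spread)
    around `center` in the standardized bioclimatic space."""
    rng = np.random.default_rng(seed)
    bio_cols = [c for c in env_grid.columns if c.startswith("bio")]
    X = env_grid[bio_cols].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    c = np.asarray(center, dtype=float)
    d2 = ((Z - c) ** 2).sum(axis=1)
    w = np.exp(-0.5 * d2 / spread**2)
    w = w / w.sum()
    cells = rng.choice(len(env_grid), size=n, replace=True, p=w)
    out = env_grid.iloc[cells].copy().reset_index(drop=True)
    out.insert(0, "species", species)
    return out


def simulate_pure_birth_tree(
    n_tips: int, depth: float = 1.0, seed: int = 0
) -> "object":
    """Pure-birth (Yule) ultrametric tree rescaled to the given depth,
    as a dendropy tree with tips sp01..spNN."""
    import dendropy

    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # grow a Yule tree: split a random pending lineage at exponential times
    birth = {id(tree.seed_node): 0.0}
    tips = [tree.seed_node]
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        node.edge.length = t - birth[id(node)]
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        birth[id(c1)] = birth[id(c2)] = t
        tips.extend([c1, c2])
    total = t + rng.exponential(1.0 / len(tips))
    for node in tips:
        node.edge.length = total - birth[id(node)]
    tree.seed_node.edge.length = None
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = taxa[i]
    # rescale crown depth (root edge dropped) to the requested depth
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    crown = max(lf.root_distance for lf in tree.leaf_node_iter())
    scale = depth / crown
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return tree
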
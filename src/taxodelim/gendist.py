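"""Genotype windows and pairwise genetic/geographic distances.

Genotypes are alternate-allele dosages in {0, 1, 2}; missing calls
(including half-calls) are coded -1. Sites are partitioned into windows
of a fixed number of SNPs so that per-window diversity statistics are
comparable across the genome. The pairwise statistic is the average
number of nucleotide differences per variant site between two diploid
individuals (pi), counting all four cross-pairings of their alleles at
each co-genotyped site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
EARTH_RADIUS_KM = 6371.0


@dataclass
class SampleTable:
    """Per-individual metadata: candidate label and coordinates."""

    table: pd.DataFrame  # columns: sample_id, candidate, latitude, longitude[, population]

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "candidate", "latitude", "longitude"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if (t["latitude"].abs() > 90).any() or (t["longitude"].abs() > 180).any():
            raise ValueError("coordinates outside valid WGS84 range")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def candidate_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["candidate"]))

    def coords_of(self) -> dict[str, tuple[float, float]]:
        return {
            r.sample_id: (float(r.latitude), float(r.longitude))
            for r in self.table.itertuples()
        }


def read_sample_table(path: str) -> SampleTable:
    """Read a whitespace/tab-delimited metadata table with a header."""
    t = pd.read_csv(path, sep=None, engine="python")
    return SampleTable(t)


@dataclass
class GenotypeWindowSet:
    """Biallelic genotype matrix partitioned into fixed-SNP windows."""

    sites: pd.DataFrame  # columns chrom, pos (1-based), sorted
    genotypes: np.ndarray  # (n_individuals, n_sites) int8, -1 = missing
    sample_ids: list[str]
    window_index: np.ndarray  # (n_sites,) int, -1 for dropped trailing sites
    snps_per_window: int
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_windows = int(self.window_index.max()) + 1 if len(self.window_index) else 0
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("genotype matrix shape does not match samples x sites")

    def window_slices(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.window_index == w) for w in range(self.n_windows)]


def window_partition(sites: pd.DataFrame, snps_per_window: int) -> np.ndarray:
    """Assign consecutive blocks of W sorted sites to window ids 0..k.

    The trailing block of fewer than W sites is dropped (id -1) so every
    retained window holds exactly W SNPs.
    """
    if snps_per_window < 1:
        raise ValueError("snps_per_window must be >= 1")
    n = len(sites)
    if n < snps_per_window:
        raise ValueError(
            f"insufficient SNPs: {n} sites < one window of {snps_per_window}"
        )
    order = sites[["chrom", "pos"]]
    if not order.equals(order.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)):
        raise ValueError("sites must be sorted by (chrom, pos)")
    idx = np.arange(n) // snps_per_window
    idx[idx > (n // snps_per_window - 1)] = -1
    return idx.astype(np.int64)


def read_vcf(path: str, snps_per_window: int = 1000) -> GenotypeWindowSet:
    """Load biallelic SNPs from a VCF into a windowed genotype set.

    Multiallelic and non-SNP records are skipped; half-calls are treated
    as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gt = var.gt_types.copy()  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt[gt == 3] = MISSING
        # half-calls: cyvcf2 marks ./x as unknown already under gts012
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(gt.astype(np.int8))
    sites = pd.DataFrame({"chrom": chroms, "pos": poss})
    geno = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    )
    widx = window_partition(sites, snps_per_window)
    return GenotypeWindowSet(sites, geno, samples, widx, snps_per_window)


def pairwise_pi(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Average fraction of differing allele pairings between two diploids.

    At each site the four cross-comparisons of the two individuals'
    alleles yield d = g_a(2-g_b) + (2-g_a)g_b differences; pi is the mean
    of d/4 over sites genotyped in both individuals. Returns NaN when no
    co-genotyped site exists.
    """
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        return math.nan
    a, b = a[ok], b[ok]
    d = a * (2 - b) + (2 - a) * b
    return float(np.mean(d / 4.0))


def _pi_matrix(geno: np.ndarray) -> np.ndarray:
    """All-pairs pi over a block of sites, vectorized.

    For co-genotyped sites, sum of d/4 = 0.5*(sum g_a + sum g_b - g_a.g_b)
    restricted to the joint mask; computed with masked matmuls.
    """
    g = geno.astype(np.float64)
    m = (geno != MISSING).astype(np.float64)
    g = g * m  # zero out missing
    n_shared = m @ m.T
    cross = g @ g.T
    sum_a = g @ m.T  # sum of a's dosage over sites where b present
    num = 0.5 * (sum_a + sum_a.T - cross)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_shared > 0, num / np.maximum(n_shared, 1), np.nan)
    return pi


def pi_by_window(gws: GenotypeWindowSet) -> np.ndarray:
    """Per-window pi for every individual pair.

    Returns an array of shape (n_ind, n_ind, n_windows); the diagonal
    holds within-individual heterozygosity-derived values and is not
    used downstream.
    """
    n = len(gws.sample_ids)
    out = np.full((n, n, gws.n_windows), np.nan)
    for w, cols in enumerate(gws.window_slices()):
        out[:, :, w] = _pi_matrix(gws.genotypes[:, cols])
    return out


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class DistanceRecords:
    """Pairwise geographic and per-window genetic distances."""

    sample_ids: list[str]
    geo_km: np.ndarray  # (n, n) symmetric
    pi: np.ndarray  # (n, n, n_windows)

    def pair_table(self) -> pd.DataFrame:
        ids = self.sample_ids
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                row = {"id_a": ids[i], "id_b": ids[j], "geo_km": self.geo_km[i, j]}
                for w in range(self.pi.shape[2]):
                    row[f"window_{w}"] = self.pi[i, j, w]
                rows.append(row)
        return pd.DataFrame(rows)


def distance_records(gws: GenotypeWindowSet, samples: SampleTable) -> DistanceRecords:
    """Combine great-circle and per-window genetic distances for all pairs."""
    coords = samples.coords_of()
    missing = [s for s in gws.sample_ids if s not in coords]
    if missing:
        raise ValueError(f"genotyped individuals absent from sample table: {missing}")
    n = len(gws.sample_ids)
    geo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            la1, lo1 = coords[gws.sample_ids[i]]
            la2, lo2 = coords[gws.sample_ids[j]]
            geo[i, j] = geo[j, i] = haversine_km(la1, lo1, la2, lo2)
    return DistanceRecords(gws.sample_ids, geo, pi_by_window(gws))
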
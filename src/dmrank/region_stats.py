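"""Region-level statistics: spatially correlated p-value combination.

Probe p-values are mapped onto fixed genomic regions (tilings, promoters
or user BED) and combined per region with the Stouffer–Liptak method.
Neighbouring probes on a methylation array are correlated, so treating
their p-values as independent would overstate significance; the
combination therefore scales the summed z-scores by a covariance built
from the empirical autocorrelation of the z-scores as a function of
genomic distance.  A 1-step Sidak correction turns combined p-values
into family-wise q-values, and per-region min/median/max methylation
change (difference of group median betas) supports effect-size
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

from .io import MethylationDataset, Region, RegionSet
from .probe_stats import all_pairs_probe_tests

__all__ = [
    "AcfEstimate",
    "RegionResult",
    "DEFAULT_LAG_BINS",
    "map_probes_to_regions",
    "estimate_acf",
    "stouffer_liptak",
    "sidak_correct",
    "region_change_summary",
    "call_dmrs",
    "results_to_frame",
]

#: default genomic-distance bin edges (bp); bin i covers (edge[i], edge[i+1]]
DEFAULT_LAG_BINS = (0, 1, 51, 101, 201, 501, 1001)

#: minimum number of probe pairs for a distance bin to contribute
MIN_PAIRS_PER_BIN = 30

#: p-value clamp applied before the inverse-normal transform
P_CLAMP = 1e-16


@dataclass
class AcfEstimate:
    """Correlation of probe z-scores by genomic-distance bin.

    ``lag_bins`` holds the bin edges; bin ``i`` covers distances in
    ``(lag_bins[i], lag_bins[i+1]]``.  Distances beyond the last edge
    have correlation 0.  Negative estimates are truncated at 0 so that
    the combination is never anti-conservative relative to independence.
    """

    lag_bins: tuple[int, ...]
    corr: np.ndarray  # one value per bin, in [0, 1]
    n_pairs: np.ndarray  # pairs observed per bin

    def corr_at(self, distance) -> np.ndarray:
        """Correlation for one or more genomic distances (bp)."""
        d = np.asarray(distance, dtype=float)
        edges = np.asarray(self.lag_bins, dtype=float)
        # right-closed bins: distance d falls in bin i if edges[i] < d <= edges[i+1]
        idx = np.searchsorted(edges, d, side="left") - 1
        out = np.zeros(d.shape, dtype=float)
        inside = (idx >= 0) & (idx < len(self.corr))
        out[inside] = self.corr[idx[inside]]
        # co-located probes (distance 0) are treated like the closest bin
        out[d == 0] = self.corr[0] if len(self.corr) else 0.0
        return out


@dataclass
class RegionResult:
    """One tested region for one group pair.

    Directions: ``a`` means methylation higher in the lexicographically
    first group of the pair, ``b`` higher in the second.  ``change_*``
    summarize the per-probe difference of group median betas, second
    group minus first, so positive change matches direction ``b``.
    """

    region: Region
    group_pair: tuple[str, str]
    probe_ids: list[str]
    n_probes: int
    p_a: float
    p_b: float
    q_a: float
    q_b: float
    direction: str  # group label with the smaller q
    q: float  # min(q_a, q_b)
    change_min: float
    change_median: float
    change_max: float


def map_probes_to_regions(
    ds: MethylationDataset, regions: RegionSet
) -> tuple[dict[str, np.ndarray], int]:
    """Assign probes to regions by the half-open convention.

    A probe at position p belongs to region [s, e) iff s <= p < e; probes
    may fall in several overlapping regions.  Returns a mapping region
    name -> probe indices (in dataset order) for regions with at least
    one probe, plus the count of regions skipped for having none.
    """
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    hits: dict[int, list[int]] = {}
    for probe_idx in range(ds.n_probes):
        tree = trees.get(ds.chrom[probe_idx])
        if tree is None:
            continue
        for iv in tree.at(int(ds.pos[probe_idx])):
            hits.setdefault(iv.data, []).append(probe_idx)
    mapping = {
        regions[i].name: np.asarray(sorted(idxs)) for i, idxs in hits.items()
    }
    n_skipped = len(regions) - len(mapping)
    return mapping, n_skipped


def estimate_acf(
    z: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    lag_bins: Sequence[int] = DEFAULT_LAG_BINS,
) -> AcfEstimate:
    """Estimate the distance-binned autocorrelation of probe z-scores.

    For each distance bin, the Pearson correlation is computed over all
    intra-chromosomal probe pairs whose distance falls in the bin.  Bins
    with fewer than ``MIN_PAIRS_PER_BIN`` pairs, or zero variance, get
    correlation 0, and negative estimates are truncated at 0.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 probes to estimate autocorrelation")
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    edges = np.asarray(lag_bins, dtype=np.int64)
    max_lag = int(edges[-1])
    n_bins = len(edges) - 1
    pairs_x: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_y: list[list[float]] = [[] for _ in range(n_bins)]
    for c in np.unique(chrom.astype(str)):
        sel = np.where(chrom.astype(str) == c)[0]
        p = pos[sel]
        zc = z[sel]
        # probes are in genomic order; walk forward while within max lag
        for i in range(len(sel)):
            j = i + 1
            while j < len(sel) and p[j] - p[i] <= max_lag:
                d = p[j] - p[i]
                b = int(np.searchsorted(edges, d, side="left")) - 1
                if 0 <= b < n_bins:
                    pairs_x[b].append(zc[i])
                    pairs_y[b].append(zc[j])
                j += 1
    corr = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        n_pairs[b] = len(pairs_x[b])
        if n_pairs[b] < MIN_PAIRS_PER_BIN:
            continue
        x = np.asarray(pairs_x[b])
        y = np.asarray(pairs_y[b])
        if x.std() == 0 or y.std() == 0:
            continue
        corr[b] = max(0.0, float(np.corrcoef(x, y)[0, 1]))
    return AcfEstimate(lag_bins=tuple(int(e) for e in edges), corr=corr,
                       n_pairs=n_pairs)


def stouffer_liptak(p_list, sigma=None) -> float:
    """Combine p-values with the Stouffer–Liptak method.

    z_i = Phi^-1(1 - p_i); C = sum(z) / sqrt(sum_ij sigma_ij);
    combined p = 1 - Phi(C).  ``sigma`` is the pairwise correlation
    matrix of the region's probes (unit diagonal); ``None`` means
    independence.  If the covariance sum is not positive the method
    falls back to the independence denominator sqrt(k).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    z = norm.isf(p)  # Phi^-1(1 - p)
    k = p.size
    if sigma is None:
        denom_sq = float(k)
    else:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (k, k):
            raise ValueError(f"sigma shape {sigma.shape} does not match k={k}")
        denom_sq = float(sigma.sum())
        if denom_sq <= 0:
            denom_sq = float(k)
    c = z.sum() / np.sqrt(denom_sq)
    return float(np.clip(norm.sf(c), P_CLAMP, 1.0 - P_CLAMP))


def sidak_correct(p: float, region_span_bp: float, total_tested_span_bp: float) -> float:
    """1-step Sidak correction sized by genomic span.

    The effective number of tests is m = max(1, floor(total span tested /
    this region's span)) — the number of regions of this size that would
    fit in the tested genome, following the convention of length-based
    correction for region tests.  q = 1 - (1 - p)^m evaluated via
    log1p/expm1 for stability at small p.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if region_span_bp <= 0 or total_tested_span_bp <= 0:
        raise ValueError("spans must be positive")
    m = max(1, int(total_tested_span_bp // region_span_bp))
    q = -np.expm1(m * np.log1p(-p)) if p < 1.0 else 1.0
    return float(min(max(q, p), 1.0))


def sidak_correct_count(p: float, n_tests: int) -> float:
    """Sidak correction with an explicit test count (alternative to spans)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    m = max(1, int(n_tests))
    q = -np.expm1(m * np.log1p(-p)) if p < 1.0 else 1.0
    return float(min(max(q, p), 1.0))


def region_change_summary(
    ds: MethylationDataset,
    pair: tuple[str, str],
    probe_idx: Iterable[int],
) -> tuple[float, float, float]:
    """Min/median/max methylation change over a region's probes.

    Per probe, change d = median beta of the second group minus median
    beta of the first group (pair order fixed); the triple summarizes d
    over the region's probes.  Values lie in [-1, 1].
    """
    idx = np.asarray(list(probe_idx))
    cols_a = ds.group_columns(pair[0])
    cols_b = ds.group_columns(pair[1])
    d = np.median(ds.beta[np.ix_(idx, cols_b)], axis=1) - np.median(
        ds.beta[np.ix_(idx, cols_a)], axis=1
    )
    return float(d.min()), float(np.median(d)), float(d.max())


def _sigma_from_acf(acf: AcfEstimate, pos: np.ndarray) -> np.ndarray:
    """Pairwise correlation matrix for probes at the given positions."""
    d = np.abs(pos[:, None] - pos[None, :])
    sigma = acf.corr_at(d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def call_dmrs(
    ds: MethylationDataset,
    regions: RegionSet,
    q_cutoff: float = 1.0,
    min_abs_median_change: float = 0.0,
    lag_bins: Sequence[int] = DEFAULT_LAG_BINS,
    probe_table: pd.DataFrame | None = None,
    sidak_by_count: bool = False,
) -> dict[tuple[str, str], list[RegionResult]]:
    """Full region-calling pass: combine, correct, summarize, filter.

    For every unordered group pair and each direction, the genome-wide
    autocorrelation of that direction's z-scores is estimated, each
    region's probe p-values are combined with the resulting covariance,
    and q-values are obtained by Sidak correction with the summed span
    of all tested regions (or the tested-region count when
    ``sidak_by_count``).  Regions pass when the smaller directional q is
    <= ``q_cutoff`` and |median change| >= ``min_abs_median_change``.
    Results per pair are sorted by (q, chrom, start).
    """
    ds.require_testable()
    if probe_table is None:
        probe_table = all_pairs_probe_tests(ds)
    mapping, n_skipped = map_probes_to_regions(ds, regions)
    if not mapping:
        raise ValueError("no region contains any probe")
    tested = [r for r in regions if r.name in mapping]
    total_span = sum(r.span for r in tested)

    out: dict[tuple[str, str], list[RegionResult]] = {}
    for g_a, g_b in combinations(ds.group_names(), 2):
        sub = probe_table[
            (probe_table["group_a"] == g_a) & (probe_table["group_b"] == g_b)
        ].set_index("probe_id").reindex(ds.probe_ids)
        if sub["p_a_greater"].isna().any():
            raise ValueError("probe table does not cover all dataset probes")
        p_dir = {
            "a": sub["p_a_greater"].to_numpy(),
            "b": sub["p_b_greater"].to_numpy(),
        }
        acf_dir = {
            d: estimate_acf(
                norm.isf(np.clip(p, P_CLAMP, 1 - P_CLAMP)), ds.chrom, ds.pos, lag_bins
            )
            for d, p in p_dir.items()
        }
        results = []
        for region in tested:
            idx = mapping[region.name]
            pos = ds.pos[idx]
            combined = {}
            for d in ("a", "b"):
                sigma = _sigma_from_acf(acf_dir[d], pos)
                combined[d] = stouffer_liptak(p_dir[d][idx], sigma)
            if sidak_by_count:
                q_a = sidak_correct_count(combined["a"], len(tested))
                q_b = sidak_correct_count(combined["b"], len(tested))
            else:
                q_a = sidak_correct(combined["a"], region.span, total_span)
                q_b = sidak_correct(combined["b"], region.span, total_span)
            c_min, c_med, c_max = region_change_summary(ds, (g_a, g_b), idx)
            direction = g_a if q_a <= q_b else g_b
            results.append(
                RegionResult(
                    region=region,
                    group_pair=(g_a, g_b),
                    probe_ids=list(ds.probe_ids[idx]),
                    n_probes=len(idx),
                    p_a=combined["a"],
                    p_b=combined["b"],
                    q_a=q_a,
                    q_b=q_b,
                    direction=direction,
                    q=min(q_a, q_b),
                    change_min=c_min,
                    change_median=c_med,
                    change_max=c_max,
                )
            )
        kept = [
            r
            for r in results
            if r.q <= q_cutoff and abs(r.change_median) >= min_abs_median_change
        ]
        kept.sort(key=lambda r: (r.q, r.region.chrom, r.region.start))
        out[(g_a, g_b)] = kept
    return out


def results_to_frame(results: list[RegionResult]) -> pd.DataFrame:
    """Flatten region results into the per-pair output table."""
    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in results],
            "start": [r.region.start for r in results],
            "end": [r.region.end for r in results],
            "name": [r.region.name for r in results],
            "gene_name": [r.region.gene_name or "" for r in results],
            "n_probes": [r.n_probes for r in results],
            "p_a": [r.p_a for r in results],
            "p_b": [r.p_b for r in results],
            "q_a": [r.q_a for r in results],
            "q_b": [r.q_b for r in results],
            "direction": [r.direction for r in results],
            "change_min": [r.change_min for r in results],
            "change_median": [r.change_median for r in results],
            "change_max": [r.change_max for r in results],
        }
    )
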
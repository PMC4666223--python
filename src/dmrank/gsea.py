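"""Pre-ranked gene set enrichment on region results.

Regions that carry a ``gene_name`` are collapsed to one score per gene
(the region with the smallest q wins) and ranked by a signed metric:
sign(median change) x -log10(q), so genes with higher methylation in the
second group of a pair sit at the top of the list and genes higher in
the first group at the bottom.  A weighted running sum walks the ranked
list per gene set; the enrichment score (ES) is its signed maximum
deviation from zero.  Significance comes from a gene-label permutation
null (random same-size subsets of the ranked universe), and a leading
edge analysis identifies the core genes driving each enrichment and
their overlap across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .region_stats import RegionResult

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "permutation_p",
    "leading_edge",
    "leading_edge_overlap",
    "run_gsea",
]

_Q_FLOOR = 1e-300  # keeps -log10(q) finite


@dataclass
class RankedGeneList:
    """Unique genes ordered by descending signed score."""

    genes: list[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.genes) != len(self.score):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int  # members present in the ranked list
    es: float
    peak_index: int  # 1-based rank attaining the ES
    p_perm: float | None
    leading_edge: list[str] = field(default_factory=list)


def rank_genes(
    region_results: list[RegionResult],
    metric: str = "signed_logq",
) -> RankedGeneList:
    """Collapse gene-linked region results into a ranked gene list.

    Per gene the best region is kept: smallest q, ties broken by larger
    |median change| then by region name.  The default score is
    sign(change_median) x -log10(q); ``metric="signed_change"`` ranks by
    the signed median change instead.  Final ordering is by descending
    score with deterministic alphabetical tie-breaking.
    """
    if metric not in ("signed_logq", "signed_change"):
        raise ValueError(f"unknown metric {metric!r}")
    best: dict[str, RegionResult] = {}
    for r in region_results:
        if not r.region.gene_name:
            continue
        g = r.region.gene_name
        cur = best.get(g)
        if cur is None or (r.q, -abs(r.change_median), r.region.name) < (
            cur.q,
            -abs(cur.change_median),
            cur.region.name,
        ):
            best[g] = r
    if not best:
        raise ValueError("no region result carries a gene_name")
    genes, scores = [], []
    for g, r in best.items():
        sign = float(np.sign(r.change_median))
        if metric == "signed_logq":
            s = sign * -np.log10(max(r.q, _Q_FLOOR))
        else:
            s = r.change_median
        genes.append(g)
        scores.append(s)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedGeneList(
        genes=[genes[i] for i in order],
        score=np.asarray([scores[i] for i in order]),
    )


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight_p: float = 1.0
) -> tuple[float, int] | None:
    """Weighted Kolmogorov–Smirnov running-sum enrichment score.

    Walking the ranked list, a hit at rank i adds
    |score_i|^weight_p / sum_hits |score|^weight_p and a miss subtracts
    1 / (N - N_hit); the ES is the running sum's maximum absolute
    deviation from zero, signed, with the 1-based rank attaining it.
    ``weight_p = 0`` recovers the classic unweighted KS statistic.
    Returns ``None`` when no set member is in the ranked list (the set
    is untestable, not enriched-at-zero).
    """
    members = set(gene_set)
    n = len(ranked)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        return None
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.score) ** weight_p
    hit_norm = w[hit].sum()
    steps = np.where(hit, (w / hit_norm) if hit_norm > 0 else (1.0 / n_hit),
                     -1.0 / (n - n_hit))
    if hit_norm == 0:
        # all hit weights zero (q = 1 everywhere): fall back to equal steps
        steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak + 1


def permutation_p(
    ranked: RankedGeneList,
    gene_set,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Gene-label permutation p-value for |ES|.

    The null draws ``n_perm`` random subsets of the ranked universe of
    the same size as the observed intersection and recomputes the ES;
    p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1), so the smallest
    attainable p is 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful p-value")
    obs = enrichment_score(ranked, gene_set, weight_p)
    if obs is None:
        raise ValueError("gene set has no member in the ranked list")
    es_obs, _ = obs
    members = set(gene_set) & set(ranked.genes)
    k = len(members)
    if k > len(ranked):
        raise ValueError("gene set larger than ranked list")
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranked.genes, dtype=object)
    exceed = 0
    for _ in range(n_perm):
        null_set = rng.choice(genes, size=k, replace=False)
        es_null, _ = enrichment_score(ranked, null_set, weight_p)
        if abs(es_null) >= abs(es_obs):
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def leading_edge(ranked: RankedGeneList, gene_set, es: float, peak_index: int) -> list[str]:
    """Core genes driving the ES.

    Positive ES: set members at ranks <= peak_index (before or at the
    peak).  Negative ES: set members at ranks > peak_index.
    """
    members = set(gene_set)
    if es >= 0:
        sel = ranked.genes[:peak_index]
    else:
        sel = ranked.genes[peak_index:]
    return [g for g in sel if g in members]


def leading_edge_overlap(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Jaccard index between the leading edges of the given sets."""
    names = [r.set_name for r in results]
    edges = [set(r.leading_edge) for r in results]
    n = len(results)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = edges[i] | edges[j]
            mat[i, j] = len(edges[i] & edges[j]) / len(union) if union else 1.0
    return pd.DataFrame(mat, index=names, columns=names)


def run_gsea(
    region_results: list[RegionResult],
    gene_sets,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signed_logq",
    significance: float = 0.05,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Enrichment over a gene-set collection plus leading-edge overlap.

    Returns per-set results (untestable sets omitted) sorted by p_perm
    then name, and the Jaccard overlap matrix of the leading edges of
    sets with p_perm <= ``significance``.
    """
    ranked = rank_genes(region_results, metric=metric)
    results: list[EnrichmentResult] = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        scored = enrichment_score(ranked, members, weight_p)
        if scored is None:
            continue
        es, peak = scored
        # one independent, reproducible stream per set
        p = permutation_p(ranked, members, weight_p, n_perm, seed=seed + i)
        results.append(
            EnrichmentResult(
                set_name=name,
                set_size=len(set(members) & set(ranked.genes)),
                es=es,
                peak_index=peak,
                p_perm=p,
                leading_edge=leading_edge(ranked, members, es, peak),
            )
        )
    results.sort(key=lambda r: (r.p_perm, r.set_name))
    significant = [r for r in results if r.p_perm <= significance]
    overlap = leading_edge_overlap(significant)
    return results, overlap
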
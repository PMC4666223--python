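"""Per-probe directional two-sample rank tests, all group pairs.

For every unordered pair of sample groups, each probe is tested with two
one-sided Mann–Whitney U tests: one asking whether methylation is higher
in the first group, one whether it is higher in the second.  Keeping both
one-sided p-values preserves the direction of the change through the
downstream region combination, where each direction is combined
separately.

The exact null distribution of U is used whenever the pooled sample is
small (n_a + n_b <= ``EXACT_LIMIT``) and tie-free; otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity correction
is used.  Rank tests are invariant to monotone transforms, so testing on
beta values gives the same p-values as testing on M-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io import MethylationDataset

__all__ = ["ProbeTestResult", "mwu_one_sided", "all_pairs_probe_tests", "EXACT_LIMIT"]

#: pooled-sample-size bound below which the exact U distribution is used
EXACT_LIMIT = 16

#: smallest reportable p-value; keeps downstream z-transforms finite
P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class ProbeTestResult:
    probe_id: str
    group_pair: tuple[str, str]
    p_a_greater: float  # one-sided p: methylation higher in the first group
    p_b_greater: float  # one-sided p: methylation higher in the second group
    u_stat: float  # U of the first group, in [0, n_a * n_b]
    n_a: int
    n_b: int


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mwu_one_sided(a, b, direction: str) -> tuple[float, float]:
    """One-sided Mann–Whitney U test for stochastic dominance.

    Parameters
    ----------
    a, b
        Sample values of the two groups (1-D, non-empty).
    direction
        ``"a_greater"`` tests for larger values in ``a``, ``"b_greater"``
        for larger values in ``b``.

    Returns
    -------
    (p, U) where U is the statistic of group ``a``.  If all pooled values
    are identical the test is degenerate and p = 1.0 is returned for
    either direction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in ("a_greater", "b_greater"):
        raise ValueError(f"unknown direction {direction!r}")
    pooled = np.concatenate([a, b])
    u_a = float(mannwhitneyu(a, b, alternative="greater", method="asymptotic").statistic)
    if np.all(pooled == pooled[0]):
        return 1.0, u_a
    # direction is resolved by argument order so that
    # (a, b, a_greater) and (b, a, b_greater) are exactly symmetric
    x, y = (a, b) if direction == "a_greater" else (b, a)
    exact = a.size + b.size <= EXACT_LIMIT and not _has_ties(pooled)
    res = mannwhitneyu(
        x, y, alternative="greater", method="exact" if exact else "asymptotic"
    )
    p = min(max(float(res.pvalue), P_FLOOR), 1.0)
    return p, u_a


def _pair_tests_vectorized(
    beta_a: np.ndarray, beta_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both directional p-values for all probes of one group pair.

    ``beta_a``/``beta_b`` are (n_probes, n_samples) slices.  Probes where
    the exact method applies (small pooled n, no ties in that probe's row)
    are tested exactly; the rest use the asymptotic method.  Degenerate
    rows (all pooled values identical) get p = 1 in both directions.
    """
    n_a, n_b = beta_a.shape[1], beta_b.shape[1]
    pooled = np.concatenate([beta_a, beta_b], axis=1)
    tie_free = np.array(
        [len(np.unique(row)) == row.size for row in pooled], dtype=bool
    )
    degenerate = (pooled == pooled[:, :1]).all(axis=1)

    p_a = np.empty(len(pooled))
    p_b = np.empty(len(pooled))
    u_a = mannwhitneyu(
        beta_a, beta_b, alternative="greater", method="asymptotic", axis=1
    ).statistic.astype(float)

    use_exact = tie_free & (n_a + n_b <= EXACT_LIMIT)
    for mask, method in ((use_exact, "exact"), (~use_exact, "asymptotic")):
        if not mask.any():
            continue
        p_a[mask] = mannwhitneyu(
            beta_a[mask], beta_b[mask], alternative="greater", method=method, axis=1
        ).pvalue
        p_b[mask] = mannwhitneyu(
            beta_b[mask], beta_a[mask], alternative="greater", method=method, axis=1
        ).pvalue
    p_a[degenerate] = 1.0
    p_b[degenerate] = 1.0
    np.clip(p_a, P_FLOOR, 1.0, out=p_a)
    np.clip(p_b, P_FLOOR, 1.0, out=p_b)
    return p_a, p_b, u_a


def all_pairs_probe_tests(ds: MethylationDataset) -> pd.DataFrame:
    """Directional rank tests for every probe and every unordered group pair.

    Returns a long-format table with one row per (probe, pair):
    ``probe_id, chrom, pos, group_a, group_b, p_a_greater, p_b_greater,
    u_stat, n_a, n_b``.  Pairs are ordered lexicographically within and
    across, so ``group_a < group_b`` always holds.
    """
    ds.require_testable()
    frames = []
    for g_a, g_b in combinations(ds.group_names(), 2):
        cols_a = ds.group_columns(g_a)
        cols_b = ds.group_columns(g_b)
        p_a, p_b, u_a = _pair_tests_vectorized(ds.beta[:, cols_a], ds.beta[:, cols_b])
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": ds.probe_ids,
                    "chrom": ds.chrom,
                    "pos": ds.pos,
                    "group_a": g_a,
                    "group_b": g_b,
                    "p_a_greater": p_a,
                    "p_b_greater": p_b,
                    "u_stat": u_a,
                    "n_a": len(cols_a),
                    "n_b": len(cols_b),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_probe_table(table: pd.DataFrame, path) -> None:
    """Dump the per-probe p-value table as TSV (wide per-pair columns)."""
    wide = table.pivot_table(
        index=["probe_id", "chrom", "pos"],
        columns=["group_a", "group_b"],
        values=["p_a_greater", "p_b_greater"],
        sort=False,
    )
    wide.columns = [f"{a}_vs_{b}:{v}" for v, a, b in wide.columns]
    wide.reset_index().to_csv(path, sep="\t", index=False, float_format="%.17g")
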
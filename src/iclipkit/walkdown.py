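"""Walk-down threshold inference on a ranked target list.

The ranked gene list is split serially into fixed-size groups (the
remainder is appended to the last group).  Each group is scored for
functional-annotation clustering with a one-sided hypergeometric
over-representation test per term (BH-corrected across terms); the
number of significant terms ("clusters") and the minimum raw p are
accumulated down the ranking, and the same machinery applied to
permuted rankings supplies the control curves.  The functional binding
threshold is the rank at which the cumulative curve's slope drops, as
located by an exhaustive two-segment piecewise-linear fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-term hypergeometric over-representation for one gene set."""

    table: pd.DataFrame  # term, k, n, K, N, p, p_adj
    n_clusters: int      # terms with adjusted p < alpha
    min_p: float         # smallest raw p over terms


@dataclass
class WalkdownCurve:
    group_size: int
    boundaries: list[tuple[int, int]]         # rank intervals per group (0-based)
    per_group: pd.DataFrame                   # n_clusters, neglog_min_p per group
    cum_clusters: np.ndarray
    cum_neglog_minp: np.ndarray


def enrich(
    query: set | list,
    universe: set | list,
    terms: dict[str, list[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of each term in ``query``.

    ``p = P(X >= k)`` for X ~ Hypergeom(N=|universe|, K=|term|,
    n=|query|); BH correction across terms.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, members in terms.items():
        K = len(universe & set(members))
        k = len(query & set(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((term, k, n, K, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    n_clusters = int((table["p_adj"] < alpha).sum())
    min_p = float(table["p"].min()) if len(table) else 1.0
    return EnrichmentResult(table=table, n_clusters=n_clusters, min_p=min_p)


def _group_bounds(n: int, group_size: int) -> list[tuple[int, int]]:
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > n:
        raise ValueError("group_size exceeds ranking length")
    n_groups = n // group_size
    bounds = [(i * group_size, (i + 1) * group_size) for i in range(n_groups)]
    # remainder genes are appended to the final group
    bounds[-1] = (bounds[-1][0], n)
    return bounds


def walk_down(
    ranked_genes: list[str],
    group_size: int,
    terms: dict[str, list[str]],
    alpha: float = 0.05,
) -> WalkdownCurve:
    """Score serial rank groups and build cumulative clustering curves."""
    genes = list(ranked_genes)
    universe = set(genes)
    bounds = _group_bounds(len(genes), group_size)
    rows = []
    for lo, hi in bounds:
        res = enrich(genes[lo:hi], universe, terms, alpha=alpha)
        neglog = -np.log10(max(res.min_p, np.finfo(float).tiny))
        rows.append((res.n_clusters, neglog))
    per_group = pd.DataFrame(rows, columns=["n_clusters", "neglog_min_p"])
    return WalkdownCurve(
        group_size=group_size,
        boundaries=bounds,
        per_group=per_group,
        cum_clusters=per_group["n_clusters"].cumsum().to_numpy(dtype=float),
        cum_neglog_minp=per_group["neglog_min_p"].cumsum().to_numpy(),
    )


def permute_walkdown(
    ranked_genes: list[str],
    n_perm: int,
    seed: int,
    group_size: int,
    terms: dict[str, list[str]],
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Pointwise mean (and sd) cumulative curves over shuffled rankings."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng([9, seed])
    genes = np.asarray(ranked_genes)
    cl, lp = [], []
    for _ in range(n_perm):
        perm = list(genes[rng.permutation(len(genes))])
        curve = walk_down(perm, group_size, terms, alpha=alpha)
        cl.append(curve.cum_clusters)
        lp.append(curve.cum_neglog_minp)
    cl, lp = np.stack(cl), np.stack(lp)
    return {
        "mean_cum_clusters": cl.mean(axis=0),
        "sd_cum_clusters": cl.std(axis=0, ddof=0),
        "mean_cum_neglog_minp": lp.mean(axis=0),
        "sd_cum_neglog_minp": lp.std(axis=0, ddof=0),
    }


def detect_inflection(
    cum_values: np.ndarray | WalkdownCurve,
    group_size: int | None = None,
    min_slope_drop: float = 1e-8,
) -> int | None:
    """Rank at which a cumulative walk-down curve flattens.

    Fits two least-squares line segments over every candidate breakpoint
    (shared knot point) and keeps the breakpoint minimizing total squared
    error, provided the second slope is smaller than the first.  Returns
    ``breakpoint group x group_size`` or None when no slope decrease
    exists (e.g. a strictly linear or constant curve).
    """
    if isinstance(cum_values, WalkdownCurve):
        if group_size is None:
            group_size = cum_values.group_size
        y = np.asarray(cum_values.cum_clusters, dtype=float)
    else:
        y = np.asarray(cum_values, dtype=float)
    if group_size is None:
        raise ValueError("group_size required with a bare array")
    G = len(y)
    if G < 4:
        raise ValueError("need at least 4 groups")
    x = np.arange(1, G + 1, dtype=float)

    best: tuple[float, int] | None = None
    for b in range(2, G - 1):  # breakpoint at group b (1-based), both sides >= 2 pts
        x1, y1 = x[:b], y[:b]
        x2, y2 = x[b - 1 :], y[b - 1 :]
        s1, i1 = np.polyfit(x1, y1, 1)
        s2, i2 = np.polyfit(x2, y2, 1)
        sse = float(np.sum((y1 - (s1 * x1 + i1)) ** 2)) + float(
            np.sum((y2 - (s2 * x2 + i2)) ** 2)
        )
        drop = s1 - s2
        if drop > min_slope_drop * (abs(s1) + 1.0):
            if best is None or sse < best[0]:
                best = (sse, b)
    if best is None:
        return None
    return best[1] * group_size


def apply_list_filter(ranking: pd.DataFrame, keep: list[str]) -> pd.DataFrame:
    """Restrict a ranking to a keep-list, preserving order, ranks 1..M."""
    keep_set = set(keep)
    out = ranking[ranking["gene_id"].isin(keep_set)].reset_index(drop=True)
    if out.empty:
        raise ValueError("keep-list does not intersect the ranking")
    out = out.copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def expression_corroboration(
    ranked_genes: list[str],
    indicator: pd.Series,
    group_size: int,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Cumulative mean differential-expression indicator down the ranking.

    The walk-down group statistic is the group mean of ``indicator``
    (e.g. |fold change| or an F ratio).  Genes with missing indicator
    values are dropped (logged).  Returns the experimental cumulative
    curve plus the permuted-mean and -sd control curves.
    """
    genes = [g for g in ranked_genes if g in indicator.index and np.isfinite(indicator[g])]
    if len(genes) < len(ranked_genes):
        logger.info("dropped %d genes without indicator values",
                    len(ranked_genes) - len(genes))
    if not genes:
        raise ValueError("no genes with indicator values")
    vals = indicator.loc[genes].to_numpy(dtype=float)
    bounds = _group_bounds(len(genes), group_size)

    def cum_curve(v: np.ndarray) -> np.ndarray:
        return np.cumsum([v[lo:hi].mean() for lo, hi in bounds])

    rng = np.random.default_rng([10, seed])
    perms = np.stack(
        [cum_curve(vals[rng.permutation(len(vals))]) for _ in range(n_perm)]
    )
    return {
        "cum_indicator": cum_curve(vals),
        "perm_mean": perms.mean(axis=0),
        "perm_sd": perms.std(axis=0, ddof=0),
        "group_size": np.array([group_size]),
    }
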
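"""Expression normalization and genotype-by-treatment interaction models.

Counts are normalized by each sample's upper quartile (75th percentile
of nonzero values), transformed per gene to normal scores of their
ranks, and fed to a per-gene two-way fixed-effects ANOVA with genotype,
treatment ("experiment") and their interaction.  Interaction p-values
come from sample-label permutations pooled across genes.  Follow-up
analyses relate interaction strength to the binding ranking (rank
regression and Spearman correlation), contrast term enrichment between
the high- and low-interaction halves of the top targets (delta log p),
tabulate direction of effect per genotype with Fisher's exact test, and
compute qPCR 2^ddCt fold changes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .walkdown import enrich

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and transformation

def quartile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by its upper quartile of nonzero values.

    After division, samples are rescaled by the mean upper quartile so
    the output stays on the input's magnitude.  Raises on an all-zero
    sample.
    """
    uqs = {}
    for col in mat.columns:
        nonzero = mat[col][mat[col] > 0]
        if nonzero.empty:
            raise ValueError(f"sample {col!r} has no nonzero values")
        uqs[col] = float(np.percentile(nonzero, 75))  # linear interpolation
    uq = pd.Series(uqs)
    return mat.div(uq, axis=1) * uq.mean()


def quantile_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Normal scores of ranks: Phi^-1((r - 0.5) / n), ties averaged.

    All-identical input maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty input")
    if np.all(v == v[0]):
        return np.zeros_like(v)
    r = stats.rankdata(v, method="average")
    return stats.norm.ppf((r - 0.5) / v.size)


# ---------------------------------------------------------------------------
# interaction ANOVA

def _design_codes(design: pd.DataFrame, columns: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    d = design.loc[columns]
    geno = pd.Categorical(d["genotype"]).codes
    trt = pd.Categorical(d["treatment"]).codes
    if len(np.unique(geno)) != 2 or len(np.unique(trt)) != 2:
        raise ValueError("design must have two genotypes and two treatments")
    return geno.astype(int), trt.astype(int)


def _anova_f(scores: np.ndarray, geno: np.ndarray, trt: np.ndarray) -> np.ndarray:
    """Vectorized balanced two-way ANOVA F statistics.

    ``scores`` is genes x samples.  Returns an array (genes, 3) of F for
    treatment ("experiment"), genotype, and interaction.
    """
    r = None
    cell_means = np.empty((scores.shape[0], 2, 2))
    for i in range(2):
        for j in range(2):
            mask = (geno == i) & (trt == j)
            nij = int(mask.sum())
            if nij < 2:
                raise ValueError("each design cell needs >= 2 replicates")
            if r is None:
                r = nij
            elif nij != r:
                raise ValueError("design must be balanced")
            cell_means[:, i, j] = scores[:, mask].mean(axis=1)
    grand = cell_means.mean(axis=(1, 2))
    g_means = cell_means.mean(axis=2)  # genotype margins
    t_means = cell_means.mean(axis=1)  # treatment margins

    ss_geno = 2 * r * ((g_means - grand[:, None]) ** 2).sum(axis=1)
    ss_trt = 2 * r * ((t_means - grand[:, None]) ** 2).sum(axis=1)
    inter = (
        cell_means
        - g_means[:, :, None]
        - t_means[:, None, :]
        + grand[:, None, None]
    )
    ss_int = r * (inter**2).sum(axis=(1, 2))
    fitted = np.empty_like(scores)
    for i in range(2):
        for j in range(2):
            mask = (geno == i) & (trt == j)
            fitted[:, mask] = cell_means[:, i, j][:, None]
    ss_err = ((scores - fitted) ** 2).sum(axis=1)
    df_err = scores.shape[1] - 4
    ms_err = np.maximum(ss_err / df_err, np.finfo(float).tiny)
    return np.column_stack([ss_trt / ms_err, ss_geno / ms_err, ss_int / ms_err])


def interaction_anova(
    mat: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    transform: bool = True,
) -> pd.DataFrame:
    """Per-gene genotype-by-treatment interaction ANOVA on normal scores.

    Each gene's values across the experiment's samples are rank
    normal-quantile transformed, then decomposed into treatment
    ("experiment"), genotype and interaction effects.  The interaction
    p-value is permutation-adjusted: sample labels are shuffled
    ``n_perm`` times and the permuted interaction F statistics of all
    genes pooled into one null distribution.

    Returns a frame indexed by gene with F_experiment, F_genotype,
    F_interaction, p_interaction, p_parametric and rank_F (1 = largest
    interaction F).
    """
    geno, trt = _design_codes(design, mat.columns)
    data = mat.to_numpy(dtype=float)
    if transform:
        scores = np.apply_along_axis(quantile_transform, 1, data)
    else:
        scores = data
    fs = _anova_f(scores, geno, trt)
    df_err = scores.shape[1] - 4
    p_param = stats.f.sf(fs[:, 2], 1, df_err)

    rng = np.random.default_rng([11, seed])
    null = np.empty((n_perm, scores.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(scores.shape[1])
        null[b] = _anova_f(scores, geno[perm], trt[perm])[:, 2]
    pooled = np.sort(null.ravel())
    n_null = pooled.size
    exceed = n_null - np.searchsorted(pooled, fs[:, 2], side="left")
    p_perm = (1.0 + exceed) / (1.0 + n_null)

    out = pd.DataFrame(
        {
            "F_experiment": fs[:, 0],
            "F_genotype": fs[:, 1],
            "F_interaction": fs[:, 2],
            "p_interaction": p_perm,
            "p_parametric": p_param,
        },
        index=mat.index,
    )
    out["rank_F"] = out["F_interaction"].rank(ascending=False, method="first").astype(int)
    return out


# ---------------------------------------------------------------------------
# relating interaction strength to the binding ranking

def rank_association(
    interaction: pd.DataFrame,
    ranking: pd.DataFrame,
    top_k: int = 2000,
) -> dict:
    """Association between binding rank and interaction strength.

    Reports a rank-regression F of the interaction-F rank on binary
    target status (top ``top_k`` of the binding ranking vs the rest)
    together with the Spearman correlation between the two rankings,
    and splits the top ``top_k`` targets at their median interaction F
    into equal high/low sets (odd counts give the extra gene to low).
    """
    common = ranking[ranking["gene_id"].isin(interaction.index)]
    if top_k > len(common):
        raise ValueError("top_k exceeds the common gene universe")
    genes = common["gene_id"].to_numpy()
    iclip_rank = np.arange(1, len(genes) + 1)
    f_rank = interaction.loc[genes, "F_interaction"].rank(ascending=False).to_numpy()

    rho, rho_p = stats.spearmanr(iclip_rank, f_rank)
    is_target = iclip_rank <= top_k
    a, b = f_rank[is_target], f_rank[~is_target]
    # one-way rank regression on target status (F with 1, n-2 df)
    n = len(f_rank)
    grand = f_rank.mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f_reg = float(ss_between / (ss_within / (n - 2)))
    p_reg = float(stats.f.sf(f_reg, 1, n - 2))

    top = common.head(top_k)
    fvals = interaction.loc[top["gene_id"], "F_interaction"]
    order = fvals.sort_values(ascending=False, kind="mergesort")
    n_high = top_k // 2
    high = set(order.index[:n_high])
    low = set(order.index[n_high:])
    return {
        "f_regression": f_reg,
        "p_regression": p_reg,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "high": high,
        "low": low,
    }


def delta_log_p(
    term: str,
    high: set,
    low: set,
    universe: set,
    terms: dict[str, list[str]],
) -> float:
    """log10 p(term | high) - log10 p(term | low), hypergeometric.

    Negative values mean the term is more significantly enriched in the
    high (most differentially abundant) set.
    """
    if term not in terms:
        raise KeyError(f"term {term!r} absent from the annotation set")
    if set(terms[term]).isdisjoint(universe):
        raise ValueError(f"term {term!r} has no genes in the universe")
    if high & low:
        raise ValueError("high and low sets must be disjoint")
    p_high = enrich(high, universe, {term: terms[term]}).table["p"].iloc[0]
    p_low = enrich(low, universe, {term: terms[term]}).table["p"].iloc[0]
    return float(np.log10(p_high) - np.log10(p_low))


# ---------------------------------------------------------------------------
# direction-of-effect contingency tables

@dataclass
class DirectionTable:
    """2x2 genotype x direction table of treatment-B/treatment-A ratios."""

    category: str
    counts: np.ndarray      # rows: (null, wildtype); cols: (ratio>1, ratio<1)
    fisher_p: float         # two-sided Fisher exact
    odds_ratio: float       # sample OR, inf on a zero cross-cell
    excluded: int           # genes with ratio exactly 1 or undefined


def direction_table(
    genes: list[str],
    mat: pd.DataFrame,
    design: pd.DataFrame,
    category: str = "",
    treatments: tuple[str, str] | None = None,
) -> DirectionTable:
    """Classify each gene's null and wildtype treatment ratio as >1 or <1.

    The ratio is the mean normalized expression of treatment B over
    treatment A within a genotype.  Ratios exactly 1 (or with a zero
    denominator) are excluded and logged.
    """
    missing = [g for g in genes if g not in mat.index]
    if missing:
        raise KeyError(f"{len(missing)} category genes absent from the matrix")
    d = design.loc[mat.columns]
    if treatments is None:
        treatments = tuple(pd.unique(d["treatment"]))[:2]
    trt_a, trt_b = treatments

    counts = np.zeros((2, 2), dtype=int)
    excluded = 0
    for row, genotype in enumerate(("null", "wildtype")):
        cols_a = d.index[(d["genotype"] == genotype) & (d["treatment"] == trt_a)]
        cols_b = d.index[(d["genotype"] == genotype) & (d["treatment"] == trt_b)]
        mean_a = mat.loc[genes, cols_a].mean(axis=1)
        mean_b = mat.loc[genes, cols_b].mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratio = mean_b / mean_a
        up = int((ratio > 1).sum())
        down = int((ratio < 1).sum())
        skipped = len(genes) - up - down
        if skipped:
            logger.info("%s/%s: excluded %d genes with ratio 1 or undefined",
                        category or "category", genotype, skipped)
        excluded += skipped
        counts[row] = (up, down)
    return _direction_from_counts(counts, category, excluded)


def _direction_from_counts(
    counts: np.ndarray, category: str = "", excluded: int = 0
) -> DirectionTable:
    a, b = counts[0]
    c, dd = counts[1]
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    odds = (a * dd) / (b * c) if b * c > 0 else float("inf")
    if a * dd == 0 and b * c == 0:
        odds = float("nan")
    return DirectionTable(
        category=category, counts=np.asarray(counts), fisher_p=float(p),
        odds_ratio=float(odds), excluded=excluded,
    )


def direction_table_from_counts(counts, category: str = "") -> DirectionTable:
    """Fisher test and odds ratio for an already-tabulated 2x2 table."""
    return _direction_from_counts(np.asarray(counts, dtype=int), category)


# ---------------------------------------------------------------------------
# qPCR fold change

@dataclass
class DdctRecord:
    gene: str
    dct_control: float       # mean Ct target - mean Ct reference, control genotype
    dct_experimental: float
    ddct: float              # dct_control - dct_experimental
    fold_change: float       # 2 ** ddct; > 1 means up in the experimental group


def _mean_ct(values, label: str) -> float:
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError(f"no usable Ct values for {label}")
    if not ok.all():
        warnings.warn(f"missing Ct replicate(s) for {label}; averaging the rest")
    return float(v[ok].mean())


def ddct_fold_change(
    ct_target_control,
    ct_ref_control,
    ct_target_experimental,
    ct_ref_experimental,
    gene: str = "",
) -> DdctRecord:
    """Relative expression as 2^ddCt from triplicate Ct values.

    dCt = mean(Ct_target) - mean(Ct_reference) per genotype;
    ddCt = dCt_control - dCt_experimental, so positive ddCt (fold > 1)
    means higher expression in the experimental genotype.
    """
    dct_c = _mean_ct(ct_target_control, "target/control") - _mean_ct(
        ct_ref_control, "reference/control"
    )
    dct_e = _mean_ct(ct_target_experimental, "target/experimental") - _mean_ct(
        ct_ref_experimental, "reference/experimental"
    )
    ddct = dct_c - dct_e
    return DdctRecord(
        gene=gene, dct_control=dct_c, dct_experimental=dct_e,
        ddct=ddct, fold_change=float(2.0**ddct),
    )
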
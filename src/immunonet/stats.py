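"""Differential-expression and cohort-characteristic statistics.

Empirical-Bayes moderated t-tests for two-group differential expression,
Benjamini-Hochberg FDR control, Pearson chi-square tests for contingency
tables, Mann-Whitney U, Kruskal-Wallis with Dunn post-hoc comparisons,
Pearson/Spearman correlation, and hypergeometric over-representation
analysis of gene sets.

All gene-level tests assume expression is already on a log scale
(e.g. log2(TPM+1) or log2 microarray intensity); fold changes are group
mean differences on that scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "ContingencyResult",
    "EnrichmentResult",
    "moderated_t_test",
    "bh_adjust",
    "chi_square_test",
    "mann_whitney_u",
    "kruskal_dunn",
    "correlate",
    "ora_hypergeometric",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene moderated-t differential expression table.

    Attributes
    ----------
    table : DataFrame indexed by gene with columns
        ``log2fc`` (group1 - group2 mean difference), ``s2`` (pooled
        residual variance), ``t`` (moderated t), ``df`` (d0 + d_g),
        ``p`` and ``q`` (BH adjusted).
    prior_df : empirical-Bayes prior degrees of freedom d0 (may be inf).
    prior_var : prior variance s0^2.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float

    def significant(self, fdr: float = 0.1) -> pd.Index:
        return self.table.index[self.table["q"] < fdr]


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation results, one row per gene set."""

    table: pd.DataFrame


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _fit_f_dist(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to residual variances.

    Matches the classical empirical-Bayes approach: moments of log(s^2)
    with digamma/trigamma corrections.  Returns (d0, s0^2); d0 = inf when
    the trigamma equation has no positive root (variances fully shrunk).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2) + np.log(df_resid / 2)
    e_mean = e.mean()
    # target: trigamma(d0/2) = var(e) - trigamma(df/2)
    rhs = np.mean((e - e_mean) ** 2) * len(e) / max(len(e) - 1, 1) - special.polygamma(
        1, df_resid / 2
    )
    if rhs <= 0:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
        return d0, s0
    # invert trigamma by Newton iteration on the 1/x-transformed scale
    x = 0.5 + 1.0 / rhs
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1 - tri / rhs) / special.polygamma(2, x)
        x = x + delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2 * x
    s0 = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return float(d0), s0


def moderated_t_test(
    expr: pd.DataFrame,
    group_labels,
    *,
    shrink: bool = True,
) -> DEResult:
    """Empirical-Bayes moderated two-sample t-test, gene by gene.

    Parameters
    ----------
    expr : gene x sample log-expression matrix.
    group_labels : sequence aligned with ``expr`` columns; exactly two
        distinct labels.  The first label in sorted order is "group 1"
        and fold changes are group1 - group2.  Pass labels "case" /
        "control" to get case-minus-control fold changes.
    shrink : when False, d0 is forced to 0 and the test reduces to the
        classical pooled two-sample t.
    """
    labels = np.asarray(group_labels)
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    m1 = labels == uniq[0]
    m2 = labels == uniq[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs n >= 2 (got {n1}, {n2})")

    x = expr.to_numpy(dtype=float)
    x1, x2 = x[:, m1], x[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    delta = mean1 - mean2
    df_resid = n1 + n2 - 2
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(
        axis=1
    )
    s2 = ss / df_resid

    if shrink and np.any(s2 > 0):
        d0, s0 = _fit_f_dist(s2, df_resid)
    else:
        d0, s0 = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    elif d0 > 0:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = np.full_like(s2, d0 + df_resid)
    else:
        s2_post = s2
        df_total = np.full_like(s2, df_resid)

    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    # all-identical gene: zero variance and zero difference -> t = 0, p = 1
    finite_df = np.where(np.isfinite(df_total), df_total, 1e9)
    p = 2 * stats.t.sf(np.abs(t), finite_df)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": delta, "s2": s2, "t": t, "df": df_total, "p": p, "q": q},
        index=expr.index,
    )
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def chi_square_test(table) -> ContingencyResult:
    """Pearson chi-square test without continuity correction.

    All-zero rows/columns are dropped (with the dropped category labels
    recorded) before computing the statistic, reducing the degrees of
    freedom accordingly.
    """
    if isinstance(table, pd.DataFrame):
        df_tab = table.copy()
    else:
        df_tab = pd.DataFrame(np.asarray(table))
    arr = df_tab.to_numpy(dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must hold nonnegative integer counts")
    row_keep = arr.sum(axis=1) > 0
    col_keep = arr.sum(axis=0) > 0
    dropped_rows = [str(i) for i in df_tab.index[~row_keep]]
    dropped_cols = [str(c) for c in df_tab.columns[~col_keep]]
    arr = arr[row_keep][:, col_keep]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("degenerate table after dropping all-zero categories")
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        expected=expected,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, *, exact: bool | None = None) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration for small tie-free samples (or when
    ``exact=True``), otherwise the tie-corrected normal approximation.
    Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if exact is None:
        exact = (x.size + y.size <= 12) and not has_ties
    if exact and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    # tie-corrected normal approximation, no continuity correction
    # (equivalent to the 2-group Kruskal-Wallis chi-square)
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2) / np.sqrt(var)
    return float(u), float(min(2 * stats.norm.sf(abs(z)), 1.0))


def kruskal_dunn(values, group_labels) -> dict:
    """Kruskal-Wallis test with Dunn's post-hoc pairwise comparisons.

    Dunn z-statistics use mean ranks with the tie-corrected standard
    error; pairwise p-values are BH adjusted.  All-identical input is
    reported as KW statistic 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(values == values[0]):
        pairs = list(itertools.combinations(groups, 2))
        pair_table = pd.DataFrame(
            {"group1": [a for a, _ in pairs], "group2": [b for _, b in pairs],
             "z": 0.0, "p": 1.0, "q": 1.0}
        )
        return {"statistic": 0.0, "p_value": 1.0, "pairwise": pair_table}

    kw_stat, kw_p = stats.kruskal(*samples)

    ranks = stats.rankdata(values)
    n_total = values.size
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_term

    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(base_var * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    pair_table = pd.DataFrame(rows)
    pair_table["q"] = bh_adjust(pair_table["p"].to_numpy())
    return {"statistic": float(kw_stat), "p_value": float(kw_p), "pairwise": pair_table}


def correlate(x, y, method: str = "pearson", *, exact_max_n: int = 8):
    """Correlation coefficient with two-sided p-value.

    method : "pearson" or "spearman".  For n <= ``exact_max_n`` the
    p-value is computed by exact enumeration of all orderings of ``y``;
    the t-approximation is used otherwise.  Zero-variance input yields
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input: correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        stat_fn = lambda a, b: stats.pearsonr(a, b)[0]  # noqa: E731
    elif method == "spearman":
        stat_fn = lambda a, b: stats.spearmanr(a, b)[0]  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(stat_fn(x, y))
    n = x.size
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(stat_fn(x, y[list(perm)])) >= abs(r) - 1e-12:
                count += 1
        return r, count / total
    if method == "pearson":
        p = float(stats.pearsonr(x, y)[1])
    else:
        p = float(stats.spearmanr(x, y)[1])
    return r, p


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def ora_hypergeometric(
    hit_genes,
    universe,
    gene_sets: dict[str, list[str]],
    de_direction: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of gene sets.

    ``de_direction`` optionally maps genes to +1 (up) / -1 (down); the
    direction z-score of a set is (n_up - n_down) / sqrt(overlap)
    over the overlapping genes (0 when the overlap is empty).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes) & universe
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        overlap = hits & members
        k, K, n, N = len(overlap), len(members), len(hits), len(universe)
        # P(X >= k) for X ~ Hypergeom(N, K, n); overlap 0 -> p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        if de_direction and overlap:
            n_up = sum(1 for g in overlap if de_direction.get(g, 0) > 0)
            n_down = sum(1 for g in overlap if de_direction.get(g, 0) < 0)
            z = (n_up - n_down) / np.sqrt(len(overlap))
        else:
            z = 0.0
        rows.append(
            {"set": name, "overlap": k, "set_size": K, "hits": n,
             "universe": N, "p": min(p, 1.0), "direction_z": z}
        )
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table)
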
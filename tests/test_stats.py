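"""Statistical primitives: moderated t, BH, chi-square, rank tests, ORA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from immunonet.stats import (
    bh_adjust,
    chi_square_test,
    correlate,
    kruskal_dunn,
    mann_whitney_u,
    moderated_t_test,
    ora_hypergeometric,
    read_gmt,
)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _toy_expr(rows, columns=None):
    df = pd.DataFrame(rows, dtype=float)
    if columns is not None:
        df.columns = columns
    return df


def test_equal_group_means_give_t_zero_p_one():
    # both groups observe the same values {5, 6, 7} -> zero difference
    expr = _toy_expr({f"s{i}": [5.0 + (i % 3)] for i in range(6)})
    labels = ["case", "control"] * 3
    res = moderated_t_test(expr, labels)
    assert res.table["t"].iloc[0] == pytest.approx(0.0)
    assert res.table["p"].iloc[0] == pytest.approx(1.0)


def test_unshrunk_moderated_t_equals_classical_pooled_t():
    rng = np.random.default_rng(5)
    expr = pd.DataFrame(rng.normal(size=(4, 6)), columns=list("abcdef"))
    labels = ["case"] * 3 + ["control"] * 3
    res = moderated_t_test(expr, labels, shrink=False)
    for g in expr.index:
        t_ref, p_ref = sps.ttest_ind(
            expr.loc[g, :"c"], expr.loc[g, "d":], equal_var=True
        )
        assert res.table.loc[g, "t"] == pytest.approx(t_ref, abs=1e-10)
        assert res.table.loc[g, "p"] == pytest.approx(p_ref, abs=1e-10)


def test_all_identical_gene_reports_t0_p1():
    expr = pd.DataFrame({f"s{i}": [3.0, float(i)] for i in range(6)})
    res = moderated_t_test(expr, ["case"] * 3 + ["control"] * 3)
    assert res.table["t"].iloc[0] == 0.0
    assert res.table["p"].iloc[0] == 1.0


def test_moderated_t_rejects_single_sample_group():
    expr = pd.DataFrame(np.ones((3, 4)))
    with pytest.raises(ValueError):
        moderated_t_test(expr, ["case", "control", "control", "control"])


def test_moderated_t_monotone_in_mean_difference():
    """|t| grows with |group mean difference| at fixed residual variance."""
    rng = np.random.default_rng(0)
    base = rng.normal(size=6)
    rows = {f"g{k}": np.concatenate([base[:3] + k, base[3:]]) for k in range(4)}
    expr = pd.DataFrame(rows).T
    res = moderated_t_test(expr, ["case"] * 3 + ["control"] * 3, shrink=False)
    t = res.table["t"].abs().to_numpy()
    assert np.all(np.diff(t) > 0)


def test_moderated_t_matches_limma_reference(tmp_path):
    """Dual-route check: the whole empirical-Bayes pipeline (prior df,
    prior variance, moderated t, p) agrees with limma's lmFit/eBayes on
    a fixed heteroscedastic matrix."""
    import subprocess

    rng = np.random.default_rng(42)
    expr = pd.DataFrame(
        rng.normal(size=(60, 10)) * rng.uniform(0.5, 2, size=(60, 1)),
        index=[f"g{i}" for i in range(60)],
    )
    res = moderated_t_test(expr, ["case"] * 5 + ["control"] * 5)
    expr.to_csv(tmp_path / "x.csv")
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.csv("{tmp_path / 'x.csv'}", row.names=1))
    design <- cbind(Intercept=1, case=c(1,1,1,1,1,0,0,0,0,0))
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(t=fit$t[,"case"], p=fit$p.value[,"case"],
                      d0=fit$df.prior, s0=fit$s2.prior)
    write.csv(out, "{tmp_path / 'limma.csv'}")
    """
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    lim = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    assert res.prior_df == pytest.approx(lim["d0"].iloc[0], rel=1e-4)
    assert res.prior_var == pytest.approx(lim["s0"].iloc[0], rel=1e-4)
    np.testing.assert_allclose(res.table["t"], lim["t"], atol=1e-8)
    np.testing.assert_allclose(res.table["p"], lim["p"], atol=1e-8)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
        ((0.005, 0.01, 0.03, 0.04), (0.02, 0.02, 0.04, 0.04)),
        ((0.2,), (0.2,)),
    ],
)
def test_bh_step_up_worked_examples(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_reapplication_never_adds_rejections(p):
    """Re-adjusting q-values preserves their order and can only move
    them up, so BH-of-BH never rejects anything BH itself did not."""
    q1 = bh_adjust(p)
    q2 = bh_adjust(q1)
    assert np.all(q2 >= q1 - 1e-12)
    order = np.argsort(q1, kind="stable")
    assert np.all(np.diff(q2[order]) >= -1e-12)
    for alpha in (0.01, 0.05, 0.1, 0.5):
        assert set(np.nonzero(q2 <= alpha)[0]) <= set(np.nonzero(q1 <= alpha)[0])


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi_square_matches_textbook_formula_on_random_tables(rng):
    for _ in range(1000):
        shape = (rng.integers(2, 5), rng.integers(2, 4))
        table = rng.integers(1, 40, size=shape)
        res = chi_square_test(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, (shape[0] - 1) * (shape[1] - 1))
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_chi_square_drops_all_zero_categories():
    table = pd.DataFrame(
        [[0, 0], [4, 1], [6, 4], [12, 7], [9, 4]],
        index=["<30", "30-39", "40-49", "50-59", "60-69"],
        columns=["cases", "controls"],
    )
    res = chi_square_test(table)
    assert res.dropped_rows == ["<30"]
    assert res.df == 3


def test_chi_square_degenerate_after_dropping_raises():
    with pytest.raises(ValueError):
        chi_square_test([[0, 0], [3, 4]])


def test_chi_square_expected_margins_match_observed():
    res = chi_square_test([[6, 5], [8, 9]])
    obs = np.array([[6, 5], [8, 9]])
    assert res.expected.sum(axis=0) == pytest.approx(obs.sum(axis=0))
    assert res.expected.sum(axis=1) == pytest.approx(obs.sum(axis=1))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _mwu_exact_enumeration(x, y):
    """Exact two-sided MWU p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
    n = len(pooled)
    stats_all = []
    for idx in itertools.combinations(range(n), n1):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        u = sps.mannwhitneyu(
            pooled[sel], pooled[~sel], alternative="two-sided", method="exact"
        ).statistic
        stats_all.append(u)
    stats_all = np.asarray(stats_all, float)
    mid = len(x) * len(y) / 2
    return np.mean(np.abs(stats_all - mid) >= abs(obs - mid) - 1e-12)


def test_mwu_identical_multisets_p_one():
    x = [1.0, 2.0, 2.0, 3.0]
    assert mann_whitney_u(x, x)[1] == pytest.approx(1.0)


def test_mwu_exact_small_sample():
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)
    assert p == pytest.approx(_mwu_exact_enumeration(np.array([1.0, 2]), np.array([3.0, 4])))


def test_mwu_enumeration_oracle_random_instances(rng):
    for _ in range(5):
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        _, p = mann_whitney_u(x, y, exact=True)
        assert p == pytest.approx(_mwu_exact_enumeration(x, y), abs=1e-10)


def test_mwu_empty_sample_raises():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def test_kruskal_all_equal_convention():
    res = kruskal_dunn([1.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert res["statistic"] == 0.0
    assert res["p_value"] == 1.0
    assert (res["pairwise"]["q"] == 1.0).all()


def test_kruskal_separated_groups_all_dunn_significant():
    values = list(range(5)) + list(range(10, 15)) + list(range(20, 25))
    labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
    res = kruskal_dunn(values, labels)
    assert res["p_value"] < 0.01
    assert (res["pairwise"]["q"] < 0.1).all()


def test_kruskal_two_groups_agrees_with_mwu():
    x = [1.0, 4.0, 2.5]
    y = [3.0, 5.0, 6.0]
    res = kruskal_dunn(x + y, ["a"] * 3 + ["b"] * 3)
    _, p_mwu = mann_whitney_u(x, y, exact=False)
    assert res["p_value"] == pytest.approx(p_mwu, rel=0.05)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_pearson_perfect_linear():
    x = np.arange(10.0)
    r, _ = correlate(x, 2 * x + 1, "pearson")
    assert r == pytest.approx(1.0)


def test_spearman_monotone_invariance():
    x = np.linspace(-1, 2, 12)
    rho, _ = correlate(x, np.exp(x), "spearman")
    assert rho == pytest.approx(1.0)


def test_correlation_exact_permutation_p(rng):
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    for method in ("pearson", "spearman"):
        r, p = correlate(x, y, method)
        # independent enumeration of all 120 orderings
        stat = (
            (lambda a, b: sps.pearsonr(a, b)[0])
            if method == "pearson"
            else (lambda a, b: sps.spearmanr(a, b)[0])
        )
        count = sum(
            abs(stat(x, y[list(perm)])) >= abs(r) - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert p == pytest.approx(count / 120)


def test_correlation_zero_variance_reported_missing():
    with pytest.warns(UserWarning):
        r, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(r) and np.isnan(p)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def test_ora_full_set_overlap_exact_tail():
    universe = [f"g{i}" for i in range(100)]
    hits = universe[:10]
    res = ora_hypergeometric(hits, universe, {"S": universe[:10]})
    # all 10 hits inside the 10-gene set: p = P(X >= 10) for
    # X ~ Hypergeom(100, 10, 10)
    expected = sps.hypergeom.pmf(10, 100, 10, 10)
    assert res.table.loc["S", "p"] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(1 / 17310309456440, rel=1e-6)


def test_ora_disjoint_set_p_one():
    universe = [f"g{i}" for i in range(50)]
    res = ora_hypergeometric(universe[:5], universe, {"S": universe[40:]})
    assert res.table.loc["S", "p"] == 1.0


def test_ora_direction_z():
    universe = [f"g{i}" for i in range(50)]
    hits = universe[:9]
    res = ora_hypergeometric(
        hits, universe, {"S": universe[:20]}, de_direction={g: 1 for g in hits}
    )
    assert res.table.loc["S", "direction_z"] == pytest.approx(3.0)


def test_gmt_round_trip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("s1\tdesc\tg1\tg2\ng_empty\tdesc\tg3\n")
    sets = read_gmt(path)
    assert sets == {"s1": ["g1", "g2"], "g_empty": ["g3"]}
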
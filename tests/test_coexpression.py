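"""Signed networks, TOM, module detection, eigengenes, preservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunonet import coexpression as cx
from immunonet import simulate as sim

from conftest import two_block_expr


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------

def _tom_loop_oracle(adj):
    """Brute-force O(n^3) topological overlap, straight from the formula."""
    n = adj.shape[0]
    k = adj.sum(axis=1) - 1
    tom = np.zeros_like(adj)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def test_signed_adjacency_limits():
    n = 20
    t = np.linspace(0, 1, n)
    up = pd.DataFrame({"g1": t, "g2": t + 0.0, "g3": 1 - t}).T
    net = cx.build_network(up, beta=6)
    assert net.adjacency.loc["g1", "g2"] == pytest.approx(1.0)      # cor = +1
    assert net.adjacency.loc["g1", "g3"] == pytest.approx(0.0, abs=1e-12)  # cor = -1


@pytest.mark.parametrize("n_genes,seed", [(4, 0), (30, 1), (50, 2)])
def test_tom_matches_triple_loop_oracle(n_genes, seed):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(rng.normal(size=(n_genes, 15)))
    net = cx.build_network(expr, beta=4)
    oracle = _tom_loop_oracle(net.adjacency.to_numpy())
    np.testing.assert_allclose(net.tom.to_numpy(), oracle, atol=1e-8)


def test_tom_bounds_symmetry_and_diagonal(gene_expr):
    expr1, _ = gene_expr
    net = cx.build_network(expr1.iloc[:60], beta=6)
    tom = net.tom.to_numpy()
    assert np.all((tom >= 0) & (tom <= 1))
    assert np.max(np.abs(tom - tom.T)) < 1e-10
    assert np.allclose(np.diag(tom), 1.0)


def test_constant_gene_rejected():
    expr = pd.DataFrame([[1.0] * 10, list(range(10))], index=["flat", "ok"])
    with pytest.raises(ValueError, match="flat"):
        cx.build_network(expr, beta=2)


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

def test_mean_connectivity_strictly_decreasing_in_beta(gene_expr):
    expr1, _ = gene_expr
    _, fit = cx.pick_soft_threshold(expr1.iloc[:80], candidate_betas=[2, 4, 6, 8])
    assert np.all(np.diff(fit["mean_k"]) < 0)
    assert len(fit) == 4


def test_scale_free_fit_matches_independent_binned_regression():
    expr = two_block_expr(10, 40, noise=0.3)
    net = cx.build_network(expr, beta=6)
    k = net.adjacency.to_numpy().sum(axis=1) - 1
    # independent re-implementation of the binned log-log regression
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), 11)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(10):
        if (which == b).sum():
            xs.append(k[which == b].mean())
            ys.append((which == b).mean())
    slope, _, r, _, _ = sps.linregress(np.log10(xs), np.log10(ys))
    expected = -np.sign(slope) * r**2
    assert cx._scale_free_fit(k) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def test_two_clean_blocks_detected_exactly():
    expr = two_block_expr(10, 40, noise=0.0)
    net = cx.build_network(expr, beta=6)
    mods = cx.detect_modules(net, expr, min_size=5)
    assert len(mods.modules) == 2
    assert (mods.labels == "grey").sum() == 0
    # all A-genes share one label, all B-genes the other
    assert mods.labels[[f"A{i}" for i in range(10)]].nunique() == 1
    assert mods.labels[[f"B{i}" for i in range(10)]].nunique() == 1


def test_min_size_larger_than_clusters_gives_all_grey():
    expr = two_block_expr(5, 30, noise=0.0)
    net = cx.build_network(expr, beta=6)
    with pytest.warns(UserWarning):
        mods = cx.detect_modules(net, expr, min_size=50)
    assert (mods.labels == "grey").all()


def test_detection_invariant_to_gene_order(gene_expr):
    expr1, _ = gene_expr
    sub = expr1.iloc[:100]
    net = cx.build_network(sub, beta=6)
    mods = cx.detect_modules(net, sub, min_size=10)
    perm = np.random.default_rng(3).permutation(len(sub))
    sub2 = sub.iloc[perm]
    net2 = cx.build_network(sub2, beta=6)
    mods2 = cx.detect_modules(net2, sub2, min_size=10)
    # same partition of genes (labels are size-ordered so names agree)
    assert mods.labels.sort_index().equals(mods2.labels.sort_index())


def test_planted_modules_recovered(default_truth, gene_expr):
    from sklearn.metrics import adjusted_rand_score

    expr1, _ = gene_expr
    beta, _ = cx.pick_soft_threshold(expr1)
    net = cx.build_network(expr1, beta)
    mods = cx.detect_modules(net, expr1, min_size=20)
    truth_labels = [default_truth.module_assignment[g] for g in expr1.index]
    assert adjusted_rand_score(truth_labels, mods.labels) >= 0.8


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def test_rank1_module_eigengene_is_standardized_profile():
    t = np.sin(np.linspace(0, 7, 25))
    expr = pd.DataFrame({f"g{i}": 3 * t + i for i in range(4)}).T
    labels = pd.Series("m", index=expr.index)
    eig = cx.module_eigengenes(expr, labels)
    zt = (t - t.mean()) / t.std(ddof=1)
    np.testing.assert_allclose(eig.loc["m"].to_numpy(), zt, atol=1e-8)


def test_eigengene_sign_convention_and_flip_invariance(rng):
    expr = pd.DataFrame(rng.normal(size=(6, 30)))
    labels = pd.Series("m", index=expr.index)
    e1 = cx.module_eigengenes(expr, labels).loc["m"]
    e2 = cx.module_eigengenes(-expr, labels).loc["m"]
    np.testing.assert_allclose(np.abs(e1), np.abs(e2), atol=1e-8)
    mean_profile = ((expr.T - expr.mean(1)) / expr.std(1, ddof=1)).mean(axis=1)
    assert np.corrcoef(e1, mean_profile)[0, 1] >= 0


def test_eigengene_variance_explained_matches_eigendecomposition(rng):
    expr = pd.DataFrame(rng.normal(size=(3, 40)))
    z = ((expr.T - expr.mean(1)) / expr.std(1, ddof=1)).T.to_numpy()
    eig = cx.module_eigengenes(expr, pd.Series("m", index=expr.index)).loc["m"]
    # variance explained by PC1 = top eigenvalue share of the 3x3
    # correlation matrix
    evals = np.linalg.eigvalsh(np.corrcoef(expr))
    share = evals[-1] / evals.sum()
    proj = np.array([np.corrcoef(z[i], eig)[0, 1] ** 2 for i in range(3)]).mean()
    assert proj == pytest.approx(share, abs=1e-8)


def test_unit_variance_eigengenes(gene_expr):
    expr1, _ = gene_expr
    net = cx.build_network(expr1.iloc[:100], beta=6)
    mods = cx.detect_modules(net, expr1.iloc[:100], min_size=10)
    if len(mods.eigengenes):
        np.testing.assert_allclose(mods.eigengenes.std(axis=1, ddof=1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# trait association
# ---------------------------------------------------------------------------

def test_trait_equal_to_eigengene_gives_rho_one(rng):
    e = rng.normal(size=20)
    eig = pd.DataFrame([e], index=["m"], columns=[f"s{i}" for i in range(20)])
    traits = pd.DataFrame({"t": e}, index=eig.columns)
    res = cx.module_trait_association(eig, traits)
    assert res["spearman_rho"].iloc[0] == pytest.approx(1.0)
    rev = pd.DataFrame({"t": -e}, index=eig.columns)
    assert cx.module_trait_association(eig, rev)["spearman_rho"].iloc[0] == pytest.approx(-1.0)


def test_trait_exact_p_small_n():
    eig = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["m"], columns=list("abcde"))
    traits = pd.DataFrame({"t": [2.0, 1, 4, 3, 5]}, index=list("abcde"))
    res = cx.module_trait_association(eig, traits)
    rho, p = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res["spearman_rho"].iloc[0] == pytest.approx(rho)
    assert res["p_value"].iloc[0] == pytest.approx(p)


def test_constant_trait_reported_missing():
    eig = pd.DataFrame([[1.0, 2, 3, 4]], index=["m"], columns=list("abcd"))
    traits = pd.DataFrame({"t": [1.0, 1, 1, 1]}, index=list("abcd"))
    with pytest.warns(UserWarning):
        res = cx.module_trait_association(eig, traits)
    assert np.isnan(res["spearman_rho"].iloc[0])


# ---------------------------------------------------------------------------
# preservation
# ---------------------------------------------------------------------------

def test_identical_cohorts_preserve_coherent_module(default_truth, gene_expr):
    expr1, _ = gene_expr
    labels = pd.Series(
        {g: m for g, m in default_truth.module_assignment.items() if m == "M1"}
    )
    res = cx.preservation_zsummary(expr1, expr1, labels, n_permutations=200, seed=0)
    assert res.table.loc["M1", "z_summary"] > 10
    assert res.n_permutations == 200


def test_noise_module_not_preserved(rng):
    ref = pd.DataFrame(rng.normal(size=(120, 40)),
                       index=[f"g{i}" for i in range(120)])
    test = pd.DataFrame(rng.normal(size=(120, 40)), index=ref.index)
    labels = pd.Series("m", index=ref.index[:30])
    res = cx.preservation_zsummary(ref, test, labels, n_permutations=100, seed=0)
    assert abs(res.table.loc["m", "z_summary"]) < 3


def test_preserved_modules_beat_scrambled(default_truth, gene_expr):
    expr1, expr2 = gene_expr
    labels = pd.Series(
        {g: m for g, m in default_truth.module_assignment.items() if m != "grey"}
    )
    res = cx.preservation_zsummary(expr1, expr2, labels, n_permutations=100, seed=0)
    z = res.table["z_summary"]
    preserved = default_truth.preserved_modules
    scrambled = [m for m in z.index if m not in preserved]
    assert z[preserved].min() > z[scrambled].max()


def test_module_larger_than_universe_raises(gene_expr):
    expr1, expr2 = gene_expr
    labels = pd.Series("m", index=expr1.index)
    with pytest.raises(ValueError):
        cx.preservation_zsummary(expr1.iloc[:20], expr2.iloc[:20], labels, 100, 0)
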
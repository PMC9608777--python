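"""Transition-matrix analysis of regulatory-network state changes.

Two state-specific bipartite TF -> gene networks (baseline = controls,
perturbed = cases) are inferred by blending a motif prior with direct
expression-correlation evidence.  A transition matrix tau maps the
baseline network onto the perturbed one column-by-column (ridge least
squares); the differential involvement of TF j (dTFI) is the proportion
of squared off-diagonal mass in tau's column j, in [0, 1].  TFs whose
targeting pattern is unchanged have dTFI near 0; a TF whose perturbed
targeting profile must be assembled from *other* TFs' baseline profiles
has dTFI near 1.  Significance comes from re-running the whole
inference under sample-label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "BipartiteNetwork",
    "TransitionModel",
    "DTFIResult",
    "infer_state_network",
    "estimate_transition",
    "compute_dtfi",
    "dtfi_significance",
]


@dataclass
class BipartiteNetwork:
    tfs: list[str]
    genes: list[str]
    weights: pd.DataFrame        # gene x TF regulatory scores
    state: str                   # "baseline" or "perturbed"

    def __post_init__(self):
        if len(set(self.tfs)) != len(self.tfs) or len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate TF or gene identifiers")
        if not np.all(np.isfinite(self.weights.to_numpy())):
            raise ValueError("non-finite network weights")


@dataclass
class TransitionModel:
    tau: pd.DataFrame            # TF x TF transition matrix
    ridge_lambda: float


@dataclass
class DTFIResult:
    table: pd.DataFrame          # per TF: dtfi, null_mean, null_sd, z, p, q
    n_permutations: int
    seed: int

    def significant(self, fdr: float = 0.1) -> list[str]:
        return list(self.table.index[self.table["q"] < fdr])

    def top(self) -> str:
        return str(self.table["dtfi"].idxmax())


def infer_state_network(
    expr_subset: pd.DataFrame,
    tf_list: list[str],
    motif_prior: pd.DataFrame,
    blend_alpha: float = 0.5,
    state: str = "baseline",
) -> BipartiteNetwork:
    """Bipartite TF -> gene network for one state.

    weight = blend_alpha * motif + (1 - blend_alpha) * cor(TF, gene),
    with the Pearson correlation taken across the state's samples.
    ``expr_subset`` must contain a row for every TF in ``tf_list``; the
    target universe is every non-TF row.  ``motif_prior`` is a long
    (tf, gene, weight) table; pairs absent from it count as 0.
    """
    if expr_subset.shape[1] < 3:
        raise ValueError("a state needs at least 3 samples")
    missing = [t for t in tf_list if t not in expr_subset.index]
    if missing:
        raise ValueError(f"TFs missing expression rows: {missing}")
    genes = [g for g in expr_subset.index if g not in set(tf_list)]

    motif = pd.DataFrame(0.0, index=genes, columns=tf_list)
    if len(motif_prior):
        sub = motif_prior[
            motif_prior["tf"].isin(tf_list) & motif_prior["gene"].isin(genes)
        ]
        for tf, gene, w in sub[["tf", "gene", "weight"]].itertuples(index=False):
            motif.loc[gene, tf] = float(w)

    x = expr_subset.to_numpy(dtype=float)
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = np.inf                      # constant row -> correlation 0
    z = z / sd[:, None]
    pos = {g: i for i, g in enumerate(expr_subset.index)}
    gi = np.array([pos[g] for g in genes])
    ti = np.array([pos[t] for t in tf_list])
    direct = (z[gi] @ z[ti].T) / expr_subset.shape[1]

    weights = blend_alpha * motif.to_numpy() + (1.0 - blend_alpha) * direct
    return BipartiteNetwork(
        tfs=list(tf_list),
        genes=genes,
        weights=pd.DataFrame(weights, index=genes, columns=tf_list),
        state=state,
    )


def estimate_transition(
    baseline: BipartiteNetwork,
    perturbed: BipartiteNetwork,
    ridge_lambda: float | None = None,
) -> TransitionModel:
    """Ridge least-squares transition matrix from baseline to perturbed.

    Each column tau[:, j] solves min ||B[:, j] - A tau[:, j]||^2 +
    lambda ||tau[:, j]||^2.  Default lambda = 0.1 tr(A'A)/m (heavy enough to damp the collinear noise that within-module correlation structure induces).  With
    lambda = 0 and rank-deficient A the minimum-norm solution is
    returned with a warning.
    """
    if baseline.tfs != perturbed.tfs or baseline.genes != perturbed.genes:
        raise ValueError("baseline/perturbed TF or gene orderings differ")
    a = baseline.weights.to_numpy(dtype=float)
    b = perturbed.weights.to_numpy(dtype=float)
    m = a.shape[1]
    if ridge_lambda is None:
        ridge_lambda = 1e-1 * np.trace(a.T @ a) / m
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    if ridge_lambda == 0:
        if np.linalg.matrix_rank(a) < m:
            warnings.warn("rank-deficient baseline with lambda=0: minimum-norm solution")
        tau, *_ = np.linalg.lstsq(a, b, rcond=None)
    else:
        ata = a.T @ a + ridge_lambda * np.eye(m)
        tau = np.linalg.solve(ata, a.T @ b)
    return TransitionModel(
        tau=pd.DataFrame(tau, index=baseline.tfs, columns=baseline.tfs),
        ridge_lambda=float(ridge_lambda),
    )


def compute_dtfi(model: TransitionModel) -> pd.Series:
    """dTFI_j = sum_{i != j} tau_ij^2 / sum_i tau_ij^2 per TF column j."""
    tau = model.tau.to_numpy(dtype=float)
    total = (tau**2).sum(axis=0)
    diag = np.diag(tau) ** 2
    out = np.zeros(tau.shape[1])
    zero = total == 0
    if np.any(zero):
        warnings.warn("all-zero transition column: dTFI set to 0")
    nz = ~zero
    out[nz] = (total[nz] - diag[nz]) / total[nz]
    return pd.Series(out, index=model.tau.columns, name="dtfi")


def _observed_dtfi(
    expr: pd.DataFrame,
    case_mask: np.ndarray,
    tf_list: list[str],
    motif_prior: pd.DataFrame,
    blend_alpha: float,
    ridge_lambda: float | None,
) -> pd.Series:
    base = infer_state_network(
        expr.loc[:, ~case_mask], tf_list, motif_prior, blend_alpha, state="baseline"
    )
    pert = infer_state_network(
        expr.loc[:, case_mask], tf_list, motif_prior, blend_alpha, state="perturbed"
    )
    return compute_dtfi(estimate_transition(base, pert, ridge_lambda))


def dtfi_significance(
    expr: pd.DataFrame,
    group_labels,
    tf_list: list[str],
    motif_prior: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
    fdr_threshold: float = 0.1,
    blend_alpha: float = 0.5,
    ridge_lambda: float | None = None,
) -> DTFIResult:
    """Permutation significance of per-TF differential involvement.

    The null permutes sample group labels and re-runs the full
    inference (both state networks and the transition matrix) per
    permutation.  z = (observed - null mean)/null sd, upper-tail normal
    p, BH q, significance at q < ``fdr_threshold``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    labels = np.asarray(group_labels)
    case_mask = labels == "case"
    n_case = int(case_mask.sum())
    if n_case < 3 or int((~case_mask).sum()) < 3:
        raise ValueError("each group needs at least 3 samples")

    obs = _observed_dtfi(expr, case_mask, tf_list, motif_prior, blend_alpha, ridge_lambda)

    rng = np.random.default_rng(seed)
    n = expr.shape[1]
    null = np.empty((n_permutations, len(tf_list)))
    for b in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_case, replace=False)] = True
        null[b] = _observed_dtfi(
            expr, perm, tf_list, motif_prior, blend_alpha, ridge_lambda
        ).to_numpy()

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    null_sd[null_sd == 0] = 1e-12
    z = (obs.to_numpy() - null_mean) / null_sd
    p = sps.norm.sf(z)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "dtfi": obs.to_numpy(),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
        },
        index=list(tf_list),
    )
    table.index.name = "tf"
    return DTFIResult(table=table, n_permutations=n_permutations, seed=seed)
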
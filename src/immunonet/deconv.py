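"""Signature-based cell-type deconvolution of bulk expression.

Estimates per-sample cell-type fractions by regressing each bulk
profile onto a marker-gene signature matrix, with nonnegative least
squares (default, deterministic) or linear nu-support-vector regression
over a small nu grid.  Coefficients are clipped at zero and normalized
to sum to one.

Standardization: each mixture column is scaled to unit mean (making
proportions invariant to a sample's global scale) and each gene row of
both signature and mixture is divided by the signature row's SD (a
shared per-gene scale, so the exact linear mixing identity survives the
transform; centering would break it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .stats import correlate, mann_whitney_u

__all__ = [
    "CellProportions",
    "deconvolve",
    "compare_groups",
    "median_split",
    "concordance",
]


@dataclass
class CellProportions:
    """Sample x cell-type fraction estimates plus per-sample fit diagnostics."""

    fractions: pd.DataFrame      # rows sum to 1
    diagnostics: pd.DataFrame    # per sample: rmse, r
    method: str

    def __post_init__(self):
        rs = self.fractions.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("fraction rows must sum to 1")


def deconvolve(
    mixture_expr: pd.DataFrame,
    signature: pd.DataFrame,
    method: str = "nnls",
    nu_grid=(0.25, 0.5, 0.75),
) -> CellProportions:
    """Estimate cell-type fractions for every mixture column.

    Requires >= 50% of signature genes present among the mixture rows
    (an error lists the missing genes otherwise); fitting uses the
    shared genes only.
    """
    if signature.shape[1] < 2:
        raise ValueError("signature needs at least 2 cell types")
    shared = signature.index.intersection(mixture_expr.index)
    missing = signature.index.difference(mixture_expr.index)
    if len(shared) < 0.5 * len(signature.index):
        raise ValueError(
            f"only {len(shared)}/{len(signature.index)} signature genes in mixture; "
            f"missing: {sorted(missing)[:20]}"
        )
    sig = signature.loc[shared].to_numpy(dtype=float)
    mix = mixture_expr.loc[shared].to_numpy(dtype=float)

    # per-sample scale to unit mean; shared per-gene scale from signature rows
    col_mean = mix.mean(axis=0)
    col_mean[col_mean == 0] = 1.0
    mix = mix / col_mean[None, :]
    gene_scale = sig.std(axis=1, ddof=0)
    gene_scale[gene_scale == 0] = 1.0
    sig_s = sig / gene_scale[:, None]
    mix_s = mix / gene_scale[:, None]

    coefs, rmses, rs = [], [], []
    for j in range(mix_s.shape[1]):
        y = mix_s[:, j]
        if method == "nnls":
            c, _ = nnls(sig_s, y)
        elif method == "nu_svr":
            best, best_rmse = None, np.inf
            for nu in nu_grid:
                svr = NuSVR(kernel="linear", nu=nu, C=1.0)
                svr.fit(sig_s, y)
                cc = np.clip(svr.coef_.ravel(), 0.0, None)
                resid = y - sig_s @ cc
                rm = float(np.sqrt(np.mean(resid**2)))
                if rm < best_rmse:
                    best, best_rmse = cc, rm
            c = best
        else:
            raise ValueError(f"unknown method {method!r}")
        if c.sum() == 0:
            raise ValueError(f"all-zero coefficient vector for sample {j}")
        fitted = sig_s @ c
        resid = y - fitted
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        rs.append(
            float(np.corrcoef(y, fitted)[0, 1]) if np.std(fitted) > 0 else np.nan
        )
        coefs.append(c / c.sum())

    fractions = pd.DataFrame(
        coefs, index=mixture_expr.columns, columns=signature.columns
    )
    diagnostics = pd.DataFrame(
        {"rmse": rmses, "r": rs}, index=mixture_expr.columns
    )
    return CellProportions(fractions=fractions, diagnostics=diagnostics, method=method)


def compare_groups(proportions: CellProportions, group_labels) -> pd.DataFrame:
    """Per-cell-type Mann-Whitney U case-vs-control comparison.

    The ``direction`` column is the sign of (case median - control
    median).
    """
    labels = np.asarray(group_labels)
    case = labels == "case"
    ctrl = ~case
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for cell in proportions.fractions.columns:
        v = proportions.fractions[cell].to_numpy()
        u, p = mann_whitney_u(v[case], v[ctrl])
        rows.append(
            {
                "cell_type": cell,
                "u": u,
                "p": p,
                "direction": int(np.sign(np.median(v[case]) - np.median(v[ctrl]))),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize at the cohort median: "high" iff value >= median."""
    v = pd.Series(values)
    if len(v) < 2:
        raise ValueError("need at least 2 samples")
    med = float(np.median(v.to_numpy(dtype=float)))
    return pd.Series(np.where(v >= med, "high", "low"), index=v.index)


def concordance(
    imputed: pd.DataFrame,
    clinical: pd.DataFrame,
    scale_to_percent: bool = True,
) -> pd.DataFrame:
    """Imputed-vs-clinical agreement per cell type.

    Both inputs are sample x cell-type tables on the fraction (or
    percent) scale with matched sample identifiers.  Reports Pearson r,
    Spearman rho with p-values, RMSE on the percentage scale, and the
    number of samples whose high/low median-split label (computed
    separately within each measurement) agrees.
    """
    samples = imputed.index.intersection(clinical.index)
    if len(samples) < 3:
        raise ValueError("need at least 3 matched samples")
    cells = [c for c in imputed.columns if c in clinical.columns]
    factor = 100.0 if scale_to_percent else 1.0
    rows = []
    for cell in cells:
        a = imputed.loc[samples, cell].to_numpy(dtype=float) * factor
        b = clinical.loc[samples, cell].to_numpy(dtype=float) * factor
        r, pr = correlate(a, b, "pearson", exact_max_n=0)
        rho, ps = correlate(a, b, "spearman", exact_max_n=0)
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        grp_a = median_split(pd.Series(a, index=samples))
        grp_b = median_split(pd.Series(b, index=samples))
        rows.append(
            {
                "cell_type": cell,
                "pearson_r": r,
                "pearson_p": pr,
                "spearman_rho": rho,
                "spearman_p": ps,
                "rmse_percent": rmse,
                "concordant": int((grp_a == grp_b).sum()),
                "n": len(samples),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
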
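"""PLS-DA classification of high/low cell-proportion groups.

Partial least squares regression against a +1/-1 class code (PLS1,
NIPALS deflation), with features and response median-centred and scaled
to unit variance.  Classification thresholds the predicted response at
zero (>= 0 -> "high").  Calibration passes when component-1
resubstitution yields fewer than 5 misclassifications and accuracy
above 70%.  VIP scores rank features; AUC is the Mann-Whitney
concordance probability, and paired ROC curves are compared with
Venkatraman's rank-exchange permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .stats import bh_adjust  # noqa: F401  (re-export convenience)

__all__ = [
    "PLSDA",
    "PLSDAResults",
    "CalibrationReport",
    "fit_plsda",
    "roc_auc",
    "venkatraman_test",
]


@dataclass
class CalibrationReport:
    misclassifications: int
    accuracy: float
    n: int

    @property
    def passed(self) -> bool:
        return self.misclassifications < 5 and self.accuracy > 0.70


@dataclass
class PLSDAResults:
    """Fitted PLS-DA model: weights, loadings, scores and scalers."""

    genes: list[str]
    x_weights: np.ndarray        # p x A, each column unit norm
    x_loadings: np.ndarray       # p x A
    y_loadings: np.ndarray       # A
    x_scores: np.ndarray         # n x A
    center: np.ndarray           # feature medians
    scale: np.ndarray            # feature SDs
    y_center: float
    y_scale: float
    n_components: int
    ssy: np.ndarray = field(default=None)  # variance of y explained per component

    # -- prediction ---------------------------------------------------------
    def _standardize(self, x_new: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.genes if g not in x_new.columns]
        if missing:
            raise ValueError(f"genes missing from new data: {missing}")
        x = x_new[self.genes].to_numpy(dtype=float)
        return (x - self.center) / self.scale

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        a = n_components or self.n_components
        w = self.x_weights[:, :a]
        p = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return w @ np.linalg.solve(p.T @ w, q)

    def decision_scores(
        self, x_new: pd.DataFrame, n_components: int | None = None
    ) -> pd.Series:
        """Predicted (standardized) response for new samples."""
        z = self._standardize(x_new)
        return pd.Series(z @ self.coefficients(n_components), index=x_new.index)

    def classify(
        self, x_new: pd.DataFrame, n_components: int | None = None
    ) -> pd.Series:
        """Call "high" iff the predicted response is >= 0."""
        s = self.decision_scores(x_new, n_components)
        return pd.Series(np.where(s >= 0, "high", "low"), index=s.index)

    def calibrate_check(self, x_train: pd.DataFrame, y_train) -> CalibrationReport:
        """Resubstitution gate on component 1 only: misclassifications
        < 5 and accuracy > 70%."""
        calls = self.classify(x_train, n_components=1)
        y = np.asarray(y_train)
        miss = int((calls.to_numpy() != y).sum())
        acc = 1.0 - miss / len(y)
        return CalibrationReport(misclassifications=miss, accuracy=acc, n=len(y))

    def vip_scores(self) -> pd.DataFrame:
        """VIP_j = sqrt(p sum_a SSY_a w_aj^2 / sum_a SSY_a); the mean
        squared VIP is 1 by construction, and VIP > 1 flags a feature
        as more influential than average."""
        p = len(self.genes)
        w2 = self.x_weights**2
        num = (w2 * self.ssy[None, :]).sum(axis=1)
        vip = np.sqrt(p * num / self.ssy.sum())
        table = pd.DataFrame({"vip": vip}, index=self.genes)
        table["selected"] = table["vip"] > 1.0
        table.index.name = "gene"
        return table

    def summary(self) -> str:
        lines = [
            f"PLS-DA model: {len(self.genes)} features, {self.n_components} components",
            f"  y explained per component: "
            + ", ".join(f"{v:.3f}" for v in self.ssy / self.ssy.sum()),
            f"  features with VIP > 1: {int(self.vip_scores()['selected'].sum())}",
        ]
        return "\n".join(lines)


class PLSDA:
    """PLS-DA model builder; ``fit`` returns :class:`PLSDAResults`.

    Parameters
    ----------
    x : sample x gene expression DataFrame.
    y : per-sample "high"/"low" labels (or +1/-1 codes).
    n_components : number of latent components (default 2).
    """

    def __init__(self, x: pd.DataFrame, y, n_components: int = 2):
        self.x = x
        self.y = pd.Series(y, index=x.index) if not isinstance(y, pd.Series) else y
        self.n_components = n_components

    def fit(self) -> PLSDAResults:
        y_raw = self.y.to_numpy()
        if set(pd.unique(y_raw)) <= {"high", "low"}:
            y = np.where(y_raw == "high", 1.0, -1.0)
        else:
            y = y_raw.astype(float)
        if len(np.unique(y)) < 2:
            raise ValueError("y contains a single class")

        x = self.x.to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance genes"
            )
        genes = [g for g, k in zip(self.x.columns, keep) if k]
        x = x[:, keep]
        center = np.median(x, axis=0)
        scale = x.std(axis=0, ddof=1)
        xs = (x - center) / scale
        y_center = float(np.median(y))
        y_scale = float(y.std(ddof=1))
        ys = (y - y_center) / y_scale

        n, p = xs.shape
        a_max = min(self.n_components, n - 1, p)
        ws, ps_, qs, ts, ssy = [], [], [], [], []
        xd, yd = xs.copy(), ys.copy()
        for _ in range(a_max):
            w = xd.T @ yd
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w = w / norm
            t = xd @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            p_load = xd.T @ t / tt
            q_load = float(yd @ t / tt)
            xd = xd - np.outer(t, p_load)
            yd = yd - q_load * t
            ws.append(w)
            ps_.append(p_load)
            qs.append(q_load)
            ts.append(t)
            ssy.append(q_load**2 * tt)
        if not ws:
            raise ValueError("no PLS component could be extracted")
        return PLSDAResults(
            genes=genes,
            x_weights=np.column_stack(ws),
            x_loadings=np.column_stack(ps_),
            y_loadings=np.array(qs),
            x_scores=np.column_stack(ts),
            center=center,
            scale=scale,
            y_center=y_center,
            y_scale=y_scale,
            n_components=len(ws),
            ssy=np.array(ssy),
        )


def fit_plsda(x: pd.DataFrame, y, n_components: int = 2) -> PLSDAResults:
    """Functional wrapper around :class:`PLSDA`."""
    return PLSDA(x, y, n_components).fit()


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC (Mann-Whitney concordance, ties counted 1/2).

    ``labels``: 1/"high" = positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if v in (1, "1", "high", True) else 0 for v in np.asarray(labels)])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    auc = (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(auc)


def _roc_error_curve(ranks: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Misclassification count at every rank threshold k = 1..n-1 when
    samples ranked above k are called positive."""
    n = len(ranks)
    order = np.argsort(ranks)
    y_sorted = y[order]
    # errors(k) = #positives with rank <= k + #negatives with rank > k
    cum_pos = np.cumsum(y_sorted)
    total_neg = int((1 - y).sum())
    cum_neg = np.cumsum(1 - y_sorted)
    ks = np.arange(1, n)
    return cum_pos[ks - 1] + (total_neg - cum_neg[ks - 1])


def venkatraman_test(
    scores_a,
    scores_b,
    labels,
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict:
    """Venkatraman's permutation test for equality of paired ROC curves.

    Both markers are rank-transformed (jitter breaks ties, seeded); the
    statistic is the integrated absolute difference between the two
    empirical error curves over all rank thresholds.  The null swaps
    the two markers' ranks within each sample with probability 1/2 and
    re-ranks; p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray([1 if v in (1, "1", "high", True) else 0 for v in np.asarray(labels)])
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be paired and aligned")
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000")
    rng = np.random.default_rng(seed)
    n = len(y)

    # one shared per-sample jitter breaks ties identically in both
    # markers, so identical (or monotone-equivalent) markers stay tied
    jitter = 1e-9 * rng.standard_normal(n)
    ra = rankdata(rankdata(a, method="average") + jitter)
    rb = rankdata(rankdata(b, method="average") + jitter)
    obs = float(np.abs(
        _roc_error_curve(ra, y).astype(float) - _roc_error_curve(rb, y)
    ).sum())

    count = 0
    for _ in range(n_permutations):
        swap = rng.random(n) < 0.5
        jit = 1e-6 * rng.standard_normal(n)
        pa = rankdata(np.where(swap, rb, ra) + jit)
        pb = rankdata(np.where(swap, ra, rb) + jit)
        stat = float(np.abs(
            _roc_error_curve(pa, y).astype(float) - _roc_error_curve(pb, y)
        ).sum())
        if stat >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    _, auc_a = roc_auc(a, y)
    _, auc_b = roc_auc(b, y)
    return {
        "statistic": obs,
        "p_value": float(p),
        "auc_a": auc_a,
        "auc_b": auc_b,
        "n_permutations": n_permutations,
        "seed": seed,
    }
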
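"""Statistical stage: group comparisons, logistic models, ROC analysis.

Outcome contrasts are one-vs-rest binary models over the lesion-segment
table (progression vs rest, regression vs rest); results are reported in
the conventional beta / SE / Z / p / OR (95% CI) layout.  ROC analysis uses
the empirical curve (trapezoidal AUC, identical to pairwise concordance
with ties counted 1/2), a Youden-maximizing operating point with ties
broken toward higher specificity, and seeded stratified-bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import SeparationError, ValidationError

__all__ = [
    "LogisticResult",
    "RocResult",
    "compare_groups",
    "fit_logistic",
    "roc_analysis",
    "forest_data",
]


@dataclass
class LogisticResult:
    """Per-covariate beta/SE/Z/p/OR(CI) table plus model metadata."""

    table: pd.DataFrame  # index = covariate; columns beta, se, z, p, or, ci_low, ci_high
    outcome: str
    covariates: list
    n: int
    converged: bool
    intercept: float
    method: str = "mle"
    model: object = field(default=None, repr=False)

    def predicted_probabilities(self, df: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(df[self.covariates].to_numpy(dtype=float), has_constant="add")
        beta = np.concatenate([[self.intercept], self.table["beta"].to_numpy()])
        return 1.0 / (1.0 + np.exp(-(X @ beta)))


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    metric_cis: dict
    confusion: dict  # tp, fp, tn, fn
    n_bootstrap: int
    fpr: np.ndarray = field(default=None, repr=False)
    tpr: np.ndarray = field(default=None, repr=False)


def compare_groups(cohort: pd.DataFrame, variable: str, group_col: str = "label") -> dict:
    """Per-group mean ± SD and a one-way ANOVA F across outcome groups."""
    groups = {}
    for name, sub in cohort.groupby(group_col):
        vals = sub[variable].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValidationError(f"group '{name}' has fewer than 2 members")
        groups[name] = vals
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    f_stat, p = sps.f_oneway(*groups.values())
    return {
        "groups": {
            name: {"n": len(v), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for name, v in groups.items()
        },
        "F": float(f_stat),
        "p": float(p),
    }


def _make_binary_outcome(cohort: pd.DataFrame, contrast: str, label_col: str) -> np.ndarray:
    labels = cohort[label_col].to_numpy()
    y = (labels == contrast).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError(f"outcome '{contrast}' is not binary in this table")
    return y


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalized logistic MLE (Jeffreys prior), Newton iterations."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def fit_logistic(
    cohort: pd.DataFrame,
    contrast: str,
    covariates: list,
    adjust: list | None = None,
    label_col: str = "label",
    firth: bool = False,
) -> LogisticResult:
    """One-vs-rest logistic regression with Wald inference.

    ``contrast`` names the positive class (e.g. ``"progression"``); all other
    rows form the rest.  ``adjust`` appends adjustment covariates to the
    model; the reported table covers every fitted covariate.  Complete or
    quasi-complete separation raises :class:`SeparationError` unless
    ``firth=True`` enables the Jeffreys-penalized fit.
    """
    cols = list(covariates) + list(adjust or [])
    if not cols:
        raise ValidationError("at least one covariate is required")
    sub = cohort.dropna(subset=cols + [label_col])
    y = _make_binary_outcome(sub, contrast, label_col)
    Xraw = sub[cols].to_numpy(dtype=float)
    X = sm.add_constant(Xraw, has_constant="add")

    if firth:
        beta, cov = _firth_fit(X, y)
        se = np.sqrt(np.diag(cov))
        converged = True
        method = "firth"
    else:
        model = sm.Logit(y, X)
        try:
            with np.errstate(all="ignore"):
                fit = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(
                f"logistic fit failed ({exc}); refit with firth=True"
            ) from exc
        beta = np.asarray(fit.params)
        se = np.asarray(fit.bse)
        converged = bool(fit.mle_retvals.get("converged", True))
        if (not converged) or np.any(np.abs(beta[1:]) > 20) or np.any(~np.isfinite(se)):
            raise SeparationError(
                "complete or quasi-complete separation detected; "
                "refit with firth=True for a penalized estimate"
            )
        method = "mle"

    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "beta": beta[1:],
            "se": se[1:],
            "z": z[1:],
            "p": pvals[1:],
            "or": np.exp(beta[1:]),
            "ci_low": np.exp(beta[1:] - 1.959963984540054 * se[1:]),
            "ci_high": np.exp(beta[1:] + 1.959963984540054 * se[1:]),
        },
        index=cols,
    )
    return LogisticResult(
        table=table,
        outcome=contrast,
        covariates=cols,
        n=len(y),
        converged=converged,
        intercept=float(beta[0]),
        method=method,
    )


def _confusion_metrics(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    acc = (tp + tn) / (tp + tn + fp + fn)
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "accuracy": acc,
    }


def _auc_trapezoid(scores, labels):
    fpr, tpr, thr = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr, thr


def roc_analysis(
    scores,
    labels,
    n_bootstrap: int = 2000,
    seed: int = 0,
    threshold_policy: str = "youden",
) -> RocResult:
    """Empirical ROC with Youden operating point and bootstrap CIs.

    AUC is the trapezoidal area under the empirical curve (equal to the
    pairwise concordance probability with ties scored 1/2).  The operating
    threshold maximizes Youden J = sensitivity + specificity - 1; exact ties
    resolve toward the higher-specificity (higher-threshold) point.  CIs are
    percentile intervals from a class-stratified bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind not in "biu":
        labels = (labels == labels.max()).astype(int)
    labels = labels.astype(int)
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC analysis needs both classes present")
    if threshold_policy != "youden":
        raise ValidationError("only the Youden threshold policy is implemented")

    auc, fpr, tpr, thr = _auc_trapezoid(scores, labels)
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # ties toward higher specificity = smaller fpr; roc_curve sorts thresholds
    # descending, so the smallest index among ties wins
    i_best = best[np.argmin(fpr[best])]
    threshold = float(thr[i_best])
    if not np.isfinite(threshold):  # sklearn's sentinel max(score)+1 edge
        threshold = float(scores.max())
    cm = _confusion_metrics(scores, labels, threshold)

    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    boot_auc = np.empty(n_bootstrap)
    boot_metrics = {k: np.empty(n_bootstrap) for k in
                    ("sensitivity", "specificity", "ppv", "npv", "accuracy")}
    for b in range(n_bootstrap):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=len(idx_pos), replace=True),
                rng.choice(idx_neg, size=len(idx_neg), replace=True),
            ]
        )
        sb, lb = scores[take], labels[take]
        boot_auc[b], *_ = _auc_trapezoid(sb, lb)
        m = _confusion_metrics(sb, lb, threshold)
        for k in boot_metrics:
            boot_metrics[k][b] = m[k]

    def ci(arr):
        ok = arr[np.isfinite(arr)]
        if len(ok) == 0:
            return (float("nan"), float("nan"))
        return (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))

    return RocResult(
        auc=auc,
        auc_ci=ci(boot_auc),
        threshold=threshold,
        sensitivity=cm["sensitivity"],
        specificity=cm["specificity"],
        ppv=cm["ppv"],
        npv=cm["npv"],
        accuracy=cm["accuracy"],
        metric_cis={k: ci(v) for k, v in boot_metrics.items()},
        confusion={k: cm[k] for k in ("tp", "fp", "tn", "fn")},
        n_bootstrap=n_bootstrap,
        fpr=fpr,
        tpr=tpr,
    )


def forest_data(results: list[LogisticResult]) -> pd.DataFrame:
    """Plot-ready long table: (model, covariate, OR, CI bounds, p, flagged).

    Rows with a degenerate CI (SE == 0) are flagged rather than dropped;
    input order is preserved.
    """
    if not results:
        raise ValidationError("forest_data needs at least one fitted model")
    rows = []
    for res in results:
        for cov, row in res.table.iterrows():
            rows.append(
                {
                    "model": res.outcome,
                    "covariate": cov,
                    "or": row["or"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "flagged": bool(row["se"] == 0),
                }
            )
    return pd.DataFrame(rows)
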
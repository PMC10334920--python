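"""Statistics for the human evaluations and model comparison.

Exact binomial (Clopper-Pearson) confidence intervals, visual-Turing-test
metrics (FPR = generated images voted real, TPR = real images voted real),
diagnosis recall and confusion matrices, OLS predictor significance, ROC/AUC,
and the DeLong test for paired ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed reports)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def format_p(p: float) -> str:
    """Report-style p string: tiny values print as '<.001'."""
    if p < 0.001:
        return "<.001"
    return f"{p:.2f}".lstrip("0") or "0"


@dataclass(frozen=True)
class BinomialCI:
    """Exact binomial interval: x successes of n at the given level."""

    successes: int
    trials: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.successes / self.trials


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial CI from Beta-distribution quantiles.

    lower = BetaInv(alpha/2; x, n-x+1), 0 when x = 0;
    upper = BetaInv(1-alpha/2; x+1, n-x), 1 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid counts x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(_stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(_stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(x, n, level, lower, upper)


# ---------------------------------------------------------------------------
# Visual Turing test
# ---------------------------------------------------------------------------


def vtt_metrics(table: pd.DataFrame, level: float = 0.95) -> dict[str, BinomialCI]:
    """FPR, TPR and accuracy of a visual-Turing-test response table.

    FPR is computed over generated-truth rows (vote "real" is a false
    positive), TPR over real-truth rows, accuracy over all rows; each comes
    with its exact binomial CI.
    """
    if len(table) == 0:
        raise ValueError("empty response table")
    gen = table[table["truth"] == "generated"]
    real = table[table["truth"] == "real"]
    out: dict[str, BinomialCI] = {}
    if len(gen) == 0 or len(real) == 0:
        raise ValueError("both truth classes are required")
    out["fpr"] = clopper_pearson(int((gen["vote"] == "real").sum()), len(gen), level)
    out["tpr"] = clopper_pearson(int((real["vote"] == "real").sum()), len(real), level)
    correct = int((table["vote"] == table["truth"]).sum())
    out["accuracy"] = clopper_pearson(correct, len(table), level)
    return out


def vtt_scores_per_rater(table: pd.DataFrame) -> pd.DataFrame:
    """Per-rater generated/real correct-identification scores and covariates."""
    rows = []
    for rater, sub in table.groupby("rater_id"):
        gen = sub[sub["truth"] == "generated"]
        real = sub[sub["truth"] == "real"]
        rows.append(
            {
                "rater_id": rater,
                "background": sub["background"].iloc[0],
                "experience_band": int(sub["experience_band"].iloc[0]),
                "generated_score": int((gen["vote"] == "generated").sum()),
                "real_score": int((real["vote"] == "real").sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnosis recall
# ---------------------------------------------------------------------------


def recall_by_group(table: pd.DataFrame, group_keys=("truth_type",)) -> pd.DataFrame:
    """Correct-diagnosis rate within each group, with exact binomial CIs.

    A response is correct when ``chosen_disease == truth_disease``. Returns
    one row per group with correct, total, recall, ci_low, ci_high.
    """
    if len(table) == 0:
        raise ValueError("empty diagnosis table")
    correct = (table["chosen_disease"] == table["truth_disease"]).astype(int)
    df = table.assign(_correct=correct)
    rows = []
    for keys, sub in df.groupby(list(group_keys)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        x, n = int(sub["_correct"].sum()), len(sub)
        ci = clopper_pearson(x, n)
        rows.append(
            dict(zip(group_keys, keys))
            | {"correct": x, "total": n, "recall": x / n, "ci_low": ci.lower, "ci_high": ci.upper}
        )
    return pd.DataFrame(rows)


def confusion_matrix(
    table: pd.DataFrame, partition: str, diseases=None
) -> pd.DataFrame:
    """Row-normalized confusion matrix of one skin-color partition.

    Rows are true diseases, columns chosen diseases; non-empty rows sum to 1.
    ``partition`` is one of the table's skin_color values (real/tan/brown/dark).
    """
    from .fixtures import DISEASES

    diseases = list(diseases) if diseases is not None else list(DISEASES)
    sub = table[table["skin_color"] == partition]
    unknown = (set(sub["truth_disease"]) | set(sub["chosen_disease"])) - set(diseases)
    if unknown:
        raise ValueError(f"unknown disease labels: {sorted(unknown)}")
    mat = pd.crosstab(sub["truth_disease"], sub["chosen_disease"])
    mat = mat.reindex(index=diseases, columns=diseases, fill_value=0).astype(float)
    sums = mat.sum(axis=1)
    nonzero = sums > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(sums[nonzero], axis=0)
    return mat


# ---------------------------------------------------------------------------
# OLS significance
# ---------------------------------------------------------------------------


def ols_significance(outcome, predictors: pd.DataFrame) -> pd.DataFrame:
    """Per-predictor OLS coefficient, t statistic and two-sided p value.

    Fits outcome ~ intercept + predictors by ordinary least squares and
    reports the usual t-tests. Raises on rank-deficient designs, naming the
    collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else (X.columns[0],)
        raise ValueError(f"rank-deficient design; collinear columns: {worst}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic (ties count one half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _midrank(x: np.ndarray) -> np.ndarray:
    return _stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values (V10, V01) and AUC for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance for a single ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = _binary_labels(labels)
    auc, v10, v01 = _delong_placements(scores, labels)
    m, n = int(labels.sum()), int((1 - labels).sum())
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(auc), float(var)


def _binary_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("both classes must be present")
    return (labels == uniq.max()).astype(int)


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong test comparing two correlated ROC curves on the same cases.

    Estimates var(AUC_a - AUC_b) from the placement-value covariance and
    returns a two-sided normal p. Degenerate variance (e.g. identical score
    vectors) yields z = 0, p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = _binary_labels(labels)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("paired scores must align with the labels")

    auc_a, v10_a, v01_a = _delong_placements(a, labels)
    auc_b, v10_b, v01_b = _delong_placements(b, labels)
    m, n = int(labels.sum()), int((1 - labels).sum())

    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    diff = auc_a - auc_b
    if var <= 0 or (diff == 0 and var == 0):
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * _stats.norm.sf(abs(z)))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": p}
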
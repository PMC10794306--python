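"""Group comparison of topological features: rank-sum tests and effect sizes.

For each of the six features and each stimulus condition (TGT, IGN, ALL)
the healthy and impaired epoch-level distributions are compared with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test, and the common-language
effect size (CLES) and single-feature ROC AUC are reported alongside.
CLES, AUC and U/(n1*n2) are the same number — the probability that a
random healthy epoch exceeds a random impaired one (ties counted half) —
computed here by three routes as a consistency guarantee.

Tests run at epoch level by default, mirroring the per-epoch feature
distributions; epochs within a subject are NOT independent, so the
p-values are descriptive. A subject-level aggregation (median feature
per subject) is available via ``aggregate="subject"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, shapiro

from .tda import FEATURE_NAMES

__all__ = ["rank_sum_test", "cles", "feature_auc", "compare_all",
           "CONDITIONS"]

CONDITIONS = ("TGT", "IGN", "ALL")


def _check(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    return x, y


def rank_sum_test(x, y):
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic counting
    x-wins (pairs with x > y, ties half) via midranks, and p comes from
    the normal approximation with tie and continuity corrections.
    """
    x, y = _check(x, y)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))) \
        if n > 1 else 0.0
    var = nx * ny / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return u, 1.0
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity correction
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return u, float(p)


def cles(x, y) -> float:
    """Common-language effect size P(X > Y) + 0.5 P(X = Y), pair counting."""
    x, y = _check(x, y)
    wins = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(x) * len(y)))


def feature_auc(values_pos, values_neg) -> float:
    """ROC AUC of the single-feature ranking classifier.

    Computed from midranks of the pooled sample; identical to the CLES
    of positive vs negative values.
    """
    pos, neg = _check(values_pos, values_neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _normality_p(values: np.ndarray, cap: int = 500) -> float:
    """Shapiro-Wilk p on at most ``cap`` values; NaN when undefined."""
    v = np.asarray(values, dtype=float)[:cap]
    if len(v) < 3 or np.ptp(v) == 0:
        return float("nan")
    return float(shapiro(v).pvalue)


def compare_all(features: pd.DataFrame, aggregate: str = "epoch",
                feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Per-feature, per-condition comparison table (18 rows by default).

    ``features`` is the study feature table (columns subject_id, group,
    condition plus the feature columns). Healthy is the x/positive side,
    so CLES > 0.5 means healthy epochs tend to exceed impaired ones.
    ``aggregate="subject"`` replaces each subject's epochs by their
    median before testing.
    """
    if aggregate not in ("epoch", "subject"):
        raise ValueError("aggregate must be 'epoch' or 'subject'")
    groups = set(features["group"])
    if not {"healthy", "mci"} <= groups:
        raise ValueError(f"need both groups present, have {sorted(groups)}")
    rows = []
    for condition in CONDITIONS:
        sub = features if condition == "ALL" else \
            features[features["condition"] == condition]
        for name in feature_names:
            if aggregate == "subject":
                per = sub.groupby(["subject_id", "group"], observed=True)[
                    name].median().reset_index()
                x = per.loc[per["group"] == "healthy", name].to_numpy()
                y = per.loc[per["group"] == "mci", name].to_numpy()
            else:
                x = sub.loc[sub["group"] == "healthy", name].to_numpy()
                y = sub.loc[sub["group"] == "mci", name].to_numpy()
            if len(x) and len(y):
                u, p_r = rank_sum_test(x, y)
                effect = cles(x, y)
                auc = feature_auc(x, y)
            else:  # a condition can be empty in tiny studies
                u = p_r = effect = auc = float("nan")
            rows.append({
                "feature": name,
                "condition": condition,
                "n_healthy": len(x),
                "n_mci": len(y),
                "U": u,
                "p_r": p_r,
                "cles": effect,
                "auc": auc,
                "p_n_healthy": _normality_p(x),
                "p_n_mci": _normality_p(y),
            })
    return pd.DataFrame(rows)
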
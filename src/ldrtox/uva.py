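"""Univariate screen: Spearman correlation with the toxicity label plus the
standalone discrimination (AUC) of each feature.

The reported AUC is orientation-corrected, ``max(a, 1 - a)``, so a feature
predictive in the protective direction (negative rank correlation) still
reports its discriminative ability above 0.5. Raw two-sided p-values are
reported without multiple-testing adjustment, with Benjamini–Hochberg
q-values added as a transparency column only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman_screen", "feature_auc", "univariate_table"]

P_SIGNIFICANT = 0.05
P_TREND = 0.1


def spearman_screen(
    features: pd.DataFrame, labels: np.ndarray
) -> pd.DataFrame:
    """Per-feature Spearman rho (mid-rank ties) and two-sided p-value.

    Constant features have no defined rank correlation; they are returned
    with NaN rho/p and flagged.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) < 3:
        raise ValueError("need at least 3 patients")
    if len(set(y)) != 2:
        raise ValueError("labels must contain both classes")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append((name, np.nan, np.nan, True))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((name, float(rho), float(p), False))
    return pd.DataFrame(rows, columns=["feature", "rho", "p_value", "constant"])


def feature_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Orientation-corrected AUC of one feature used as a raw score.

    Equals the Mann–Whitney U statistic (mid-rank tie convention) scaled to
    [0, 1], folded to ``max(a, 1 - a)``.
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y)) != 2:
        raise ValueError("labels must contain both classes")
    a = roc_auc_score(y, np.asarray(values, dtype=float))
    return float(max(a, 1.0 - a))


def univariate_table(features: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Full UVA table: rho, p, AUC, significance flags and BH q-values."""
    screen = spearman_screen(features, labels)
    y = np.asarray(labels, dtype=int)
    aucs = [
        np.nan if const else feature_auc(features[name].to_numpy(), y)
        for name, const in zip(screen["feature"], screen["constant"])
    ]
    screen["auc"] = aucs
    screen["significant"] = screen["p_value"] < P_SIGNIFICANT
    screen["trend"] = (screen["p_value"] >= P_SIGNIFICANT) & (screen["p_value"] < P_TREND)
    ok = screen["p_value"].notna()
    q = np.full(len(screen), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(screen.loc[ok, "p_value"], method="fdr_bh")[1]
    screen["bh_q"] = q
    return screen
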
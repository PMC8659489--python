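"""Hour-scale group statistics on the four main motion features.

The per-subject session means of the four main vector-magnitude features
(max, coefficient of variation, RMS, total power below 4 Hz) are
compared between medication states with a MANOVA on the paired
per-subject differences (a one-sample Hotelling T^2 test, which respects
the repeated-measures design), followed by post-hoc repeated-measures
ANOVAs per feature (two-level, so F = t^2 of the paired t-test) with
Benjamini-Hochberg FDR correction.  Clinical-score fluctuations are
related to model performance by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bradyflux.features import MAIN_FEATURES


def subject_state_means(standardized: pd.DataFrame) -> pd.DataFrame:
    """Mean of each main feature over all retained windows per
    (subject, state): one row per subject and state."""
    return (
        standardized.groupby(["subject_id", "state"], sort=True)[list(MAIN_FEATURES)]
        .mean()
        .reset_index()
    )


def _paired_differences(means: pd.DataFrame) -> np.ndarray:
    pre = means[means["state"] == "pre"].set_index("subject_id")[list(MAIN_FEATURES)]
    post = means[means["state"] == "post"].set_index("subject_id")[list(MAIN_FEATURES)]
    common = pre.index.intersection(post.index)
    if len(common) < 2:
        raise ValueError("MANOVA needs >= 2 subjects with both states")
    return (post.loc[common] - pre.loc[common]).to_numpy()


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_value: float
    p_value: float
    df_num: int
    df_den: int


def manova_medication(means: pd.DataFrame) -> ManovaResult:
    """One-way MANOVA of medication state on the four main features,
    formulated on paired per-subject differences (Hotelling T^2)."""
    d = _paired_differences(means)
    n, p = d.shape
    if n <= p:
        raise ValueError(f"need more than {p} subjects for a {p}-variate test")
    dbar = d.mean(axis=0)
    cov = np.cov(d, rowvar=False, ddof=1)
    if np.allclose(d, 0.0):
        return ManovaResult(1.0, 0.0, 1.0, p, n - p)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        offenders = [
            MAIN_FEATURES[i] for i in range(p) if cov[i, i] < 1e-15 * max(np.diag(cov))
        ]
        raise ValueError(
            "singular covariance of paired differences"
            + (f" (degenerate features: {offenders})" if offenders else "")
        )
    t2 = float(n * dbar @ np.linalg.solve(cov, dbar))
    f_value = (n - p) / (p * (n - 1)) * t2
    p_value = float(stats.f.sf(f_value, p, n - p))
    wilks = 1.0 / (1.0 + t2 / (n - 1))
    return ManovaResult(wilks, f_value, p_value, p, n - p)


@dataclass(frozen=True)
class RmAnovaResult:
    feature: str
    f_value: float
    p_value: float
    flagged: bool  # zero variance of differences -> p undefined


def posthoc_rm_anova(means: pd.DataFrame, feature: str) -> RmAnovaResult:
    """Two-level repeated-measures ANOVA for one feature (paired t-test,
    F = t^2, two-sided p)."""
    if feature not in means.columns:
        raise KeyError(feature)
    pre = means[means["state"] == "pre"].set_index("subject_id")[feature]
    post = means[means["state"] == "post"].set_index("subject_id")[feature]
    common = pre.index.intersection(post.index)
    diffs = (post.loc[common] - pre.loc[common]).to_numpy()
    if np.std(diffs, ddof=1) <= 1e-12 * max(abs(diffs.mean()), 1.0):
        if np.allclose(diffs, 0.0):
            return RmAnovaResult(feature, 0.0, 1.0, False)
        # every subject shifted by the identical non-zero amount: the
        # paired t statistic diverges, p tends to 0; flag the degeneracy
        return RmAnovaResult(feature, np.inf, 0.0, True)
    t_stat, p_value = stats.ttest_rel(post.loc[common], pre.loc[common])
    return RmAnovaResult(feature, float(t_stat**2), float(p_value), False)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure: (reject flags, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, adjusted


def main_feature_analysis(standardized: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """MANOVA followed by FDR-corrected post-hoc tests; one row per test."""
    means = subject_state_means(standardized)
    manova = manova_medication(means)
    posthoc = [posthoc_rm_anova(means, f) for f in MAIN_FEATURES]
    raw_p = [r.p_value for r in posthoc]
    reject, adj = fdr_bh(np.nan_to_num(raw_p, nan=1.0), alpha=alpha)
    rows = [
        {
            "test": "manova",
            "statistic": manova.wilks_lambda,
            "f_value": manova.f_value,
            "p_raw": manova.p_value,
            "p_adjusted": manova.p_value,
            "rejected": manova.p_value < alpha,
        }
    ]
    for r, rej, pa in zip(posthoc, reject, adj):
        rows.append(
            {
                "test": f"rm_anova_{r.feature}",
                "statistic": r.f_value,
                "f_value": r.f_value,
                "p_raw": r.p_value,
                "p_adjusted": pa,
                "rejected": bool(rej),
            }
        )
    return pd.DataFrame(rows)


def clinical_correlation(
    per_subject_auc: pd.Series, clinical_deltas: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of per-subject AUC against the absolute
    fluctuation of each clinical scale; one row per scale."""
    if len(per_subject_auc) < 5:
        raise ValueError("need >= 5 subjects for clinical correlations")
    rows = []
    for scale in clinical_deltas.columns:
        deltas = clinical_deltas[scale].loc[per_subject_auc.index]
        if deltas.nunique() <= 1 or per_subject_auc.nunique() <= 1:
            rows.append({"scale": scale, "rho": np.nan, "p_value": np.nan, "flagged": True})
            continue
        rho, p = stats.spearmanr(per_subject_auc.to_numpy(), deltas.to_numpy())
        rows.append({"scale": scale, "rho": float(rho), "p_value": float(p), "flagged": False})
    return pd.DataFrame(rows)


def clinical_delta_table(scores) -> pd.DataFrame:
    """Absolute pre/post fluctuation per clinical scale, indexed by subject."""
    rows = {
        s.subject_id: {
            "bradykinesia": abs(s.bradykinesia_post - s.bradykinesia_pre),
            "tremor": abs(s.tremor_post - s.tremor_pre),
            "aims": abs(s.aims_post - s.aims_pre),
        }
        for s in scores
    }
    return pd.DataFrame.from_dict(rows, orient="index")
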
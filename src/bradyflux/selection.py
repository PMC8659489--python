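"""Window selection: activity filter, state balancing, standardization.

Pipeline order is fixed: extract -> activity filter (60 s analyses only)
-> balance medication states -> standardize against the pre-medication
session.  Standardization statistics therefore describe exactly the
windows that enter the models, and are always per-subject, so group
models never share scale parameters across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bradyflux.features import FEATURE_NAMES, coefficient_of_variation
from bradyflux.preprocess import ProcessedRecording


@dataclass(frozen=True)
class SelectionConfig:
    """A window whose vector-magnitude coefficient of variation falls
    below ``activity_cov_threshold`` contains no meaningful movement and
    is discarded (when the filter is enabled)."""

    activity_cov_threshold: float = 0.3
    activity_filter_enabled: bool = True

    def validate(self) -> None:
        if self.activity_cov_threshold <= 0:
            raise ValueError("activity_cov_threshold must be positive")


def activity_filter(
    windows: pd.DataFrame,
    rec: ProcessedRecording,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Flag and drop no-activity windows of one session.

    The coefficient of variation is computed on the gravity-included
    vector magnitude of the resampled axes over each window's span (at
    rest that magnitude sits at ~9.81 m/s^2, so its CoV is near zero and
    the no-activity threshold has its intended meaning); a window is
    retained iff CoV >= threshold.  Returns a copy with the ``active``
    flag set and inactive windows removed (original ordering preserved).
    """
    config = config or SelectionConfig()
    config.validate()
    out = windows.copy()
    covs = []
    for _, row in out.iterrows():
        start = int(round((row["t_start"] - rec.t[0]) * rec.fs))
        stop = start + int(round(row["window_s"] * rec.fs))
        covs.append(coefficient_of_variation(rec.svm_raw[start:stop]))
    out["active"] = np.asarray(covs) >= config.activity_cov_threshold
    if not config.activity_filter_enabled:
        return out
    return out[out["active"]].reset_index(drop=True)


def balance_states(windows: pd.DataFrame) -> pd.DataFrame:
    """Equalise pre/post window counts for one subject by discarding the
    surplus from the temporal end of the longer state's sequence."""
    subjects = windows["subject_id"].unique()
    if len(subjects) > 1:
        raise ValueError("balance_states expects windows of exactly one subject")
    pre = windows[windows["state"] == "pre"]
    post = windows[windows["state"] == "post"]
    if pre.empty or post.empty:
        label = subjects[0] if len(subjects) else "<none>"
        warnings.warn(
            f"subject {label}: a medication state has no retained windows",
            stacklevel=2,
        )
        return windows.iloc[0:0].copy()
    k = min(len(pre), len(post))
    pre = pre.sort_values("window_index").iloc[:k]
    post = post.sort_values("window_index").iloc[:k]
    return pd.concat([pre, post]).reset_index(drop=True)


def standardize_to_premed(
    windows: pd.DataFrame, feature_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject z-scores against the pre-medication windows.

    For each feature f: z = (v - mean_pre(f)) / sd_pre(f), with mean and
    (sample) sd taken over the subject's retained pre-medication windows,
    so pre-state windows have mean 0 and sd 1 per feature afterwards.  A
    feature constant across pre windows is flagged and set to 0.

    Returns (standardized windows, per-feature scale table with columns
    feature, mean_pre, sd_pre, flagged).
    """
    feature_names = feature_names or FEATURE_NAMES
    pre = windows[windows["state"] == "pre"]
    if len(pre) < 2:
        raise ValueError("standardization needs at least 2 pre-medication windows")
    means = pre[feature_names].mean()
    sds = pre[feature_names].std(ddof=1)
    flagged = sds == 0.0
    out = windows.copy()
    safe_sd = sds.where(~flagged, 1.0)
    out[feature_names] = (out[feature_names] - means) / safe_sd
    out.loc[:, np.asarray(feature_names)[flagged.to_numpy()]] = 0.0
    scale = pd.DataFrame(
        {
            "feature": feature_names,
            "mean_pre": means.to_numpy(),
            "sd_pre": sds.to_numpy(),
            "flagged": flagged.to_numpy(),
        }
    )
    return out, scale


def select_and_standardize(
    per_session_windows: dict[tuple[str, str], pd.DataFrame],
    recordings: dict[tuple[str, str], ProcessedRecording],
    config: SelectionConfig | None = None,
    return_scales: bool = False,
):
    """Full selection stage for a cohort.

    ``per_session_windows`` and ``recordings`` are keyed by
    (subject_id, state).  Returns the concatenated balanced,
    standardized feature table over all subjects (subjects whose
    sessions end up empty are dropped with a warning); with
    ``return_scales`` also the per-subject standardization table
    (columns subject_id, feature, mean_pre, sd_pre, flagged).
    """
    config = config or SelectionConfig()
    subjects = sorted({sid for sid, _ in per_session_windows})
    tables = []
    scales = []
    for sid in subjects:
        per_state = []
        for state in ("pre", "post"):
            win = per_session_windows[(sid, state)]
            per_state.append(activity_filter(win, recordings[(sid, state)], config))
        balanced = balance_states(pd.concat(per_state, ignore_index=True))
        if balanced.empty or len(balanced[balanced["state"] == "pre"]) < 2:
            warnings.warn(f"subject {sid} dropped: too few balanced windows", stacklevel=2)
            continue
        standardized, scale = standardize_to_premed(balanced)
        tables.append(standardized)
        scales.append(scale.assign(subject_id=sid))
    if not tables:
        raise ValueError("no subject retained any balanced windows")
    table = pd.concat(tables, ignore_index=True)
    if return_scales:
        return table, pd.concat(scales, ignore_index=True)
    return table
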
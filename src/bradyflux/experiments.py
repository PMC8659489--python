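"""Training-size and window-length sweeps, and equality-plot comparison.

The training-size sweep varies how many subjects enter a group model's
training data (with repeated random subject draws); the window-length
sweep re-extracts features at several window durations (activity filter
disabled, since the 60 s activity rule has no analogue for
short windows) and re-runs the leave-one-subject-out group analysis.  The
equality comparison tests whether one model beats another in more
subjects than chance would allow, via a permutation approximation to the
binomial tail.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from bradyflux import classify
from bradyflux.features import extract_features
from bradyflux.preprocess import ProcessedRecording
from bradyflux.selection import SelectionConfig, select_and_standardize

DEFAULT_SIZES = tuple(range(1, 20))
DEFAULT_LENGTHS = (3.0, 10.0, 30.0, 60.0, 90.0, 120.0, 150.0, 300.0)


def training_size_sweep(
    standardized: pd.DataFrame,
    sizes: Sequence[int] = DEFAULT_SIZES,
    repeats: int = 5,
    model_kinds: Sequence[classify.ModelKind] = ("sv",),
    seed: int = 0,
) -> pd.DataFrame:
    """Group-model AUC as a function of the number of training subjects.

    For every test subject, training-set size and repeat, a random
    subject subset (excluding the test subject) is drawn without
    replacement, seeded per (size, repeat), and the group model is
    evaluated on all of the test subject's windows.
    """
    subjects = sorted(standardized["subject_id"].unique())
    if max(sizes) >= len(subjects):
        raise ValueError("training size must be smaller than the cohort")
    rows = []
    for size in sizes:
        for repeat in range(repeats):
            rng = np.random.default_rng((seed, size, repeat))
            for test_subject in subjects:
                others = [s for s in subjects if s != test_subject]
                train_subjects = list(rng.choice(others, size=size, replace=False))
                for kind in model_kinds:
                    res = classify.run_group_model(
                        standardized,
                        test_subject,
                        kind,
                        model_seed=seed,
                        training_subjects=train_subjects,
                    )
                    rows.append(
                        {
                            "size": size,
                            "repeat": repeat,
                            "test_subject": test_subject,
                            "model": kind,
                            "auc": res.auc,
                            "accuracy": res.accuracy,
                        }
                    )
    return pd.DataFrame(rows)


def mean_auc_by_size(sweep: pd.DataFrame) -> pd.DataFrame:
    return sweep.groupby(["model", "size"], as_index=False)["auc"].mean()


def window_length_sweep(
    processed: dict[tuple[str, str], ProcessedRecording],
    lengths: Sequence[float] = DEFAULT_LENGTHS,
    model_kinds: Sequence[classify.ModelKind] = ("sv",),
    seed: int = 0,
) -> pd.DataFrame:
    """Group leave-one-subject-out AUC per feature window length.

    Features are re-extracted from the processed channels at each
    length; the activity filter is disabled, states are balanced and
    standardized as usual.
    """
    selection = SelectionConfig(activity_filter_enabled=False)
    rows = []
    for length in lengths:
        windows = {key: extract_features(rec, length) for key, rec in processed.items()}
        standardized = select_and_standardize(windows, processed, selection)
        for test_subject in sorted(standardized["subject_id"].unique()):
            for kind in model_kinds:
                res = classify.run_group_model(
                    standardized, test_subject, kind, model_seed=seed
                )
                rows.append(
                    {
                        "length_s": length,
                        "test_subject": test_subject,
                        "model": kind,
                        "auc": res.auc,
                        "accuracy": res.accuracy,
                    }
                )
    return pd.DataFrame(rows)


def equality_comparison(
    auc_a: Sequence[float],
    auc_b: Sequence[float],
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[int, float]:
    """Paired model comparison on an equality plot.

    ``k_above`` counts subjects where model A strictly beats model B
    (ties count as not-above).  The null scatters each subject's dot
    above the equality line independently with probability 1/2; the
    returned p is the fraction of ``n_perm`` permutation draws whose
    count reaches ``k_above`` (a Monte-Carlo binomial tail).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired AUC vectors must have equal length")
    k_above = int(np.sum(a > b))
    rng = np.random.default_rng(seed)
    counts = rng.binomial(a.size, 0.5, size=n_perm)
    p = float(np.mean(counts >= k_above))
    return k_above, p
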
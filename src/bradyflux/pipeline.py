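"""End-to-end orchestration: cohort -> channels -> features -> models."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from bradyflux import classify
from bradyflux.cohort import Cohort, SimulationConfig, simulate_cohort
from bradyflux.features import extract_features
from bradyflux.preprocess import PreprocessConfig, ProcessedRecording, preprocess_recording
from bradyflux.selection import SelectionConfig, select_and_standardize


def preprocess_cohort(
    cohort: Cohort, config: PreprocessConfig | None = None
) -> dict[tuple[str, str], ProcessedRecording]:
    """Preprocess every session; keyed by (subject_id, state)."""
    config = config or PreprocessConfig()
    out = {}
    for pre, post in cohort.recordings:
        for raw in (pre, post):
            out[(raw.subject_id, raw.state)] = preprocess_recording(raw, config)
    return out


def feature_table(
    processed: dict[tuple[str, str], ProcessedRecording],
    window_s: float = 60.0,
    selection: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Windowed features for a whole cohort: extraction, activity
    filtering, balancing and pre-medication standardization."""
    windows = {key: extract_features(rec, window_s) for key, rec in processed.items()}
    return select_and_standardize(windows, processed, selection)


def classify_cohort(
    standardized: pd.DataFrame,
    model_kinds: Sequence[classify.ModelKind] = ("sv", "rf"),
    modes: Sequence[str] = ("individual", "group"),
    n_perm: int = 0,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[classify.ModelResult]:
    """Individual and/or group models for every subject, with optional
    permutation significance and cohort-level FDR correction."""
    subjects = sorted(standardized["subject_id"].unique())
    results: list[classify.ModelResult] = []
    for kind in model_kinds:
        if "individual" in modes:
            batch = []
            for j, sid in enumerate(subjects):
                sub = standardized[standardized["subject_id"] == sid]
                res = classify.run_individual_model(sub, kind, model_seed=seed)
                if n_perm:
                    res = classify.individual_significance(
                        sub, res, n_perm=n_perm, seed=seed + 101 * j + 1
                    )
                batch.append(res)
            if n_perm:
                batch = classify.significance_across_subjects(batch, alpha=alpha)
            results.extend(batch)
        if "group" in modes:
            batch = []
            for j, sid in enumerate(subjects):
                res = classify.run_group_model(standardized, sid, kind, model_seed=seed)
                if n_perm:
                    res = classify.group_significance(
                        res, n_perm=n_perm, seed=seed + 131 * j + 7
                    )
                batch.append(res)
            if n_perm:
                batch = classify.significance_across_subjects(batch, alpha=alpha)
            results.extend(batch)
    return results


def run_default_analysis(
    sim_config: SimulationConfig,
    window_s: float = 60.0,
    model_kinds: Sequence[classify.ModelKind] = ("sv",),
    modes: Sequence[str] = ("group",),
    n_perm: int = 0,
    seed: int = 0,
    preprocess_config: PreprocessConfig | None = None,
) -> tuple[Cohort, pd.DataFrame, list[classify.ModelResult]]:
    """Simulate, preprocess, extract and classify in one call."""
    cohort = simulate_cohort(sim_config)
    processed = preprocess_cohort(cohort, preprocess_config)
    table = feature_table(processed, window_s=window_s)
    results = classify_cohort(
        table, model_kinds=model_kinds, modes=modes, n_perm=n_perm, seed=seed
    )
    return cohort, table, results
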
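"""CSV readers/writers and run manifests.

CSV is the interchange dialect throughout.  Session files have columns
``t,ax,ay,az`` (seconds, m/s^2); processed files ``t,x,y,z,svm,svm_raw``.  Every
file written here starts with a comment line carrying the configuration
hash and seed of the run that produced it; readers skip ``#`` lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from bradyflux.cohort import ClinicalScores, Cohort, RawRecording, SimulationConfig
from bradyflux.preprocess import ProcessedRecording


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    if dataclasses.is_dataclass(config):
        payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    else:
        payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config, seed) -> str:
    return f"# bradyflux config_hash={config_hash(config)} seed={seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config, seed, float_format="%.6f") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config, seed))
        df.to_csv(fh, index=False, float_format=float_format)


def write_session(rec: RawRecording, path: Path, config, seed) -> None:
    df = pd.DataFrame({"t": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az})
    _write_csv(df, Path(path), config, seed, float_format="%.5f")


def read_session(path: Path, subject_id: str, state: str, fs: float) -> RawRecording:
    df = pd.read_csv(path, comment="#")
    missing = {"t", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return RawRecording(
        subject_id=subject_id,
        state=state,  # type: ignore[arg-type]
        fs=fs,
        t=df["t"].to_numpy(),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
    )


def write_processed(rec: ProcessedRecording, path: Path, config, seed) -> None:
    df = pd.DataFrame(
        {"t": rec.t, "x": rec.x, "y": rec.y, "z": rec.z, "svm": rec.svm, "svm_raw": rec.svm_raw}
    )
    _write_csv(df, Path(path), config, seed, float_format="%.5f")


def read_processed(path: Path, subject_id: str, state: str, fs: float) -> ProcessedRecording:
    df = pd.read_csv(path, comment="#")
    missing = {"t", "x", "y", "z", "svm", "svm_raw"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ProcessedRecording(
        subject_id=subject_id,
        state=state,  # type: ignore[arg-type]
        fs=fs,
        t=df["t"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        z=df["z"].to_numpy(),
        svm=df["svm"].to_numpy(),
        svm_raw=df["svm_raw"].to_numpy(),
        gravity_estimate=np.zeros((len(df), 3)),
    )


def write_scores(scores: list[ClinicalScores], path: Path, config, seed) -> None:
    df = pd.DataFrame([dataclasses.asdict(s) for s in scores])
    _write_csv(df, Path(path), config, seed)


def read_scores(path: Path) -> list[ClinicalScores]:
    df = pd.read_csv(path, comment="#")
    return [ClinicalScores(**row) for row in df.to_dict(orient="records")]


def write_manifest(config: SimulationConfig, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"config_hash {config_hash(config)}"]
    for field in dataclasses.fields(config):
        lines.append(f"{field.name} {getattr(config, field.name)}")
    path.write_text("\n".join(lines) + "\n")


def write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """One CSV per session plus clinical scores and a manifest."""
    out_dir = Path(out_dir)
    cfg, seed = cohort.config, cohort.config.seed
    for pre, post in cohort.recordings:
        for rec in (pre, post):
            write_session(rec, out_dir / "sessions" / f"{rec.subject_id}_{rec.state}.csv", cfg, seed)
    write_scores(cohort.scores, out_dir / "clinical_scores.csv", cfg, seed)
    write_manifest(cfg, out_dir / "manifest.txt")


def write_table(df: pd.DataFrame, path: Path, config, seed) -> None:
    """Feature or results table with the standard header comment."""
    _write_csv(df, Path(path), config, seed)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
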
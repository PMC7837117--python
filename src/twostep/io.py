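"""Readers and writers for session, neural, parameter and result formats.

All tabular data are tab-separated text with a header row; configurations and
parameter sets are YAML (``name: value``).  Result tables carry provenance
comment lines (``# key: value``) above the header.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .task import (CHOICE_LABELS, REWARD_LABELS, SECOND_STEP_LABELS,
                   TRANSITION_LABELS, Session, TaskConfig)

__all__ = [
    "write_sessions",
    "read_sessions",
    "write_params",
    "read_params",
    "write_neural_session",
    "read_neural_session",
    "write_table",
    "read_table",
    "config_hash",
]

_SESSION_COLUMNS = ("subject", "session", "trial", "choice", "second_step",
                    "outcome", "transition_state", "reward_state", "block", "stim")

_CHOICE_CODES = {v: k for k, v in CHOICE_LABELS.items()}
_SECOND_CODES = {v: k for k, v in SECOND_STEP_LABELS.items()}
_TRANSITION_CODES = {v: k for k, v in TRANSITION_LABELS.items()}
_REWARD_CODES = {v: k for k, v in REWARD_LABELS.items()}


def _session_frame(s: Session) -> pd.DataFrame:
    df = pd.DataFrame({
        "subject": s.subject_id,
        "session": s.session_id,
        "trial": np.arange(s.n_trials),
        "choice": [CHOICE_LABELS[int(c)] for c in s.choice],
        "second_step": [SECOND_STEP_LABELS[int(x)] for x in s.second_step],
        "outcome": s.outcome.astype(int),
        "transition_state": [TRANSITION_LABELS[int(x)] for x in s.transition_state],
        "reward_state": [REWARD_LABELS[int(x)] for x in s.reward_state],
        "block": s.block_index.astype(int),
    })
    if s.stim is not None:
        df["stim"] = s.stim.astype(int)
    return df


def write_sessions(sessions: Sequence[Session], path: str | Path) -> Path:
    """Write sessions as one row per trial.

    A ``.tsv`` path gets a single concatenated file; any other path is
    treated as a directory with one file per session.  The ``stim`` column is
    written only when stimulation flags exist.
    """
    path = Path(path)
    frames = [_session_frame(s) for s in sessions]
    if path.suffix == ".tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for s, df in zip(sessions, frames):
            df.to_csv(path / f"{s.subject_id}_{s.session_id}.tsv", sep="\t", index=False)
    return path


def _decode_column(df, col, codes, fname):
    values = df[col]
    bad = ~values.isin(list(codes))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{fname}: row {row + 2}: invalid {col} value {values.iloc[row]!r} "
            f"(expected one of {sorted(codes)})")
    return values.map(codes).to_numpy()


def _read_session_file(path: Path, config: Optional[TaskConfig]) -> list[Session]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _SESSION_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    has_stim = "stim" in df.columns
    out = []
    for (subj, ses), g in df.groupby(["subject", "session"], sort=False):
        fname = path.name
        choice = _decode_column(g, "choice", _CHOICE_CODES, fname)
        second = _decode_column(g, "second_step", _SECOND_CODES, fname)
        outcome = _decode_column(g, "outcome", {"0": 0, "1": 1}, fname)
        ts = _decode_column(g, "transition_state", _TRANSITION_CODES, fname)
        rs = _decode_column(g, "reward_state", _REWARD_CODES, fname)
        block = g["block"].astype(int).to_numpy()
        stim = (_decode_column(g, "stim", {"0": 0, "1": 1}, fname)
                if has_stim else None)
        out.append(Session(
            choice=np.asarray(choice, dtype=np.int8),
            second_step=np.asarray(second, dtype=np.int8),
            outcome=np.asarray(outcome, dtype=np.int8),
            transition_state=np.asarray(ts, dtype=np.int8),
            reward_state=np.asarray(rs, dtype=np.int8),
            block_index=np.asarray(block, dtype=np.int16),
            stim=None if stim is None else np.asarray(stim, dtype=np.int8),
            subject_id=str(subj), session_id=str(ses),
            config=config if config is not None else TaskConfig()))
    return out


def read_sessions(path: str | Path, config: Optional[TaskConfig] = None) -> list[Session]:
    """Read sessions from a ``.tsv`` file or a directory of them.

    Schema violations raise with the offending file, row and value.  A file
    without a ``stim`` column yields sessions with ``stim=None`` (optogenetic
    analyses then refuse to run on them).
    """
    path = Path(path)
    files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no .tsv session files under {path}")
    sessions: list[Session] = []
    for f in files:
        sessions.extend(_read_session_file(f, config))
    return sessions


def write_params(params: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump({k: float(v) for k, v in params.items()},
                                   sort_keys=False))
    return path


def read_params(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of name: value")
    return {str(k): float(v) for k, v in data.items()}


def write_neural_session(ns, path: str | Path, prefix: str = "neural") -> Path:
    """Write one neural session as an activity matrix (neurons x frames) and
    a trial-events table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / f"{prefix}_activity.tsv", ns.activity, delimiter="\t", fmt="%.6g")
    pd.DataFrame({
        "trial": np.arange(ns.n_trials),
        "choice_time_s": ns.choice_times,
        "outcome_time_s": ns.outcome_times,
    }).to_csv(path / f"{prefix}_events.tsv", sep="\t", index=False)
    return path


def read_neural_session(path: str | Path, behavior: Session,
                        prefix: str = "neural", frame_rate: float = 10.0):
    from .neural import NeuralSession

    path = Path(path)
    activity = np.loadtxt(path / f"{prefix}_activity.tsv", delimiter="\t", ndmin=2)
    events = pd.read_csv(path / f"{prefix}_events.tsv", sep="\t")
    return NeuralSession(activity=activity,
                         choice_times=events["choice_time_s"].to_numpy(),
                         outcome_times=events["outcome_time_s"].to_numpy(),
                         behavior=behavior, frame_rate=frame_rate)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping (for provenance headers)."""
    text = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict) -> Path:
    """Write a result table with ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a result table, returning (frame, provenance dict)."""
    prov = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            prov[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, prov
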
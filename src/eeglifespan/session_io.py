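"""Session and manifest I/O for 4-channel headband EEG stored as CSV.

On-disk layout: one CSV per recording with columns
``sample_index,TP9,AF7,AF8,TP10`` (samples in microvolts), plus a cohort
manifest CSV with one row per recording
(``user_id,session_id,order,task,age,sex,line_freq,path``).

Channel order is normalized to (TP9, AF7, AF8, TP10) regardless of the
column order in the file; unknown extra columns are tolerated with a
warning. Users younger than 18 years, or with a missing age, are excluded
at manifest-read time and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("TP9", "AF7", "AF8", "TP10")
TASKS = ("CAL", "NFB")
MANIFEST_COLUMNS = (
    "user_id",
    "session_id",
    "order",
    "task",
    "age",
    "sex",
    "line_freq",
    "path",
)

DEFAULT_FS = 220.0
MIN_AGE = 18


@dataclass(frozen=True)
class SubjectProfile:
    """One cohort member: demographics plus recording context."""

    user_id: str
    age: int
    sex: int  # male = 0, female = 1
    line_freq: int  # 50 or 60 Hz mains
    n_sessions: int = 1

    def __post_init__(self) -> None:
        if self.age < MIN_AGE:
            raise ValueError(f"age must be >= {MIN_AGE}, got {self.age}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (male) or 1 (female), got {self.sex}")
        if self.line_freq not in (50, 60):
            raise ValueError(f"line_freq must be 50 or 60, got {self.line_freq}")


@dataclass
class RawSession:
    """One raw recording: channel-major sample array in microvolts.

    ``samples`` has shape (4, n) in the canonical channel order
    (TP9, AF7, AF8, TP10).
    """

    samples: np.ndarray
    fs: float
    task: str
    order: int
    line_freq: int | None
    user: SubjectProfile
    session_id: str = ""
    artifact_truth: np.ndarray | None = None  # ground-truth contaminated 256-sample windows

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNELS):
            raise ValueError(
                f"samples must be (4, n) in order {CHANNELS}, got {self.samples.shape}"
            )
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if not self.session_id:
            self.session_id = f"{self.user.user_id}-{self.order:03d}-{self.task}"

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ManifestEntry:
    user_id: str
    session_id: str
    order: int
    task: str
    path: Path


@dataclass
class CohortManifest:
    """Validated manifest: per-user profiles with their session entries."""

    users: list[tuple[SubjectProfile, list[ManifestEntry]]]
    n_excluded_underage: int = 0
    fs: float = DEFAULT_FS
    base_dir: Path = field(default_factory=Path)

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_sessions(self) -> int:
        return sum(len(entries) for _, entries in self.users)


def read_manifest(path: str | Path, fs: float = DEFAULT_FS) -> CohortManifest:
    """Read and validate a cohort manifest.

    Entries are grouped by user and ordered by session order. Users whose
    age is missing or below 18 are excluded and counted in
    ``n_excluded_underage``. Duplicate (user_id, session_id) pairs and
    unknown sex / line-frequency / task codes are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"user_id": str, "session_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"manifest {path} is empty", stacklevel=2)
        return CohortManifest(users=[], fs=fs, base_dir=path.parent)

    dup = df.duplicated(subset=["user_id", "session_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"duplicate (user_id, session_id) in manifest at line {row + 2}: "
            f"{df.iloc[row]['user_id']}/{df.iloc[row]['session_id']}"
        )
    for col, allowed in (("sex", {0, 1}), ("line_freq", {50, 60})):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"manifest line {row + 2}: invalid {col} code {df.iloc[row][col]!r}"
            )
    bad_task = ~df["task"].isin(TASKS)
    if bad_task.any():
        row = int(np.flatnonzero(bad_task.to_numpy())[0])
        raise ValueError(f"manifest line {row + 2}: unknown task {df.iloc[row]['task']!r}")

    underage = df["age"].isna() | (df["age"] < MIN_AGE)
    n_excluded = int(df.loc[underage, "user_id"].nunique())
    df = df.loc[~underage]

    users: list[tuple[SubjectProfile, list[ManifestEntry]]] = []
    for user_id, grp in df.groupby("user_id", sort=True):
        grp = grp.sort_values("order")
        first = grp.iloc[0]
        profile = SubjectProfile(
            user_id=str(user_id),
            age=int(first["age"]),
            sex=int(first["sex"]),
            line_freq=int(first["line_freq"]),
            n_sessions=int(grp["order"].nunique()),
        )
        entries = [
            ManifestEntry(
                user_id=str(user_id),
                session_id=str(r["session_id"]),
                order=int(r["order"]),
                task=str(r["task"]),
                path=Path(r["path"]),
            )
            for _, r in grp.iterrows()
        ]
        users.append((profile, entries))
    return CohortManifest(
        users=users, n_excluded_underage=n_excluded, fs=fs, base_dir=path.parent
    )


def read_session(
    entry: ManifestEntry,
    profile: SubjectProfile,
    base_dir: str | Path = ".",
    fs: float = DEFAULT_FS,
) -> RawSession:
    """Read one session CSV into a RawSession.

    The four channel columns may appear in any order in the file; extra
    columns are ignored with a warning. NaN or non-numeric samples are an
    error naming the offending row.
    """
    csv_path = Path(base_dir) / entry.path
    if not csv_path.exists():
        raise FileNotFoundError(
            f"session {entry.session_id}: data file not found: {csv_path}"
        )
    df = pd.read_csv(csv_path)
    missing = set(CHANNELS) - set(df.columns)
    if missing:
        raise ValueError(
            f"session {entry.session_id}: missing channel columns {sorted(missing)}"
        )
    extra = set(df.columns) - set(CHANNELS) - {"sample_index"}
    if extra:
        warnings.warn(
            f"session {entry.session_id}: ignoring extra columns {sorted(extra)}",
            stacklevel=2,
        )
    data = df.loc[:, list(CHANNELS)].apply(pd.to_numeric, errors="coerce")
    bad = data.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"session {entry.session_id}: non-numeric or missing sample at row {row}"
        )
    return RawSession(
        samples=data.to_numpy().T,
        fs=fs,
        task=entry.task,
        order=entry.order,
        line_freq=profile.line_freq,
        user=profile,
        session_id=entry.session_id,
    )


def write_session_csv(session: RawSession, path: str | Path, decimals: int = 4) -> None:
    """Write one session to CSV (µV, fixed decimal precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"sample_index": np.arange(session.n_samples)}
        | {ch: session.samples[i] for i, ch in enumerate(CHANNELS)}
    )
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")
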
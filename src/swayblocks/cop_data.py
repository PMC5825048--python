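"""Data model and CSV I/O for center-of-pressure (CoP) recordings and cohorts.

A statokinesigram is the 2-D trajectory of the CoP under a subject standing on
a force platform: x is the medio-lateral (ML, side-to-side) displacement, y the
antero-posterior (AP, front-back) displacement, both in centimetres.  Each
subject is recorded under two conditions, eyes open (EO) and eyes closed (EC),
and carries a binary faller / non-faller label from a fall questionnaire
(faller = at least one unintentional fall to a lower level in the previous six
months).

On-disk conventions
-------------------
Trajectory CSV: header ``time_s,x_cm,y_cm``, UTF-8, '.' decimal separator.
Manifest CSV: header ``subject_id,label,eo_path,ec_path``; trajectory paths are
relative to the manifest's directory; an empty path marks a missing condition.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ValidationError

TRAJECTORY_COLUMNS = ["time_s", "x_cm", "y_cm"]
MANIFEST_COLUMNS = ["subject_id", "label", "eo_path", "ec_path"]
SCORE_COLUMNS = [
    "subject_id",
    "label",
    "eo_score",
    "ec_score",
    "global_score",
    "ub_fraction_ec",
]


class Condition(str, enum.Enum):
    """Acquisition condition: eyes open or eyes closed."""

    EO = "EO"
    EC = "EC"


class Label(str, enum.Enum):
    """Subject class from the fall questionnaire."""

    FALLER = "faller"
    NON_FALLER = "non_faller"


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclasses.dataclass
class RawTrajectory:
    """CoP positions as acquired: possibly irregular, strictly increasing times.

    Attributes
    ----------
    times : array of sample times in seconds, strictly increasing.
    x, y : ML and AP positions in cm, same length as ``times``.
    condition : acquisition condition (EO/EC).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    condition: Condition

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.condition = Condition(self.condition)
        n = len(self.times)
        if not (n == len(self.x) == len(self.y)):
            raise ValidationError("times, x and y must have equal length")
        if n < 2:
            raise InsufficientDataError("a trajectory needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        """Recording span in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclasses.dataclass
class Statokinesigram:
    """Uniformly resampled CoP trajectory on an implicit grid at ``rate`` Hz."""

    rate: float
    x: np.ndarray
    y: np.ndarray
    condition: Condition

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        self.condition = Condition(self.condition)
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if len(self.x) != len(self.y):
            raise ValidationError("x and y must have equal length")
        if len(self.x) < 2:
            raise InsufficientDataError("a statokinesigram needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Grid span (n - 1) / rate in seconds."""
        return (len(self.x) - 1) / self.rate


Trajectory = Union[RawTrajectory, Statokinesigram]


@dataclasses.dataclass
class SubjectRecord:
    """One subject: id, faller label, and up to two condition recordings."""

    subject_id: str
    label: Label
    eo: Optional[Trajectory] = None
    ec: Optional[Trajectory] = None

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        if self.eo is None and self.ec is None:
            raise ValidationError(
                f"subject {self.subject_id!r} has neither condition recorded"
            )

    def get(self, condition: Condition) -> Optional[Trajectory]:
        return self.eo if Condition(condition) is Condition.EO else self.ec


@dataclasses.dataclass
class Cohort:
    """Ordered collection of subjects with unique ids."""

    subjects: list

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def ids(self) -> list:
        return [s.subject_id for s in self.subjects]

    def ids_by_label(self, label: Label) -> list:
        return [s.subject_id for s in self.subjects if s.label is Label(label)]

    @property
    def prevalence(self) -> float:
        """Fraction of fallers among all subjects."""
        n_fall = len(self.ids_by_label(Label.FALLER))
        return n_fall / len(self.subjects)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_trajectory(path, condition: Condition) -> RawTrajectory:
    """Read a trajectory CSV (``time_s,x_cm,y_cm``) into a :class:`RawTrajectory`."""
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read trajectory file {path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(frame) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 samples")
    return RawTrajectory(
        times=frame["time_s"].to_numpy(float),
        x=frame["x_cm"].to_numpy(float),
        y=frame["y_cm"].to_numpy(float),
        condition=condition,
    )


def write_trajectory(traj: RawTrajectory, path) -> None:
    """Write a trajectory to CSV with full float precision (round-trip safe)."""
    frame = pd.DataFrame(
        {"time_s": traj.times, "x_cm": traj.x, "y_cm": traj.y}
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def _parse_label(raw: str, subject_id: str) -> Label:
    text = str(raw).strip().lower()
    try:
        return Label(text)
    except ValueError:
        raise ValidationError(
            f"subject {subject_id!r}: label {raw!r} not in "
            f"{{'faller', 'non_faller'}}"
        ) from None


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort manifest and every referenced trajectory file.

    Paths in the manifest are resolved relative to the manifest's directory.
    An empty (or missing) path marks an absent condition; a subject must have
    at least one condition.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read manifest {manifest_path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"{manifest_path}: missing columns {missing}")
    if manifest["subject_id"].duplicated().any():
        dupes = sorted(manifest.loc[manifest["subject_id"].duplicated(), "subject_id"])
        raise ValidationError(f"duplicate subject_id in manifest: {dupes}")

    base = manifest_path.parent
    subjects = []
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        label = _parse_label(row.label, sid)
        trajs: dict = {}
        for cond, rel in ((Condition.EO, row.eo_path), (Condition.EC, row.ec_path)):
            rel = str(rel).strip()
            if not rel:
                trajs[cond] = None
                continue
            try:
                trajs[cond] = read_trajectory(base / rel, cond)
            except OSError as exc:
                raise IOError(
                    f"subject {sid!r}: cannot read {cond.value} trajectory "
                    f"{base / rel}: {exc}"
                ) from exc
        if trajs[Condition.EO] is None and trajs[Condition.EC] is None:
            raise ValidationError(f"subject {sid!r}: both condition paths empty")
        subjects.append(
            SubjectRecord(sid, label, eo=trajs[Condition.EO], ec=trajs[Condition.EC])
        )
    return Cohort(subjects)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write trajectory CSVs plus a manifest under ``out_dir``.

    Returns the manifest path.  Trajectory files are named
    ``<subject_id>_<condition>.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in cohort:
        paths = {}
        for cond in (Condition.EO, Condition.EC):
            traj = subject.get(cond)
            if traj is None:
                paths[cond] = ""
                continue
            name = f"{subject.subject_id}_{cond.value}.csv"
            write_trajectory(traj, out_dir / name)
            paths[cond] = name
        rows.append(
            {
                "subject_id": subject.subject_id,
                "label": subject.label.value,
                "eo_path": paths[Condition.EO],
                "ec_path": paths[Condition.EC],
            }
        )
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, index=False, lineterminator="\n"
    )
    return manifest_path


def write_scores(cohort_scores: pd.DataFrame, path) -> None:
    """Write the per-subject score table with the canonical column set."""
    missing = [c for c in SCORE_COLUMNS if c not in cohort_scores.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    cohort_scores[SCORE_COLUMNS].to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )
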
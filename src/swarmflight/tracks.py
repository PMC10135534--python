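"""Data model and I/O for 3D flight tracks, trials and datasets.

A *track* is an ordered sequence of 3D positions (metres) with timestamps
(seconds) for one tracked individual — or one mating couple tracked as a
single entity.  Tracks are grouped into *trials* (recording sessions), each
carrying a class label per track: swarming ``male``, ``female``, ``focal_male``
(a male pursuing a female he later mates with) or ``couple`` (a pair mating in
flight).  The canonical on-disk representation is a long-format CSV with one
row per sample: ``track_id,trial_id,label,t,x,y,z``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four known behavioural classes; anything else is mapped to "unknown"
#: and excluded from evaluation (open-world use of the one-class design).
KNOWN_LABELS = ("male", "female", "focal_male", "couple")

#: Expected binary outcome per class: males and focal males should fall inside
#: the one-class boundary, couples and females outside.
MALE_LIKE = frozenset({"male", "focal_male"})
NON_MALE = frozenset({"female", "couple"})

CSV_COLUMNS = ("track_id", "trial_id", "label", "t", "x", "y", "z")


class TrackValidationError(ValueError):
    """A track violates an invariant (non-monotone time, NaN coordinate...)."""


class FormatError(ValueError):
    """An input file does not follow the long-format CSV dialect."""


@dataclass
class Track:
    """One 3D trajectory: positions (N, 3) in metres, times (N,) in seconds."""

    track_id: str
    trial_id: str
    label: str
    positions: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.label not in KNOWN_LABELS:
            self.label = "unknown"
        self.validate()

    def validate(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrackValidationError(
                f"track {self.track_id!r}: positions must be (N, 3), "
                f"got {self.positions.shape}"
            )
        n = len(self.times)
        if n != len(self.positions) or n < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: need >= 2 samples with matching "
                f"positions/times lengths ({len(self.positions)} vs {n})"
            )
        if not np.all(np.isfinite(self.positions)) or not np.all(
            np.isfinite(self.times)
        ):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinate or time"
            )
        if np.any(np.diff(self.times) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: times must be strictly increasing"
            )

    @property
    def duration(self) -> float:
        """Track duration t_N - t_0 in seconds (windows are set in seconds)."""
        return float(self.times[-1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def displacement(self) -> float:
        """Straight-line distance between start and end position (metres)."""
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))

    def path_length(self) -> float:
        """Total distance travelled along the track (metres)."""
        steps = np.diff(self.positions, axis=0)
        return float(np.linalg.norm(steps, axis=1).sum())


@dataclass
class Trial:
    """One recording session (a swarm) contributing a set of tracks."""

    trial_id: str
    tracks: list[Track] = field(default_factory=list)
    date: str = ""
    notes: str = ""

    def labels(self) -> Counter:
        return Counter(t.label for t in self.tracks)


@dataclass
class Dataset:
    """A collection of trials with unique track ids across the dataset."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for trial in self.trials:
            for track in trial.tracks:
                if track.track_id in seen:
                    raise TrackValidationError(
                        f"duplicate track_id {track.track_id!r} in dataset"
                    )
                seen.add(track.track_id)
                if track.trial_id != trial.trial_id:
                    raise TrackValidationError(
                        f"track {track.track_id!r} carries trial_id "
                        f"{track.trial_id!r} but lives in trial "
                        f"{trial.trial_id!r}"
                    )

    def __iter__(self) -> Iterator[Track]:
        for trial in self.trials:
            yield from trial.tracks

    def __len__(self) -> int:
        return sum(len(trial.tracks) for trial in self.trials)

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    def trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def tracks_by_label(self, label: str) -> list[Track]:
        return [t for t in self if t.label == label]

    def trials_with_label(self, label: str) -> list[str]:
        """Sorted ids of trials containing at least one track of `label`."""
        return sorted(t.trial_id for t in self.trials if label in t.labels())

    def subset(self, trial_ids: Iterable[str]) -> "Dataset":
        wanted = set(trial_ids)
        return Dataset([t for t in self.trials if t.trial_id in wanted])


def _dataset_from_frame(df: pd.DataFrame) -> Dataset:
    trials: dict[str, Trial] = {}
    for (trial_id, track_id), group in df.groupby(
        ["trial_id", "track_id"], sort=True
    ):
        group = group.sort_values("t", kind="stable")
        t = group["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(
                f"track {track_id!r}: duplicated or non-monotone timestamps"
            )
        label = str(group["label"].iloc[0])
        track = Track(
            track_id=str(track_id),
            trial_id=str(trial_id),
            label=label,
            positions=group[["x", "y", "z"]].to_numpy(dtype=float),
            times=t,
        )
        trials.setdefault(str(trial_id), Trial(str(trial_id))).tracks.append(track)
    return Dataset([trials[k] for k in sorted(trials)])


def read_tracks(path: str | Path) -> Dataset:
    """Read a long-format track CSV into a :class:`Dataset`.

    The file must contain the columns ``track_id,trial_id,label,t,x,y,z``;
    rows are grouped by (trial_id, track_id) and ordered by t.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"track_id": str, "trial_id": str, "label": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df.empty:
        return Dataset([])
    return _dataset_from_frame(df)


def to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a Dataset to the long-format row-per-sample DataFrame."""
    parts = []
    for track in dataset:
        parts.append(
            pd.DataFrame(
                {
                    "track_id": track.track_id,
                    "trial_id": track.trial_id,
                    "label": track.label,
                    "t": track.times,
                    "x": track.positions[:, 0],
                    "y": track.positions[:, 1],
                    "z": track.positions[:, 2],
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_tracks(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as long-format CSV; inverse of :func:`read_tracks`.

    Floats are written with 17 significant digits so a round trip preserves
    every coordinate bit-for-bit.
    """
    to_frame(dataset).to_csv(Path(path), index=False, float_format="%.17g")


def filter_short_tracks(dataset: Dataset, window_s: float) -> Dataset:
    """Drop tracks shorter than twice the segment window.

    Keeping only tracks of duration >= 2 * window_s guarantees at least two
    segments per track, which the per-track vote requires.  Removal counts are
    logged per class.  Idempotent.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    removed: Counter = Counter()
    trials = []
    for trial in dataset.trials:
        kept = []
        for track in trial.tracks:
            if track.duration >= 2.0 * window_s:
                kept.append(track)
            else:
                removed[track.label] += 1
        if kept:
            trials.append(
                Trial(trial.trial_id, kept, date=trial.date, notes=trial.notes)
            )
    if removed:
        logger.info(
            "filter_short_tracks removed %d tracks (%s)",
            sum(removed.values()),
            dict(removed),
        )
    return Dataset(trials)
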
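"""Raw signal containers (EEG/EOG) and per-run class labels.

Recordings are plain time-major float arrays in microvolts with a uniform
sampling clock. On disk a recording is a CSV matrix (one column per channel)
next to a JSON sidecar holding the sampling rate, channel labels and, for a
labeled run, the class intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2", "EOG3", "EOG4")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``samples`` is time x channel, in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D time x channel array")
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[:, self.channel_labels.index(label)]


@dataclass
class EOGRecording:
    """Four-sensor EOG: right canthus, nasion, left canthus, forehead ref."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 4:
            raise ValueError("EOG recording must have exactly 4 channels")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class RunLabels:
    """Non-overlapping class intervals ``(start_s, end_s, class_name)``."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (s, e, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e:
                raise ValueError("label intervals overlap")
        for s, e, _ in ivs:
            if e <= s:
                raise ValueError("label interval has non-positive duration")
        self.intervals = ivs

    def label_at(self, start: float, end: float) -> str | None:
        """Class of the interval fully containing ``[start, end]``, else None."""
        for s, e, c in self.intervals:
            if s <= start and end <= e:
                return c
        return None

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c for _, _, c in self.intervals))


def save_run(
    directory: str | Path,
    eeg: EEGRecording,
    eog: EOGRecording | None = None,
    labels: RunLabels | None = None,
    float_fmt: str = "%.4f",
) -> Path:
    """Write a run to ``directory`` as eeg.csv (+ eog.csv) and meta.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    header = ",".join(eeg.channel_labels)
    np.savetxt(d / "eeg.csv", eeg.samples, delimiter=",", fmt=float_fmt,
               header=header, comments="")
    meta = {
        "sampling_rate": eeg.sampling_rate,
        "channel_labels": list(eeg.channel_labels),
        "start_time": eeg.start_time,
    }
    if eog is not None:
        np.savetxt(d / "eog.csv", eog.samples, delimiter=",", fmt=float_fmt,
                   header=",".join(EOG_CHANNELS), comments="")
    if labels is not None:
        meta["labels"] = [[s, e, c] for s, e, c in labels.intervals]
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    return d


def load_run(
    directory: str | Path,
) -> tuple[EEGRecording, EOGRecording | None, RunLabels | None]:
    """Inverse of :func:`save_run`."""
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    eeg = EEGRecording(
        samples=np.loadtxt(d / "eeg.csv", delimiter=",", skiprows=1, ndmin=2),
        sampling_rate=meta["sampling_rate"],
        channel_labels=tuple(meta["channel_labels"]),
        start_time=meta.get("start_time", 0.0),
    )
    eog = None
    if (d / "eog.csv").exists():
        eog = EOGRecording(
            samples=np.loadtxt(d / "eog.csv", delimiter=",", skiprows=1,
                               ndmin=2),
            sampling_rate=meta["sampling_rate"],
        )
    labels = None
    if "labels" in meta:
        labels = RunLabels([(s, e, c) for s, e, c in meta["labels"]])
    return eeg, eog, labels
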
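"""Frame-wise EOG artifact detection and decoder gating.

Four EOG sensors (right canthus, nasion, left canthus, forehead reference)
are combined into a horizontal channel EOGh = EOG1 - EOG3, a vertical
channel EOGv = EOG2 - (EOG1 + EOG3)/2, and the sensor average. All derived
channels are band-pass filtered 1-10 Hz with a causal second-order
Butterworth filter and rectified; each 62.5 ms frame decides 1 if any
processed sample exceeds a common threshold. A 0-to-1 frame transition
raises an artifact onset that blocks BCI output; the block is lifted a
configurable timeout after the latest onset, later onsets extending it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EOGRecording


@dataclass
class EogDerived:
    """Derived monitoring channels, same clock as the source EOG."""

    h: np.ndarray
    v: np.ndarray
    avg: np.ndarray
    sampling_rate: float


@dataclass
class ArtifactConfig:
    band_hz: tuple[float, float] = (1.0, 10.0)
    filter_order: int = 2
    threshold_uv: float = 25.0
    frame_s: float = 0.0625
    offset_timeout_s: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_uv <= 0:
            raise ValueError("threshold must be positive")
        if self.offset_timeout_s < self.frame_s:
            raise ValueError("offset timeout must be >= one frame")


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str  # "onset" | "offset"
    timestamp: float


def derive_eog_channels(eog: EOGRecording) -> EogDerived:
    """Horizontal, vertical and average monitoring channels.

    The average uses the three active sensors (EOG1..EOG3); the fourth
    sensor is the recording reference and carries no signal of its own.
    """
    s = eog.samples
    h = s[:, 0] - s[:, 2]
    v = s[:, 1] - (s[:, 0] + s[:, 2]) / 2.0
    avg = s[:, :3].mean(axis=1)
    return EogDerived(h, v, avg, eog.sampling_rate)


def detect_frames(derived: EogDerived, cfg: ArtifactConfig) -> np.ndarray:
    """Binary decision per complete 62.5 ms frame.

    The filter runs causally from zero initial state (the online system sees
    the stream from its start), so a brief settling transient at the very
    beginning of a recording is expected and documented.
    """
    fs = derived.sampling_rate
    frame_n = int(round(cfg.frame_s * fs))
    n_frames = len(derived.h) // frame_n
    if n_frames == 0:
        raise ValueError("signal shorter than one frame")
    sos = signal.butter(cfg.filter_order, cfg.band_hz, btype="bandpass",
                        fs=fs, output="sos")
    stack = np.stack([derived.h, derived.v, derived.avg], axis=1)
    rectified = np.abs(signal.sosfilt(sos, stack, axis=0))
    n = n_frames * frame_n
    frames = rectified[:n].reshape(n_frames, frame_n, 3)
    return (frames > cfg.threshold_uv).any(axis=(1, 2))


def frames_to_events(
    decisions: np.ndarray, cfg: ArtifactConfig
) -> list[ArtifactEvent]:
    """Onset/offset events from the frame decision sequence.

    An onset is a 0-to-1 transition (a leading 1 counts, the stream starts
    unblocked); every onset detection restarts the offset timeout, so
    overlapping blocks merge into one [onset, offset) interval.
    """
    d = np.asarray(decisions).astype(bool)
    prev = np.concatenate(([False], d[:-1]))
    onset_times = np.flatnonzero(d & ~prev) * cfg.frame_s
    events: list[ArtifactEvent] = []
    block_end: float | None = None
    for t in onset_times:
        if block_end is None or t >= block_end:
            if block_end is not None:
                events.append(ArtifactEvent("offset", block_end))
            events.append(ArtifactEvent("onset", float(t)))
        block_end = float(t) + cfg.offset_timeout_s
    if block_end is not None:
        events.append(ArtifactEvent("offset", block_end))
    return events


def gated_intervals(events: list[ArtifactEvent]) -> list[tuple[float, float]]:
    """Half-open [onset, offset) blocking intervals from an event list."""
    out = []
    onset = None
    for ev in events:
        if ev.kind == "onset":
            onset = ev.timestamp
        elif onset is not None:
            out.append((onset, ev.timestamp))
            onset = None
    return out


def artifact_gate(
    eog: EOGRecording, cfg: ArtifactConfig | None = None
) -> tuple[list[ArtifactEvent], list[tuple[float, float]]]:
    """Full detection chain: derive, filter, frame, and emit events."""
    cfg = cfg or ArtifactConfig()
    frames = detect_frames(derive_eog_channels(eog), cfg)
    events = frames_to_events(frames, cfg)
    return events, gated_intervals(events)
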
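"""Spatiospectral features: Laplacian filtering, sliding Welch band power,
Fisher-score discriminancy and CVA feature ranking.

The feature space follows the online decoder's conventions: power spectral
density per channel at 2 Hz resolution, estimated with a Welch periodogram
(0.5 s Hann sub-segments, 50% overlap) over 1 s windows sliding every
62.5 ms. Features are log10 band powers by default; a "band" labeled f Hz is
the 2 Hz-wide bin centered at f, and a spectral region [lo, hi] comprises the
bins with lo <= center <= hi inclusive (so beta 22-32 Hz has six bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import montage
from .recording import EEGRecording, RunLabels

DEFAULT_WINDOW_S = 1.0
DEFAULT_STEP_S = 0.0625
DEFAULT_RESOLUTION_HZ = 2.0
#: Default band centers (Hz) retained as candidate features.
DEFAULT_BANDS: tuple[float, ...] = tuple(float(f) for f in range(4, 50, 2))


@dataclass
class FeatureMatrix:
    """Windows x features band-power matrix with feature bookkeeping."""

    values: np.ndarray
    window_times: np.ndarray  # window end times, s
    feature_index: list[tuple[str, float]]  # (channel, band center Hz)
    labels: np.ndarray | None = None  # per-window class or None
    log: bool = True
    window_s: float = DEFAULT_WINDOW_S
    step_s: float = DEFAULT_STEP_S

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_index):
            raise ValueError("feature_index does not match value columns")
        if not self.log and np.any(self.values < 0):
            raise ValueError("raw band powers must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(ch for ch, _ in self.feature_index))

    @property
    def bands(self) -> tuple[float, ...]:
        return tuple(dict.fromkeys(b for _, b in self.feature_index))

    def column(self, channel: str, band: float) -> np.ndarray:
        return self.values[:, self.feature_index.index((channel, band))]

    def select(self, features: list[tuple[str, float]]) -> np.ndarray:
        """Column submatrix for the given (channel, band) features."""
        idx = [self.feature_index.index(f) for f in features]
        return self.values[:, idx]

    def class_rows(self, klass: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        return self.values[self.labels == klass]

    def to_frame(self):
        """One row per window; columns ``<channel>_<band>`` plus time/label."""
        import pandas as pd

        cols = {f"{ch}_{band:g}": self.values[:, i]
                for i, (ch, band) in enumerate(self.feature_index)}
        df = pd.DataFrame(cols)
        df.insert(0, "time", self.window_times)
        if self.labels is not None:
            df["label"] = self.labels
        return df


def laplacian_filter(
    eeg: EEGRecording, lap_map: dict[str, tuple[str, ...]] | None = None
) -> EEGRecording:
    """Surface-Laplacian spatial filter: out[c] = in[c] - mean(neighbors).

    Channels with an empty neighbor list pass through unchanged. The default
    map uses orthogonal nearest neighbors on the sensorimotor grid.
    """
    if lap_map is None:
        lap_map = montage.default_laplacian_map(eeg.channel_labels)
    montage.validate_laplacian_map(lap_map, eeg.channel_labels)
    out = eeg.samples.copy()
    for ch, neigh in lap_map.items():
        if not neigh:
            continue
        ci = eeg.channel_labels.index(ch)
        ni = [eeg.channel_labels.index(n) for n in neigh]
        out[:, ci] = eeg.samples[:, ci] - eeg.samples[:, ni].mean(axis=1)
    return EEGRecording(out, eeg.sampling_rate, eeg.channel_labels,
                        eeg.start_time)


def n_windows(n_samples: int, fs: float,
              window_s: float = DEFAULT_WINDOW_S,
              step_s: float = DEFAULT_STEP_S) -> int:
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if n_samples < win:
        return 0
    return (n_samples - win) // step + 1


def _hann_segment_psd(x: np.ndarray, nperseg: int, fs: float) -> np.ndarray:
    """One-sided Hann periodogram density of each row segment of ``x``."""
    win = np.hanning(nperseg + 1)[:-1]  # periodic Hann, as in Welch
    spec = np.fft.rfft(x * win, axis=-1)
    scale = 1.0 / (fs * np.sum(win**2))
    psd = (np.abs(spec) ** 2) * scale
    psd[..., 1:-1] *= 2.0
    return psd


def welch_band_power(
    eeg: EEGRecording,
    window_s: float = DEFAULT_WINDOW_S,
    step_s: float = DEFAULT_STEP_S,
    resolution_hz: float = DEFAULT_RESOLUTION_HZ,
    bands: tuple[float, ...] = DEFAULT_BANDS,
    labels: RunLabels | None = None,
    log: bool = True,
) -> FeatureMatrix:
    """Sliding-window Welch band power for every (channel, band) feature.

    Each window of ``window_s`` seconds is split into half-window Hann
    sub-segments with 50% overlap whose periodograms are averaged, giving
    exactly ``resolution_hz`` bin spacing. Windows shorter than the recording
    yield ``floor((T - window_s)/step_s) + 1`` rows; a too-short recording
    returns an empty matrix with a warning.

    If ``labels`` is given, a window is labeled with the class whose interval
    fully contains it, else None.
    """
    fs = eeg.sampling_rate
    win_n = int(round(window_s * fs))
    step_n = int(round(step_s * fs))
    nperseg = int(round(fs / resolution_hz))
    if nperseg > win_n:
        raise ValueError("resolution too fine for the window length")
    nw = n_windows(eeg.n_samples, fs, window_s, step_s)
    nch = len(eeg.channel_labels)
    feature_index = [(ch, float(b)) for ch in eeg.channel_labels
                     for b in bands]
    if nw == 0:
        warnings.warn("recording shorter than one window; empty features")
        return FeatureMatrix(
            np.zeros((0, len(feature_index))), np.zeros(0), feature_index,
            labels=None, log=log, window_s=window_s, step_s=step_s,
        )

    bins = np.asarray([int(round(b / resolution_hz)) for b in bands])
    if np.any(bins > nperseg // 2) or np.any(
        np.abs(bins * resolution_hz - np.asarray(bands)) > 1e-9
    ):
        raise ValueError("band centers must sit on the resolution grid")

    hop = nperseg // 2
    n_sub = (win_n - nperseg) // hop + 1
    power = np.empty((nw, nch, len(bands)))
    if hop % step_n == 0:
        # Fast path: every sub-segment start lies on the step grid, so the
        # segment periodograms are shared between overlapping windows.
        x = eeg.samples.T  # channel x time
        n_seg = (eeg.n_samples - nperseg) // step_n + 1
        starts = np.arange(n_seg) * step_n
        segs = np.lib.stride_tricks.sliding_window_view(
            x, nperseg, axis=1)[:, starts, :]
        psd = _hann_segment_psd(segs, nperseg, fs)[..., bins]
        stride = hop // step_n
        acc = np.zeros((nw, nch, len(bands)))
        for j in range(n_sub):
            acc += psd[:, j * stride: j * stride + nw, :].transpose(1, 0, 2)
        power = acc / n_sub
    else:
        for w in range(nw):
            seg0 = w * step_n
            rows = np.stack([
                eeg.samples[seg0 + j * hop: seg0 + j * hop + nperseg, :].T
                for j in range(n_sub)
            ])  # n_sub x nch x nperseg
            psd = _hann_segment_psd(rows, nperseg, fs)[..., bins]
            power[w] = psd.mean(axis=0)

    values = power.reshape(nw, nch * len(bands))
    if log:
        values = np.log10(np.maximum(values, 1e-300))
    t_start = np.arange(nw) * step_n / fs
    window_times = t_start + win_n / fs
    lab = None
    if labels is not None:
        lab = np.array(
            [labels.label_at(s + eeg.start_time, e + eeg.start_time)
             for s, e in zip(t_start, window_times)], dtype=object,
        )
    return FeatureMatrix(values, window_times, feature_index, labels=lab,
                         log=log, window_s=window_s, step_s=step_s)


def fisher_score(values_class1, values_class2) -> float:
    """Two-class separability FS = |mu1 - mu2| / sqrt(s1^2 + s2^2).

    Standard deviations use the n-1 (sample) convention. Degenerate inputs:
    zero spread with equal means gives 0; zero spread with distinct means
    gives +inf with a warning.
    """
    a = np.asarray(values_class1, dtype=float)
    b = np.asarray(values_class2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per class")
    denom = np.sqrt(a.var(ddof=1) + b.var(ddof=1))
    num = abs(a.mean() - b.mean())
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("zero within-class spread with distinct means")
        return float("inf")
    return float(num / denom)


@dataclass
class DiscriminancyMap:
    """Fisher score per (channel, band) for one class pair."""

    channels: tuple[str, ...]
    bands: tuple[float, ...]
    scores: np.ndarray  # channels x bands
    classes: tuple[str, str]
    n_windows: tuple[int, int]

    def score(self, channel: str, band: float) -> float:
        return float(
            self.scores[self.channels.index(channel),
                        self.bands.index(band)]
        )

    def argmax(self) -> tuple[str, float]:
        i, j = np.unravel_index(np.argmax(self.scores), self.scores.shape)
        return self.channels[i], self.bands[j]


def discriminancy_map(
    features: FeatureMatrix,
    classes: tuple[str, str] = ("both_hands", "both_feet"),
) -> DiscriminancyMap:
    """Per-feature Fisher scores between the two MI classes.

    Windows labeled with anything else (rest, None) are excluded.
    """
    if features.labels is None:
        raise ValueError("feature matrix has no labels")
    x1 = features.class_rows(classes[0])
    x2 = features.class_rows(classes[1])
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError(
            f"need >= 2 windows per class, got {len(x1)} and {len(x2)}"
        )
    channels = features.channels
    bands = features.bands
    # Cells absent from the feature index (non-grid layouts) stay NaN.
    scores = np.full((len(channels), len(bands)), np.nan)
    for k, (ch, band) in enumerate(features.feature_index):
        scores[channels.index(ch), bands.index(band)] = fisher_score(
            x1[:, k], x2[:, k]
        )
    return DiscriminancyMap(channels, bands, scores, classes,
                            (len(x1), len(x2)))


@dataclass(frozen=True)
class RegionSpec:
    """A topographic x spectral region for aggregate discriminancy."""

    name: str
    channels: tuple[str, ...]
    band: tuple[float, float]  # inclusive bounds on band centers, Hz


MEDIAL_MU = RegionSpec("medial_mu", montage.MEDIAL_CHANNELS, montage.MU_BAND)
MEDIAL_BETA = RegionSpec("medial_beta", montage.MEDIAL_CHANNELS,
                         montage.BETA_BAND)
LATERAL_MU = RegionSpec("lateral_mu", montage.LATERAL_CHANNELS,
                        montage.MU_BAND)
LATERAL_BETA = RegionSpec("lateral_beta", montage.LATERAL_CHANNELS,
                          montage.BETA_BAND)
STANDARD_REGIONS = (MEDIAL_MU, MEDIAL_BETA, LATERAL_MU, LATERAL_BETA)


def region_discriminancy(dmap: DiscriminancyMap, region: RegionSpec) -> float:
    """Arithmetic mean Fisher score over the region's (channel, band) cells."""
    lo, hi = region.band
    bsel = [b for b in dmap.bands if lo <= b <= hi]
    csel = [c for c in region.channels if c in dmap.channels]
    if not bsel or not csel:
        raise ValueError(f"region {region.name!r} is empty on this map")
    rows = [dmap.channels.index(c) for c in csel]
    cols = [dmap.bands.index(b) for b in bsel]
    return float(dmap.scores[np.ix_(rows, cols)].mean())


@dataclass
class CvaRanking:
    """Feature ranking by canonical discriminant power (two classes)."""

    order: np.ndarray  # feature indices, most discriminant first
    scores: np.ndarray  # discriminant power per feature (unsorted)
    regularized: bool

    def top(self, k: int) -> list[int]:
        return [int(i) for i in self.order[:k]]


def cva_rank_features(
    features: FeatureMatrix,
    classes: tuple[str, str] = ("both_hands", "both_feet"),
    shrinkage: float = 0.05,
) -> CvaRanking:
    """Rank features by discriminant power via canonical variate analysis.

    For two classes the canonical direction is the Fisher linear discriminant
    w = Sw^-1 (mu1 - mu2) with shrinkage-regularized within-class scatter
    Sw <- (1-lambda) Sw + lambda (tr Sw / d) I. Per-feature discriminant
    power is |w_i| * sqrt(Sw_ii) (the weight's contribution on the pooled
    within-class scale); for uncorrelated features this ordering agrees with
    the per-feature Fisher criterion. Ties are broken toward the lower
    feature index. ``regularized`` flags an ill-conditioned scatter that
    required extra shrinkage.
    """
    x1 = features.class_rows(classes[0])
    x2 = features.class_rows(classes[1])
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need >= 2 windows per class")
    d = features.values.shape[1]
    sw = (
        (len(x1) - 1) * np.cov(x1, rowvar=False, ddof=1).reshape(d, d)
        + (len(x2) - 1) * np.cov(x2, rowvar=False, ddof=1).reshape(d, d)
    ) / (len(x1) + len(x2) - 2)
    dmu = x1.mean(axis=0) - x2.mean(axis=0)

    regularized = False
    lam = shrinkage
    target = np.trace(sw) / d
    for _ in range(8):
        sw_reg = (1 - lam) * sw + lam * target * np.eye(d)
        try:
            c, low = linalg.cho_factor(sw_reg)
            w = linalg.cho_solve((c, low), dmu)
            break
        except linalg.LinAlgError:
            regularized = True
            lam = max(2 * lam, 1e-3)
    else:  # pragma: no cover - pathological input
        w = dmu / np.maximum(np.diag(sw), 1e-12)
        sw_reg = sw + target * np.eye(d)
    if lam > shrinkage:
        regularized = True
    power = np.abs(w) * np.sqrt(np.diag(sw_reg))
    order = np.argsort(-power, kind="stable")
    return CvaRanking(order=order, scores=power, regularized=regularized)
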
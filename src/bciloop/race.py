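"""Deterministic Brain Runners race mechanics.

The avatar crosses a sequence of pads; on each pad it is in one of three
regimes with a characteristic full-pad crossing time: *boost* after a
correct command (action pads only), *base* with no input, and *penalty*
after an erroneous command. Progress accrues piecewise linearly at
1/t_regime pad-fractions per second. A correct command (matching the pad's
color) boosts until the next pad or an overriding wrong command; any wrong
command — including any command at all on a white pad — starts a 4 s
penalty whose timer resets on further wrong commands and which ends at
expiry, at the next pad, or at an overriding correct command, whichever
comes first. Regimes reset to base at every pad entry.

With the standard per-pad times (action 2/11/19 s, white 5.5/19 s, start
5/13 s, end 3/10 s) the standard 18-pad track yields 54 s under ideal
input, 162 s with no input and 327 s under continuously erroneous input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

PENALTY_DURATION_S = 4.0
VALID_RACE_CAP_S = 240.0  # competition rule: slower races are invalid

ACTION_PAD_TYPES = ("cyan", "magenta", "yellow")
WHITE_PAD_TYPES = ("white", "start", "end")
PAD_TYPES = ACTION_PAD_TYPES + WHITE_PAD_TYPES

#: (t_boost, t_base, t_penalty) full-pad crossing times per type, seconds.
PAD_TIMES: dict[str, tuple[float | None, float, float]] = {
    "cyan": (2.0, 11.0, 19.0),
    "magenta": (2.0, 11.0, 19.0),
    "yellow": (2.0, 11.0, 19.0),
    "white": (None, 5.5, 19.0),
    "start": (None, 5.0, 13.0),
    "end": (None, 3.0, 10.0),
}

#: The command each action pad rewards; white pads reward silence.
COMMAND_FOR_PAD = {"cyan": "spin", "magenta": "jump", "yellow": "slide"}


@dataclass(frozen=True)
class PadSpec:
    type: str
    t_boost: float | None
    t_base: float
    t_penalty: float

    @classmethod
    def of(cls, pad_type: str) -> "PadSpec":
        if pad_type not in PAD_TIMES:
            raise ValueError(f"unknown pad type {pad_type!r}")
        tb, tn, tp = PAD_TIMES[pad_type]
        return cls(pad_type, tb, tn, tp)

    def __post_init__(self) -> None:
        if self.t_boost is not None and not (
            self.t_boost <= self.t_base <= self.t_penalty
        ):
            raise ValueError("require t_boost <= t_base <= t_penalty")

    def regime_time(self, regime: str) -> float:
        if regime == "boost":
            if self.t_boost is None:
                raise ValueError(f"{self.type} pads have no boost regime")
            return self.t_boost
        return self.t_base if regime == "base" else self.t_penalty


@dataclass(frozen=True)
class Track:
    """Standard race track: start white + 16 shuffled pads + end white."""

    pads: tuple[PadSpec, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pads) != 18:
            raise ValueError("standard track has exactly 18 pads")
        if self.pads[0].type != "start" or self.pads[-1].type != "end":
            raise ValueError("track must start and end on the special whites")
        mid = [p.type for p in self.pads[1:-1]]
        for t in ("cyan", "magenta", "yellow", "white"):
            if mid.count(t) != 4:
                raise ValueError(f"track needs exactly 4 {t} pads, "
                                 f"got {mid.count(t)}")


def generate_track(seed: int) -> Track:
    """Random standard track; the pad order is reproducible from the seed."""
    rng = np.random.default_rng(seed)
    mid = [t for t in ("cyan", "magenta", "yellow", "white") for _ in range(4)]
    order = rng.permutation(len(mid))
    pads = (
        (PadSpec.of("start"),)
        + tuple(PadSpec.of(mid[i]) for i in order)
        + (PadSpec.of("end"),)
    )
    return Track(pads, seed)


@dataclass(frozen=True)
class GameCommandLike:
    kind: str
    timestamp: float


@dataclass
class PadRecord:
    pad_type: str
    entry_time: float
    exit_time: float | None = None
    commands: list[tuple[float, str, bool]] = field(default_factory=list)

    @property
    def crossing_time(self) -> float:
        if self.exit_time is None:
            raise ValueError("pad not yet crossed")
        return self.exit_time - self.entry_time


@dataclass
class RaceResult:
    completion_time: float
    records: list[PadRecord]
    valid: bool

    @property
    def n_pads(self) -> int:
        return len(self.records)


class RaceEngine:
    """Incremental race state machine (the single mechanics implementation).

    ``advance_to(t)`` integrates progress up to wall time ``t``, handling
    penalty expiries and pad transitions; ``apply_command(kind)`` applies a
    command at the engine's current time. :func:`simulate_race` and the
    closed-loop pipeline both drive this engine.
    """

    def __init__(self, pads) -> None:
        if isinstance(pads, Track):
            pads = pads.pads
        self.pads: tuple[PadSpec, ...] = tuple(pads)
        self.t = 0.0
        self.pad_index = 0
        self.progress = 0.0
        self.regime = "base"
        self.penalty_until: float | None = None
        self.records = [PadRecord(self.pads[0].type, 0.0)]

    @property
    def finished(self) -> bool:
        return self.pad_index >= len(self.pads)

    @property
    def current_pad(self) -> PadSpec:
        return self.pads[self.pad_index]

    def _enter_next_pad(self) -> None:
        self.pad_index += 1
        self.progress = 0.0
        self.regime = "base"  # regimes do not persist across pads
        self.penalty_until = None
        if not self.finished:
            self.records.append(PadRecord(self.current_pad.type, self.t))

    def advance_to(self, t_target: float) -> None:
        while not self.finished and self.t < t_target - 1e-12:
            pad = self.current_pad
            t_regime = pad.regime_time(self.regime)
            boundary = t_target
            if self.regime == "penalty" and self.penalty_until < boundary:
                boundary = self.penalty_until
            exit_t = self.t + (1.0 - self.progress) * t_regime
            if exit_t <= boundary + 1e-12:
                self.t = exit_t
                self.records[-1].exit_time = exit_t
                self._enter_next_pad()
                continue
            self.progress += (boundary - self.t) / t_regime
            self.t = boundary
            if self.regime == "penalty" and self.t >= self.penalty_until:
                self.regime = "base"  # penalty expired mid-pad
                self.penalty_until = None
        self.t = max(self.t, t_target) if not self.finished else self.t

    def apply_command(self, kind: str) -> bool:
        """Apply a command at the current time; returns its correctness."""
        if self.finished:
            raise ValueError("race already finished")
        pad = self.current_pad
        correct = COMMAND_FOR_PAD.get(pad.type) == kind
        self.records[-1].commands.append((self.t, kind, correct))
        if correct:
            self.regime = "boost"  # overrides any running penalty
            self.penalty_until = None
        else:
            self.regime = "penalty"
            self.penalty_until = self.t + PENALTY_DURATION_S
        return correct

    def advance_to_pad_exit(self) -> None:
        """Advance exactly to the end of the current pad (no new commands)."""
        idx = self.pad_index
        while not self.finished and self.pad_index == idx:
            t_reg = self.current_pad.regime_time(self.regime)
            # Either reaches the pad exit or a penalty expiry, after which
            # the remaining crossing is recomputed at the base rate.
            self.advance_to(self.t + (1.0 - self.progress) * t_reg)

    def run_to_finish(self) -> float:
        self.advance_to(float("inf"))
        return self.t


def simulate_race(track, commands) -> RaceResult:
    """Simulate a race from a time-ordered command stream.

    ``commands`` is any iterable of objects with ``kind`` and ``timestamp``
    attributes. Commands before the race start are ignored with a warning;
    commands after the finish line are ignored silently.
    """
    engine = RaceEngine(track)
    last_t = None
    for cmd in commands:
        if last_t is not None and cmd.timestamp < last_t:
            raise ValueError("commands must be time-ordered")
        last_t = cmd.timestamp
        if cmd.timestamp < 0:
            warnings.warn(f"ignoring command before race start "
                          f"(t={cmd.timestamp})")
            continue
        engine.advance_to(cmd.timestamp)
        if engine.finished:
            break
        engine.apply_command(cmd.kind)
    completion = engine.run_to_finish()
    return RaceResult(
        completion_time=completion,
        records=engine.records,
        valid=completion < VALID_RACE_CAP_S,
    )


def pad_crossing_times(result: RaceResult) -> dict[str, list[float]]:
    """Per-pad crossing durations partitioned by pad type."""
    out: dict[str, list[float]] = {t: [] for t in PAD_TYPES}
    for rec in result.records:
        out[rec.pad_type].append(rec.crossing_time)
    return out


def ideal_commands(track) -> list[GameCommandLike]:
    """The perfect-pilot stream: the matching command at each action-pad
    entry, silence on whites (realizes the lower race bound)."""
    engine = RaceEngine(track)
    out: list[GameCommandLike] = []
    while not engine.finished:
        pad = engine.current_pad
        if pad.type in COMMAND_FOR_PAD:
            out.append(GameCommandLike(COMMAND_FOR_PAD[pad.type], engine.t))
            engine.apply_command(COMMAND_FOR_PAD[pad.type])
        engine.advance_to_pad_exit()
    return out


def adversarial_commands(track, renew_s: float = 3.0) -> list[GameCommandLike]:
    """A continuously erroneous stream: a wrong command at each pad entry,
    renewed before the 4 s penalty expires (realizes the upper bound)."""
    if renew_s >= PENALTY_DURATION_S:
        raise ValueError("renewal must beat the penalty timer")
    engine = RaceEngine(track)
    out: list[GameCommandLike] = []
    while not engine.finished:
        wrong = "jump" if engine.current_pad.type == "cyan" else "spin"
        out.append(GameCommandLike(wrong, engine.t))
        engine.apply_command(wrong)
        # Renew within the pad, or move to the next pad entry if it is
        # closer; the whole crossing then happens in the penalty regime.
        exit_t = engine.t + (1.0 - engine.progress) * \
            engine.current_pad.t_penalty
        engine.advance_to(min(engine.t + renew_s, exit_t))
    return out


def race_bounds_table() -> dict[str, dict[str, float]]:
    """Analytic per-pad and per-track bounds, recomputed by simulation."""
    table: dict[str, dict[str, float]] = {}
    for pad_type in PAD_TYPES:
        pad = [PadSpec.of(pad_type)]
        entry: dict[str, float] = {}
        if pad_type in COMMAND_FOR_PAD:
            entry["boost"] = simulate_race(
                pad, [GameCommandLike(COMMAND_FOR_PAD[pad_type], 0.0)]
            ).completion_time
        entry["base"] = simulate_race(pad, []).completion_time
        entry["penalty"] = simulate_race(
            pad, adversarial_commands(pad)
        ).completion_time
        table[pad_type] = entry
    track = generate_track(seed=0)
    table["track"] = {
        "ideal": simulate_race(track, ideal_commands(track)).completion_time,
        "no_input": simulate_race(track, []).completion_time,
        "adversarial": simulate_race(
            track, adversarial_commands(track)
        ).completion_time,
    }
    return table
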
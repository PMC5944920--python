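"""Game control paradigms: mapping decoder decisions to avatar commands.

Four paradigms were explored for driving three avatar actions (spin, jump,
slide) from motor imagery:

1. three MI classes mapped directly to spin/jump/slide;
2. two MI classes mapped to spin/jump, slide unsupported;
3. two MI classes mapped to spin/jump, slide triggered by a configurable
   period of intentional non-control (idling);
4. two MI classes mapped to spin/jump, slide triggered by a spin/jump or
   jump/spin pair delivered within a configurable interval (the paradigm
   used in competition).

Under paradigm 4 the two constituent commands are forwarded to the game as
they occur and the slide is emitted at the second decision's time; the pair
window then resets. Under paradigm 3 the inactivity timer re-arms after
every decision or emitted slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoder import Decision

COMMAND_KINDS = ("spin", "jump", "slide")

DEFAULT_MAP_3CLASS = {
    "right_hand": "spin",
    "both_feet": "jump",
    "left_hand": "slide",
}
DEFAULT_MAP_2CLASS = {"both_hands": "spin", "both_feet": "jump"}


@dataclass(frozen=True)
class GameCommand:
    kind: str
    timestamp: float


@dataclass
class ParadigmConfig:
    paradigm_id: int = 4
    class_map: dict[str, str] = field(default_factory=dict)
    inactivity_period_s: float = 3.0  # paradigm 3
    pair_timeout_s: float = 3.0  # paradigm 4

    def __post_init__(self) -> None:
        if self.paradigm_id not in (1, 2, 3, 4):
            raise ValueError("paradigm_id must be 1..4")
        if not self.class_map:
            self.class_map = dict(
                DEFAULT_MAP_3CLASS if self.paradigm_id == 1
                else DEFAULT_MAP_2CLASS
            )
        n = len(self.class_map)
        if self.paradigm_id == 1 and n != 3:
            raise ValueError("paradigm 1 requires exactly 3 classes")
        if self.paradigm_id != 1 and n != 2:
            raise ValueError(
                f"paradigm {self.paradigm_id} requires exactly 2 classes"
            )
        if self.paradigm_id == 1 and set(self.class_map.values()) != set(
            COMMAND_KINDS
        ):
            raise ValueError("paradigm 1 must map onto spin/jump/slide")


class OnlineParadigm:
    """Streaming decision-to-command translator.

    ``update(t, decision)`` is called once per decoder step (and once per
    emitted decision) and returns the commands due at or before time ``t``.
    The offline :func:`map_decisions` wraps this class.
    """

    def __init__(self, cfg: ParadigmConfig) -> None:
        self.cfg = cfg
        self._last_event_t = 0.0  # paradigm 3 timer anchor
        self._pending: tuple[str, float] | None = None  # paradigm 4

    def _due_slides(self, until: float, inclusive: bool) -> list[GameCommand]:
        """Paradigm 3's idle-triggered slides due by ``until``, re-arming."""
        out: list[GameCommand] = []
        if self.cfg.paradigm_id != 3:
            return out
        while True:
            due = self._last_event_t + self.cfg.inactivity_period_s
            if due < until or (inclusive and due <= until):
                out.append(GameCommand("slide", due))
                self._last_event_t = due
            else:
                return out

    def update(
        self, t: float, decision: Decision | None = None
    ) -> list[GameCommand]:
        cfg = self.cfg
        if decision is None:
            return self._due_slides(t, inclusive=True)
        # Idle slides due strictly before the decision fire first.
        out = self._due_slides(decision.timestamp, inclusive=False)
        if decision.class_name not in cfg.class_map:
            raise ValueError(
                f"decision class {decision.class_name!r} not mapped by "
                f"paradigm {cfg.paradigm_id}"
            )
        kind = cfg.class_map[decision.class_name]
        td = decision.timestamp
        out.append(GameCommand(kind, td))
        self._last_event_t = td
        if cfg.paradigm_id == 4:
            if (
                self._pending is not None
                and self._pending[0] != kind
                and td - self._pending[1] <= cfg.pair_timeout_s
            ):
                out.append(GameCommand("slide", td))
                self._pending = None  # pair consumed; window resets
            else:
                self._pending = (kind, td)
        return out


def map_decisions(
    decisions: list[Decision],
    cfg: ParadigmConfig,
    horizon_s: float | None = None,
) -> list[GameCommand]:
    """Translate a time-ordered decision stream into game commands.

    ``horizon_s`` bounds paradigm 3's trailing idle-triggered slides (slides
    occur at idle multiples strictly before the horizon); for other
    paradigms it is ignored. Command timestamps are nondecreasing and
    include every decision's own mapped command.
    """
    times = [d.timestamp for d in decisions]
    if times != sorted(times):
        raise ValueError("decisions must be ordered in time")
    par = OnlineParadigm(cfg)
    out: list[GameCommand] = []
    for d in decisions:
        out.extend(par.update(d.timestamp, d))
    if horizon_s is not None:
        # Half-open horizon: trailing idle slides strictly before it.
        out.extend(par._due_slides(horizon_s, inclusive=False))
    return out


def inc_idle(
    decisions: list[Decision], window_s: float, horizon_s: float
) -> np.ndarray:
    """Per-window intentional non-control indicator.

    Window k covers the half-open interval [k*window_s, (k+1)*window_s); a
    window is idle when it contains no decision. A decision exactly on a
    boundary belongs to the later window.
    """
    n = int(np.ceil(horizon_s / window_s))
    idle = np.ones(n, dtype=bool)
    for d in decisions:
        k = int(np.floor(d.timestamp / window_s))
        if 0 <= k < n:
            idle[k] = False
    return idle
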
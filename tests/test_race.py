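"""Brain Runners race mechanics: bounds, regimes, penalties, conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bciloop import (GameCommand, PadSpec, Track, adversarial_commands,
                     generate_track, ideal_commands, pad_crossing_times,
                     simulate_race)
from bciloop.race import COMMAND_FOR_PAD, PENALTY_DURATION_S


def _cmd(kind, t):
    return GameCommand(kind, t)


# ------------------------------------------------------------------ tracks

def test_track_composition_and_reproducibility():
    track = generate_track(7)
    assert len(track.pads) == 18
    assert track.pads[0].type == "start" and track.pads[-1].type == "end"
    mid = [p.type for p in track.pads[1:-1]]
    for t in ("cyan", "magenta", "yellow", "white"):
        assert mid.count(t) == 4
    same = generate_track(7)
    assert [p.type for p in same.pads] == [p.type for p in track.pads]
    other = generate_track(8)
    assert [p.type for p in other.pads] != [p.type for p in track.pads]


def test_track_validation():
    with pytest.raises(ValueError):
        Track(tuple(PadSpec.of("white") for _ in range(18)))
    with pytest.raises(ValueError):
        Track(generate_track(0).pads[:-1])


# ------------------------------------------------------------- pad regimes

@pytest.mark.parametrize("pad_type,triple", [
    ("cyan", (2.0, 11.0, 19.0)),
    ("magenta", (2.0, 11.0, 19.0)),
    ("yellow", (2.0, 11.0, 19.0)),
])
def test_action_pad_regime_times(pad_type, triple):
    pad = [PadSpec.of(pad_type)]
    boost, base, penalty = triple
    good = COMMAND_FOR_PAD[pad_type]
    bad = "jump" if good != "jump" else "spin"
    assert simulate_race(pad, [_cmd(good, 0.0)]).completion_time == boost
    assert simulate_race(pad, []).completion_time == base
    assert simulate_race(
        pad, [_cmd(bad, 0.0), _cmd(bad, 3.0), _cmd(bad, 6.0),
              _cmd(bad, 9.0), _cmd(bad, 12.0), _cmd(bad, 15.0),
              _cmd(bad, 18.0)]
    ).completion_time == penalty


@pytest.mark.parametrize("pad_type,base,penalty", [
    ("white", 5.5, 19.0), ("start", 5.0, 13.0), ("end", 3.0, 10.0),
])
def test_white_pad_regime_times(pad_type, base, penalty):
    pad = [PadSpec.of(pad_type)]
    assert simulate_race(pad, []).completion_time == base
    stream = [_cmd("spin", 3.0 * k) for k in range(8)]
    assert simulate_race(pad, stream).completion_time == penalty


def test_penalty_expiry_resumes_base():
    """One wrong command at entry: 4 s in penalty (4/19 of the pad), then
    the remainder at base pace."""
    pad = [PadSpec.of("cyan")]
    res = simulate_race(pad, [_cmd("jump", 0.0)])
    expected = 4.0 + (1.0 - 4.0 / 19.0) * 11.0
    np.testing.assert_allclose(res.completion_time, expected, rtol=1e-12)


def test_correct_command_overrides_penalty():
    pad = [PadSpec.of("cyan")]
    res = simulate_race(pad, [_cmd("jump", 0.0), _cmd("spin", 1.0)])
    # 1 s penalty (1/19), remainder boosted
    expected = 1.0 + (1.0 - 1.0 / 19.0) * 2.0
    np.testing.assert_allclose(res.completion_time, expected, rtol=1e-12)


def test_wrong_command_overrides_boost():
    pad = [PadSpec.of("cyan")]
    res = simulate_race(pad, [_cmd("spin", 0.0), _cmd("jump", 1.0)])
    # half the pad boosted, then penalty for the rest (remaining 9.5 s in
    # penalty < 4 s timer never expires... remaining fraction 0.5 * 19 = 9.5
    # exceeds the 4 s penalty, after which base resumes)
    f_after_1s = 1.0 / 2.0
    remaining_after_penalty = 1.0 - f_after_1s - 4.0 / 19.0
    expected = 1.0 + 4.0 + remaining_after_penalty * 11.0
    np.testing.assert_allclose(res.completion_time, expected, rtol=1e-12)


@given(s=st.floats(min_value=0.01, max_value=10.9))
def test_single_switch_closed_form(s):
    """Piecewise-linear oracle: a correct command at time s on an action pad
    gives crossing time s + (1 - s/11) * 2."""
    pad = [PadSpec.of("magenta")]
    res = simulate_race(pad, [_cmd("jump", s)])
    np.testing.assert_allclose(
        res.completion_time, s + (1.0 - s / 11.0) * 2.0, rtol=1e-9)


@given(s=st.floats(min_value=0.01, max_value=4.9))
def test_single_wrong_switch_closed_form(s):
    """A lone wrong command at time s: penalty for 4 s then base; total
    matches the three-segment closed form."""
    pad = [PadSpec.of("white")]  # base 5.5, penalty 19
    res = simulate_race(pad, [_cmd("spin", s)])
    f_before = s / 5.5
    f_penalty = 4.0 / 19.0
    if f_before + f_penalty < 1.0:
        expected = s + 4.0 + (1.0 - f_before - f_penalty) * 5.5
    else:
        expected = s + (1.0 - f_before) * 19.0
    np.testing.assert_allclose(res.completion_time, expected, rtol=1e-9)


# ----------------------------------------------------------- whole tracks

def test_track_bounds():
    track = generate_track(0)
    assert simulate_race(track, ideal_commands(track)).completion_time == 54.0
    assert simulate_race(track, []).completion_time == 162.0
    assert simulate_race(
        track, adversarial_commands(track)).completion_time == 327.0


def test_validity_flag():
    track = generate_track(0)
    assert simulate_race(track, []).valid  # 162 < 240
    assert not simulate_race(track, adversarial_commands(track)).valid


def test_crossing_times_partition_and_conservation():
    track = generate_track(3)
    res = simulate_race(track, ideal_commands(track))
    times = pad_crossing_times(res)
    assert times["start"] == [5.0] and times["end"] == [3.0]
    assert times["white"] == [5.5] * 4
    for t in ("cyan", "magenta", "yellow"):
        assert times[t] == [2.0] * 4
    total = sum(sum(v) for v in times.values())
    np.testing.assert_allclose(total, res.completion_time, rtol=1e-12)


@given(seed=st.integers(0, 10_000))
def test_random_stream_invariants(seed):
    """Any command stream keeps each pad within its regime bounds and the
    race within [54, 327]; crossing times always sum to the total."""
    rng = np.random.default_rng(seed)
    track = generate_track(seed % 50)
    n = rng.integers(0, 60)
    times = np.sort(rng.uniform(0, 250, n))
    kinds = rng.choice(["spin", "jump", "slide"], n)
    stream = [_cmd(k, float(t)) for k, t in zip(kinds, times)]
    res = simulate_race(track, stream)
    assert 54.0 <= res.completion_time <= 327.0
    for rec in res.records:
        pad = PadSpec.of(rec.pad_type)
        lo = pad.t_boost if pad.t_boost is not None else pad.t_base
        assert lo - 1e-9 <= rec.crossing_time <= pad.t_penalty + 1e-9
    total = sum(r.crossing_time for r in res.records)
    np.testing.assert_allclose(total, res.completion_time, rtol=1e-9)


def test_determinism_same_stream():
    track = generate_track(9)
    rng = np.random.default_rng(2)
    times = np.sort(rng.uniform(0, 200, 30))
    stream = [_cmd(str(rng.choice(["spin", "jump", "slide"])), float(t))
              for t in times]
    r1 = simulate_race(track, stream)
    r2 = simulate_race(track, stream)
    assert r1.completion_time == r2.completion_time
    assert [rec.crossing_time for rec in r1.records] == \
        [rec.crossing_time for rec in r2.records]


def test_monotone_harm_of_wrong_command():
    """Replacing a correct command by a wrong one at the same instant never
    speeds up that pad."""
    rng = np.random.default_rng(4)
    track = generate_track(12)
    for _ in range(20):
        t = float(rng.uniform(0, 150))
        base_stream = [_cmd("spin", t)]
        res_any = simulate_race(track, base_stream)
        # find the pad the command landed on and its crossing with the
        # matching correct command instead
        rec = next((r for r in res_any.records
                    if r.entry_time <= t and
                    (r.exit_time is None or t < r.exit_time)), None)
        if rec is None or rec.pad_type not in COMMAND_FOR_PAD:
            continue
        good = simulate_race(track, [_cmd(COMMAND_FOR_PAD[rec.pad_type], t)])
        rec_good = [r for r in good.records if r.entry_time <= t][-1]
        assert rec_good.crossing_time <= rec.crossing_time + 1e-9


def test_pre_start_commands_ignored_with_warning():
    track = generate_track(0)
    with pytest.warns(UserWarning):
        res = simulate_race(track, [_cmd("spin", -3.0)])
    assert res.completion_time == 162.0


def test_penalty_timer_reset_extends_penalty():
    pad = [PadSpec.of("white")]  # base 5.5 s, penalty 19 s
    # two wrong commands 3 s apart keep the penalty alive past expiry
    res = simulate_race(pad, [_cmd("spin", 0.0), _cmd("spin", 3.0)])
    f_pen = 7.0 / 19.0  # 7 s of penalty in total
    expected = 7.0 + (1.0 - f_pen) * 5.5
    np.testing.assert_allclose(res.completion_time, expected, rtol=1e-12)
    assert PENALTY_DURATION_S == 4.0
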
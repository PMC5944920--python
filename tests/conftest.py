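"""Shared fixtures and helpers for the bciloop test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bciloop import (DecoderConfig, FeatureMatrix, IntegratorState,
                     SynthConfig, generate_run, step_integrator)
from bciloop.synth import CLASS_FEET, CLASS_HANDS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_feature_matrix(values, labels=None, step_s=0.0625):
    """FeatureMatrix over synthetic anonymous features for decoder tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    index = [(f"ch{i}", 20.0 + 2 * i) for i in range(values.shape[1])]
    times = 1.0 + np.arange(values.shape[0]) * step_s
    lab = None if labels is None else np.asarray(labels, dtype=object)
    return FeatureMatrix(values, times, index, labels=lab)


def gaussian_cloud_features(rng, n_per_class, d, separation):
    """Two spherical Gaussian clouds separated along the first feature."""
    x1 = rng.standard_normal((n_per_class, d))
    x2 = rng.standard_normal((n_per_class, d))
    x1[:, 0] += separation
    values = np.vstack([x1, x2])
    labels = np.array([CLASS_HANDS] * n_per_class + [CLASS_FEET] * n_per_class,
                      dtype=object)
    return make_feature_matrix(values, labels)


@pytest.fixture(scope="session")
def mi_run_strong():
    """A short two-class run with a strong single-channel beta effect."""
    cfg = SynthConfig(
        effect_size=1.0,
        effect_channels=("Cz",),
        trial_schedule=tuple([(CLASS_HANDS, 4.0), (CLASS_FEET, 4.0)] * 8),
        seed=101,
    )
    return cfg, generate_run(cfg)


def fuzz_integrator(n_steps: int, seed: int, cfg: DecoderConfig | None = None):
    """Drive the integrator with randomized posteriors and gating.

    Returns (decisions as (t, gated) tuples, max simplex violation). Used
    both by the module tests and, at larger n, the acceptance suite.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or DecoderConfig()
    state = IntegratorState.initial(2)
    worst_simplex = 0.0
    decisions = []
    gate_log = []
    regime = 0  # 0: noise, 1: class-0 burst, 2: class-1 burst
    for i in range(n_steps):
        t = (i + 1) * cfg.step_s
        if rng.random() < 0.02:
            regime = int(rng.integers(3))
        # Bursts of sustained confident posteriors (imagery-like) broken by
        # uncertain noise; bursts make threshold crossings frequent.
        if regime == 0:
            q = rng.uniform(0.3, 0.9)
            p = np.array([q, 1 - q]) if rng.random() < 0.5 else \
                np.array([1 - q, q])
        else:
            q = rng.uniform(0.92, 1.0)
            p = np.array([q, 1 - q]) if regime == 1 else np.array([1 - q, q])
        state.gated = bool(rng.random() < 0.2)
        gate_log.append((t, state.gated))
        state, decision = step_integrator(state, p, cfg, t)
        worst_simplex = max(
            worst_simplex,
            abs(state.integrated.sum() - 1.0),
            float(-state.integrated.min()),
        )
        if decision is not None:
            decisions.append((decision.timestamp, state.gated))
    return decisions, gate_log, worst_simplex
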
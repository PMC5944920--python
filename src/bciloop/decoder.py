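"""Online probabilistic decoder: Gaussian classifier, sample rejection,
leaky-integrator evidence accumulation and thresholded command emission.

At every 62.5 ms step the classifier turns a feature vector into a posterior
over the two motor-imagery classes. Uncertain samples (max posterior below
the rejection threshold rho) are discarded; accepted posteriors are smoothed
by a leaky integrator I' = alpha*I + (1-alpha)*p. A decision for class c is
emitted when I'_c reaches the decision threshold theta_c, after which the
integrated probabilities reset to uniform and a refractory period suppresses
further emissions. Artifact gating likewise suppresses emission without
stopping the evidence stream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureMatrix, cva_rank_features


@dataclass
class ClassifierModel:
    """Class-conditional diagonal Gaussians over selected features."""

    selected_features: list[tuple[str, float]]
    class_names: tuple[str, ...]
    means: np.ndarray  # classes x features
    variances: np.ndarray  # classes x features, positive
    priors: np.ndarray | None = None
    train_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if self.priors is None:
            self.priors = np.full(len(self.class_names),
                                  1.0 / len(self.class_names))
        self.priors = np.asarray(self.priors, dtype=float)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "bciloop-classifier-v1",
            "selected_features": [[ch, b] for ch, b in self.selected_features],
            "class_names": list(self.class_names),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "priors": self.priors.tolist(),
            "train_accuracy": self.train_accuracy,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "bciloop-classifier-v1":
            raise ValueError("unrecognized model file format")
        return cls(
            selected_features=[(ch, float(b))
                               for ch, b in d["selected_features"]],
            class_names=tuple(d["class_names"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            priors=np.asarray(d["priors"]),
            train_accuracy=d.get("train_accuracy"),
        )


@dataclass
class DecoderConfig:
    """Evidence-accumulation parameters (per 62.5 ms step)."""

    rejection_threshold: float = 0.55  # rho
    smoothing: float = 0.96  # alpha, integrator retention per step
    decision_threshold: float | dict[str, float] = 0.9  # theta_c
    refractory_s: float = 1.0
    step_s: float = 0.0625
    #: "suppress": evidence keeps integrating during refractory but emission
    #: is blocked and I is re-reset to uniform at refractory end.
    #: "freeze": the integrator state is held fixed during refractory.
    refractory_mode: str = "suppress"

    def __post_init__(self) -> None:
        if not (0 <= self.rejection_threshold <= 1):
            raise ValueError("rejection_threshold must be in [0, 1]")
        if not (0 <= self.smoothing < 1):
            raise ValueError("smoothing must be in [0, 1)")
        if self.refractory_mode not in ("suppress", "freeze"):
            raise ValueError("refractory_mode must be 'suppress' or 'freeze'")

    def theta(self, class_name: str, n_classes: int) -> float:
        if isinstance(self.decision_threshold, dict):
            th = self.decision_threshold[class_name]
        else:
            th = self.decision_threshold
        if th <= 1.0 / n_classes:
            raise ValueError("decision threshold must exceed 1/n_classes")
        return th


@dataclass
class IntegratorState:
    """Integrated class probabilities plus emission bookkeeping."""

    integrated: np.ndarray
    last_emission_t: float | None = None
    gated: bool = False
    _pending_rereset: bool = False

    @classmethod
    def initial(cls, n_classes: int) -> "IntegratorState":
        return cls(np.full(n_classes, 1.0 / n_classes))


@dataclass(frozen=True)
class Decision:
    timestamp: float
    class_name: str
    integrated_probability: float


def train_classifier(
    features: FeatureMatrix,
    selected_features: list[tuple[str, float]] | None = None,
    classes: tuple[str, str] = ("both_hands", "both_feet"),
    n_auto_features: int = 6,
    var_floor: float = 1e-10,
    gradient_refine: bool = False,
    learning_rate: float = 0.05,
    n_iter: int = 200,
) -> ClassifierModel:
    """Fit the Gaussian classifier on labeled feature windows.

    With ``selected_features=None`` the top ``n_auto_features`` by CVA
    discriminant power are used. The closed-form fit (per-class means and
    diagonal variances) can optionally be refined by full-batch gradient
    descent on the cross-entropy of the posteriors, mirroring the
    discriminative training of the online system; the closed-form fit is the
    reproducible default.
    """
    if features.labels is None:
        raise ValueError("training requires labeled windows")
    for k in classes:
        if not np.any(features.labels == k):
            raise ValueError(f"class {k!r} absent from training data")
    if selected_features is None:
        ranking = cva_rank_features(features, classes)
        idx = ranking.top(n_auto_features)
        selected_features = [features.feature_index[i] for i in idx]
    x = features.select(selected_features)
    means, variances = [], []
    for k in classes:
        xk = x[features.labels == k]
        means.append(xk.mean(axis=0))
        v = xk.var(axis=0, ddof=1)
        if np.any(v <= var_floor):
            warnings.warn("degenerate feature variance; regularized")
            v = np.maximum(v, var_floor)
        variances.append(v)
    means = np.asarray(means)
    variances = np.asarray(variances)

    if gradient_refine:
        means, variances = _refine_gradient(
            x, features.labels, classes, means, variances,
            learning_rate, n_iter, var_floor,
        )

    model = ClassifierModel(selected_features, classes, means, variances)
    mask = np.isin(features.labels, classes)
    post = classify_samples(model, x[mask])
    pred = np.asarray(classes)[np.argmax(post, axis=1)]
    model.train_accuracy = float(np.mean(pred == features.labels[mask]))
    return model


def _refine_gradient(x, labels, classes, means, variances, lr, n_iter,
                     var_floor):
    """Gradient descent on cross-entropy over means and log-variances."""
    mask = np.isin(labels, classes)
    xs = x[mask]
    y = np.asarray([list(classes).index(k) for k in labels[mask]])
    mu = means.copy()
    logv = np.log(variances.copy())
    onehot = np.eye(len(classes))[y]
    for _ in range(n_iter):
        v = np.exp(logv)
        ll = -0.5 * (
            ((xs[:, None, :] - mu[None]) ** 2) / v[None] + logv[None]
        ).sum(axis=2)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        err = p - onehot  # n x classes
        diff = xs[:, None, :] - mu[None]
        g_mu = (err[:, :, None] * diff / v[None]).sum(axis=0) / len(xs)
        g_logv = (err[:, :, None] * 0.5 * (diff**2 / v[None] - 1)
                  ).sum(axis=0) / len(xs)
        mu -= lr * g_mu
        logv -= lr * g_logv
    return mu, np.maximum(np.exp(logv), var_floor)


def classify_samples(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Posterior over classes for each row of ``x`` (diagonal Gaussians)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1]}"
        )
    diff = x[:, None, :] - model.means[None]
    ll = -0.5 * (
        diff**2 / model.variances[None] + np.log(model.variances)[None]
    ).sum(axis=2)
    ll += np.log(model.priors)[None]
    ll -= ll.max(axis=1, keepdims=True)
    p = np.exp(ll)
    return p / p.sum(axis=1, keepdims=True)


def classify_sample(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    return classify_samples(model, x)[0]


def step_integrator(
    state: IntegratorState,
    posterior: np.ndarray,
    cfg: DecoderConfig,
    t: float,
    class_names: tuple[str, ...] = ("both_hands", "both_feet"),
) -> tuple[IntegratorState, Decision | None]:
    """One evidence-accumulation step at time ``t``.

    Rejected samples (max posterior < rho) leave the state untouched.
    Accepted ones update I' = alpha*I + (1-alpha)*p. A decision is emitted
    when some I'_c >= theta_c, the refractory period has elapsed and the
    state is not artifact-gated; the integrator then resets to uniform. When
    two classes cross simultaneously the larger integrated probability wins,
    ties by class order.
    """
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-12):
        raise ValueError("posterior is not a probability distribution")
    n = len(p)
    in_refractory = (
        state.last_emission_t is not None
        and t < state.last_emission_t + cfg.refractory_s
    )
    if in_refractory and cfg.refractory_mode == "freeze":
        return state, None
    integrated = state.integrated
    pending = state._pending_rereset
    if pending and not in_refractory:
        # Refractory just elapsed: restart evidence from uniform.
        integrated = np.full(n, 1.0 / n)
        pending = False
    if np.max(p) < cfg.rejection_threshold:
        return IntegratorState(integrated, state.last_emission_t,
                               state.gated, pending), None
    new_i = cfg.smoothing * integrated + (1.0 - cfg.smoothing) * p

    decision = None
    last_t = state.last_emission_t
    if not in_refractory and not state.gated:
        thetas = np.asarray([cfg.theta(c, n) for c in class_names])
        crossing = np.flatnonzero(new_i >= thetas - 1e-12)
        if crossing.size:
            c = crossing[np.argmax(new_i[crossing])]
            decision = Decision(t, class_names[int(c)], float(new_i[c]))
            last_t = t
            new_i = np.full(n, 1.0 / n)
            pending = cfg.refractory_mode == "suppress"
    return IntegratorState(new_i, last_t, state.gated, pending), decision


def run_decoder(
    features: FeatureMatrix,
    model: ClassifierModel,
    cfg: DecoderConfig | None = None,
    gated_intervals: list[tuple[float, float]] = (),
) -> tuple[list[Decision], "object"]:
    """Decode a feature stream into timestamped decisions.

    ``gated_intervals`` are half-open [onset, offset) artifact blocks during
    which no decision may be emitted. Returns the decision list and a pandas
    audit trace with per-step posterior, integrated evidence and gating.
    """
    import pandas as pd

    cfg = cfg or DecoderConfig()
    x = features.select(model.selected_features)
    posteriors = classify_samples(model, x)
    state = IntegratorState.initial(len(model.class_names))
    decisions: list[Decision] = []
    rows = []
    for t, p in zip(features.window_times, posteriors):
        state.gated = any(on <= t < off for on, off in gated_intervals)
        state, decision = step_integrator(state, p, cfg, float(t),
                                          model.class_names)
        if decision is not None:
            decisions.append(decision)
        rows.append((float(t), *p, *state.integrated, state.gated,
                     decision.class_name if decision else ""))
    cols = (["t"] + [f"p_{c}" for c in model.class_names]
            + [f"I_{c}" for c in model.class_names] + ["gated", "decision"])
    return decisions, pd.DataFrame(rows, columns=cols)
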
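"""Declarative task definitions for the four adaptive detection methods.

A :class:`TaskSpec` binds together, for one of qYN / qYNC / qYNR / qFC:

* the ordered free-parameter layout of the SDT model (3 parameters for
  qYN and qFC, 4 for qYNC and qYNR),
* the response alphabet (binary except the ternary rated task),
* the enumerated stimulus-condition space over which the engine's
  one-step-ahead search runs.

Stimulus conditions are plain contrasts for qYN and qYNR; (contrast, cue
state) pairs for qYNC, whose adaptive search chooses the cue as well; and
signed relative contrasts for qFC, where the method picks both the signal
level and the interval that carries it (optionally including the
both-blank condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .sdt import (
    DEFAULT_BETA,
    DEFAULT_EPSILON,
    SQRT2,
    LapseConfig,
    _dprime_raw,
)

__all__ = [
    "TASK_NAMES",
    "StimulusCondition",
    "TaskSpec",
    "stimulus_grid",
    "make_task",
    "response_probabilities",
    "condition_likelihood",
]

TASK_NAMES = ("qYN", "qYNC", "qYNR", "qFC")

_PARAM_NAMES = {
    "qYN": ("tau", "gamma", "lam"),
    "qYNC": ("tau", "gamma", "lam_strict", "delta_lam"),
    "qYNR": ("tau", "gamma", "lam_strict", "delta_lam"),
    "qFC": ("tau", "gamma", "lam_fc"),
}

_RESPONSES = {
    "qYN": ("Yes", "No"),
    "qYNC": ("Yes", "No"),
    "qYNR": ("Yes", "NotSure", "No"),
    "qFC": ("Interval1", "Interval2"),
}

#: Stimulus-space presets. ``simstudy`` is the validation-simulation space
#: (0.1–99% contrast, 120 log-spaced levels); ``simstudy-coarse`` halves its
#: resolution; ``demo`` samples 0.1–99% at 0.25 dB steps.
_STIMULUS_PRESETS = {
    "simstudy": (0.001, 0.99, 120),
    "simstudy-coarse": (0.001, 0.99, 60),
    "demo": (0.001, 0.99, 121),
}


def stimulus_grid(preset: str = "simstudy") -> np.ndarray:
    """Return the log-spaced contrast levels of a named stimulus preset."""
    try:
        lo, hi, n = _STIMULUS_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown stimulus preset {preset!r}; choose from {sorted(_STIMULUS_PRESETS)}"
        ) from None
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class StimulusCondition:
    """One presentable condition.

    contrast : signal contrast magnitude (0 allowed only for the qFC
        both-blank condition)
    cue_state : 'lax' or 'strict' for qYNC, else None
    interval : 1 or 2 for qFC signal conditions, else None
    """

    contrast: float
    cue_state: Optional[str] = None
    interval: Optional[int] = None

    @property
    def signed_contrast(self) -> float:
        """qFC convention: negative = signal in interval 1, positive = interval 2."""
        if self.interval == 1:
            return -self.contrast
        return self.contrast

    def label(self) -> str:
        if self.cue_state is not None:
            return f"{self.contrast:.4g}|{self.cue_state}"
        if self.interval is not None:
            return f"{self.signed_contrast:+.4g}"
        return f"{self.contrast:.4g}"


@dataclass(frozen=True)
class TaskSpec:
    """Fully-populated description of one adaptive method's task."""

    name: str
    param_names: tuple
    response_labels: tuple
    conditions: tuple
    contrasts: np.ndarray
    lapse: LapseConfig

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_responses(self) -> int:
        return len(self.response_labels)

    def response_index(self, response: str) -> int:
        try:
            return self.response_labels.index(response)
        except ValueError:
            raise ValueError(
                f"response {response!r} not in alphabet {self.response_labels}"
            ) from None

    def condition_index(self, condition: StimulusCondition) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise ValueError(f"condition {condition} not in task space") from None


def make_task(
    name: str,
    contrasts: Optional[np.ndarray] = None,
    stimulus_preset: str = "simstudy",
    include_null: bool = True,
    epsilon: float = DEFAULT_EPSILON,
) -> TaskSpec:
    """Build the :class:`TaskSpec` for one of the four methods.

    ``contrasts`` overrides the named ``stimulus_preset``. For qFC,
    ``include_null`` adds the both-blank (signed contrast 0) condition,
    mirroring the constant-stimuli design.
    """
    if name not in TASK_NAMES:
        raise ValueError(f"unknown task {name!r}; choose from {TASK_NAMES}")
    levels = np.asarray(
        stimulus_grid(stimulus_preset) if contrasts is None else contrasts, dtype=float
    )
    if levels.ndim != 1 or len(levels) == 0 or np.any(levels <= 0):
        raise ValueError("contrast levels must be a non-empty 1-D positive array")

    if name == "qYNC":
        conds = [StimulusCondition(c, cue_state="lax") for c in levels]
        conds += [StimulusCondition(c, cue_state="strict") for c in levels]
    elif name == "qFC":
        conds = [StimulusCondition(c, interval=1) for c in levels]
        if include_null:
            conds.append(StimulusCondition(0.0))
        conds += [StimulusCondition(c, interval=2) for c in levels]
    else:
        conds = [StimulusCondition(c) for c in levels]

    lapse = LapseConfig(epsilon=epsilon, n_alternatives=len(_RESPONSES[name]))
    return TaskSpec(
        name=name,
        param_names=_PARAM_NAMES[name],
        response_labels=_RESPONSES[name],
        conditions=tuple(conds),
        contrasts=levels,
        lapse=lapse,
    )


def condition_likelihood(task: TaskSpec, condition: StimulusCondition, theta: dict,
                         beta: float = DEFAULT_BETA) -> np.ndarray:
    """Lapse-adjusted response probabilities, vectorised over parameter arrays.

    ``theta`` maps each of ``task.param_names`` to a scalar or an array of
    node values (all broadcastable); the result has shape ``(R,) + shape``.
    This is the kernel the engine uses to tabulate likelihoods over the
    whole parameter grid.
    """
    tau = np.asarray(theta["tau"], dtype=float)
    gamma = np.asarray(theta["gamma"], dtype=float)
    eps = task.lapse.epsilon
    k = task.lapse.n_alternatives

    if task.name == "qFC":
        lam = np.asarray(theta["lam_fc"], dtype=float)
        c1 = condition.contrast if condition.interval == 1 else 0.0
        c2 = condition.contrast if condition.interval == 2 else 0.0
        dd = _dprime_raw(c2, tau, gamma, beta) - _dprime_raw(c1, tau, gamma, beta)
        p_i2 = ndtr(dd / SQRT2 - lam)
        probs = np.stack(np.broadcast_arrays(1.0 - p_i2, p_i2))
    else:
        d = _dprime_raw(condition.contrast, tau, gamma, beta)
        if task.name == "qYN":
            lam = np.asarray(theta["lam"], dtype=float)
            p_yes = ndtr(d - lam)
            probs = np.stack(np.broadcast_arrays(p_yes, 1.0 - p_yes))
        elif task.name == "qYNC":
            lam_strict = np.asarray(theta["lam_strict"], dtype=float)
            delta = np.asarray(theta["delta_lam"], dtype=float)
            if np.any(delta < 0):
                raise ValueError("delta_lam must be >= 0")
            lam = lam_strict if condition.cue_state == "strict" else lam_strict - delta
            p_yes = ndtr(d - lam)
            probs = np.stack(np.broadcast_arrays(p_yes, 1.0 - p_yes))
        else:  # qYNR
            lam_strict = np.asarray(theta["lam_strict"], dtype=float)
            delta = np.asarray(theta["delta_lam"], dtype=float)
            if np.any(delta < 0):
                raise ValueError("delta_lam must be >= 0")
            p_yes = ndtr(d - lam_strict)
            p_no = ndtr((lam_strict - delta) - d)
            p_ns = 1.0 - p_yes - p_no
            probs = np.stack(np.broadcast_arrays(p_yes, p_ns, p_no))

    return eps / k + (1.0 - eps) * probs


def response_probabilities(task: TaskSpec, condition: StimulusCondition, theta) -> np.ndarray:
    """Lapse-adjusted response distribution at one parameter vector.

    ``theta`` is a dict keyed by ``task.param_names`` or a sequence in that
    order; the condition must belong to the task's stimulus space.
    """
    task.condition_index(condition)  # raises if not in the space
    if not isinstance(theta, dict):
        if len(theta) != len(task.param_names):
            raise ValueError(
                f"theta has {len(theta)} entries, expected {len(task.param_names)}"
            )
        theta = dict(zip(task.param_names, theta))
    return condition_likelihood(task, condition, theta).astype(float).ravel()
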
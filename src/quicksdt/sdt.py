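"""Signal-detection model of detection behaviour.

The model describes an observer's responses in four detection tasks --
simple Yes-No, cued Yes-No, rated Yes-No and two-interval forced choice --
with a single sensitivity (d') psychometric function plus task-specific
decision criteria.

Sensitivity is parameterised with a saturating gain-control transducer

    d'(c) = beta * (c/tau)**gamma / sqrt((beta**2 - 1) + (c/tau)**(2*gamma))

where ``tau`` is the *sensitivity threshold* -- the contrast at which
d' = 1 exactly -- ``gamma`` sets the steepness on log-contrast axes, and
``beta`` is the upper asymptote (fixed at 5 by convention; sensitivity
levels above d' ~ 4 are not reliably measurable anyway).

Response probabilities follow from placing one or two z-unit decision
criteria on the internal-response axis (standard-normal noise):

* simple detection:  P(Yes | c)  = 1 - Phi(lambda - d'(c))
* cued detection:    as simple, with lambda_lax = lambda_strict - delta
* rated detection:   Yes / Not-Sure / No carved out by the two criteria
* 2IFC:              P(Interval 2) = 1 - Phi(lambda_fc - [d'(c2) - d'(c1)]/sqrt(2))

A small stimulus-independent lapse rate ``epsilon`` mixes each response
distribution with a uniform one over the K response categories,

    psi' = epsilon/K + (1 - epsilon) * psi,

so that with epsilon = 2% and two alternatives the empirical psychometric
function asymptotes at 99%.

All functions are vectorised over contrast and/or parameter arrays; the
grid-Bayes engine evaluates them over hundreds of thousands of parameter
nodes at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SensitivityParams",
    "SimpleCriterion",
    "DualCriterion",
    "IntervalCriterion",
    "DecisionParams",
    "LapseConfig",
    "dprime",
    "yes_probability",
    "cued_probabilities",
    "rated_probabilities",
    "interval2_probability",
    "apply_lapse",
]

DEFAULT_BETA = 5.0
DEFAULT_EPSILON = 0.02

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class SensitivityParams:
    """Parameters of the d' transducer.

    tau : sensitivity threshold, contrast in (0, 1) at which d' = 1
    gamma : steepness exponent (> 0), dimensionless
    beta : d' upper asymptote (> 1), dimensionless
    """

    tau: float
    gamma: float
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if not self.gamma > 0.0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.beta > 1.0:
            raise ValueError(f"beta must exceed 1, got {self.beta}")


@dataclass(frozen=True)
class SimpleCriterion:
    """Single decision criterion (z units) for simple YN detection."""

    lam: float


@dataclass(frozen=True)
class DualCriterion:
    """Strict/lax criterion pair for cued and rated detection.

    Parameterised as (lambda_strict, delta_lam) with
    lambda_lax = lambda_strict - delta_lam, so that the order constraint
    lambda_lax <= lambda_strict is enforced by delta_lam >= 0.
    """

    lam_strict: float
    delta_lam: float

    def __post_init__(self) -> None:
        if self.delta_lam < 0.0:
            raise ValueError(
                f"delta_lam must be >= 0 (lax criterion below strict), got {self.delta_lam}"
            )

    @property
    def lam_lax(self) -> float:
        return self.lam_strict - self.delta_lam


@dataclass(frozen=True)
class IntervalCriterion:
    """Interval criterion (z units) for 2IFC; sign encodes interval bias.

    Negative values bias the observer toward responding *Interval 2*
    (P(Interval 2 | null) = 1 - Phi(lam_fc) > 1/2).
    """

    lam_fc: float


DecisionParams = Union[SimpleCriterion, DualCriterion, IntervalCriterion]


@dataclass(frozen=True)
class LapseConfig:
    """Stimulus-independent lapse model.

    epsilon : lapse probability in [0, 0.1); lapse responses are spread
        uniformly over the response categories
    n_alternatives : number of response categories (2 for YN/cued/FC, 3 for rated)
    """

    epsilon: float = DEFAULT_EPSILON
    n_alternatives: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.1):
            raise ValueError(f"epsilon must lie in [0, 0.1), got {self.epsilon}")
        if self.n_alternatives < 2:
            raise ValueError("need at least two response alternatives")


def _dprime_raw(c, tau, gamma, beta):
    """d' transducer on raw arrays; broadcasts over all arguments."""
    c = np.asarray(c, dtype=float)
    ratio = np.where(c > 0, c, 1.0) / tau  # guard 0**negative
    num = beta * ratio**gamma
    den = np.sqrt((beta * beta - 1.0) + ratio ** (2.0 * gamma))
    # keep d' strictly below the asymptote even where the ratio term
    # swamps (beta^2 - 1) in floating point
    out = np.minimum(num / den, np.nextafter(beta, 0.0))
    return np.where(c > 0, out, 0.0)


def dprime(c, params: SensitivityParams):
    """Sensitivity d' at contrast ``c`` (scalar or array).

    Raises ValueError for negative or non-finite contrast.
    """
    c_arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c_arr)) or np.any(c_arr < 0):
        raise ValueError("contrast must be finite and non-negative")
    out = _dprime_raw(c_arr, params.tau, params.gamma, params.beta)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def yes_probability(c, sens: SensitivityParams, lam: float):
    """P(Yes | c) for simple detection: 1 - Phi(lambda - d'(c)).

    At c = 0 this is the false-alarm rate 1 - Phi(lambda).
    """
    d = dprime(c, sens)
    return ndtr(d - lam) if np.ndim(d) else float(ndtr(d - lam))


def cued_probabilities(c, state: str, sens: SensitivityParams, dec: DualCriterion):
    """P(Yes | c, cue state) for cued detection; state is 'lax' or 'strict'."""
    if state not in ("lax", "strict"):
        raise ValueError(f"cue state must be 'lax' or 'strict', got {state!r}")
    lam = dec.lam_lax if state == "lax" else dec.lam_strict
    return yes_probability(c, sens, lam)


def rated_probabilities(c, sens: SensitivityParams, dec: DualCriterion):
    """(P(Yes), P(Not Sure), P(No)) at contrast ``c`` for rated detection.

    Yes responses exceed the strict criterion, No responses fall below the
    lax criterion, and Not Sure fills the band between them; the three
    probabilities partition unity at every contrast.
    """
    d = dprime(c, sens)
    p_yes = ndtr(d - dec.lam_strict)
    p_no = ndtr(dec.lam_lax - d)
    p_ns = 1.0 - p_yes - p_no
    return p_yes, p_ns, p_no


def interval2_probability(c1, c2, sens: SensitivityParams, lam_fc: float):
    """P(Interval 2) in 2IFC with contrasts (c1, c2) in the two intervals.

    The decision variable is the difference of the two intervals' internal
    responses, with the d' separation scaled by 1/sqrt(2) because both
    intervals contribute independent noise:

        P(I2) = 1 - Phi(lam_fc - [d'(c2) - d'(c1)] / sqrt(2))

    With a neutral criterion (lam_fc = 0), a signal at threshold (d' = 1)
    in one interval is reported correctly ~76% of the time, and swapping
    the intervals complements the probability.
    """
    d1 = dprime(c1, sens)
    d2 = dprime(c2, sens)
    p = ndtr((d2 - d1) / SQRT2 - lam_fc)
    return float(p) if np.ndim(p) == 0 else p


def apply_lapse(p, lapse: LapseConfig):
    """Mix a response distribution with uniform lapses.

    psi' = epsilon/K + (1 - epsilon) * psi over K = lapse.n_alternatives
    categories; the output is again a distribution, with every component
    bounded inside [epsilon/K, 1 - epsilon*(K-1)/K].
    """
    p = np.asarray(p, dtype=float)
    k = lapse.n_alternatives
    if p.shape[-1] != k:
        raise ValueError(
            f"probability vector has {p.shape[-1]} components, expected {k}"
        )
    sums = p.sum(axis=-1)
    if np.any(p < -1e-12) or not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("input is not a probability distribution")
    return lapse.epsilon / k + (1.0 - lapse.epsilon) * p
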
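"""Simulated observers and the Monte-Carlo validation harness.

Observers are defined by the same SDT model the engine assumes (matched-
model simulation): shared sensitivity parameters (threshold tau = 10%
contrast, steepness gamma = 2 throughout the reference studies) and
decision criteria specified operationally by response rates to the null
stimulus -- false-alarm rates for YN tasks, Yes/No null rates for the
rated task, and the null Interval-2 rate for 2IFC -- converted to z-unit
criteria through the inverse normal CDF. Simulated responses include the
2% lapse mixture.

The harness replicates adaptive sessions many times to measure

* accuracy: mean threshold bias  10*log10(tau_hat / tau_true)  in dB,
* precision: SD of threshold estimates (dB, or decimal log units),
* stimulus-sampling histograms (ordinary and cumulative),
* recovery of null-stimulus response probabilities (d' = 0 behaviour),
* the effect of matched/mismatched, weak/strict threshold priors.

Replications are run as a single vectorised batch: the B posteriors form
a (B, N) matrix and each trial's predictive probabilities and expected-
entropy scores for all replicates come from one matrix product against
the precomputed likelihood tables. Per-replicate RNG streams are spawned
from the master seed exactly as the sequential session runner spawns
them, so a batch replicate and a lone session with the same stream are
the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .engine import (
    AdaptiveSession,
    ParameterGrid,
    PriorSpec,
    build_prior,
)
from .sdt import (
    DEFAULT_BETA,
    DEFAULT_EPSILON,
    DualCriterion,
    IntervalCriterion,
    LapseConfig,
    SensitivityParams,
    SimpleCriterion,
)
from .tasks import StimulusCondition, TaskSpec, condition_likelihood, make_task

__all__ = [
    "ObserverState",
    "StudyResult",
    "observer_from_rates",
    "reference_states",
    "study_prior",
    "observer_probabilities",
    "simulate_response",
    "run_session",
    "bias_db",
    "run_study",
    "stimulus_histograms",
    "criterion_recovery",
    "prior_mismatch_study",
]

#: Default contrast threshold / steepness of the simulated reference observer.
TRUE_TAU = 0.10
TRUE_GAMMA = 2.0

#: Null-stimulus response rates defining the three response states per task
#: (conservative -> liberal ordering within each list).
REFERENCE_RATES = {
    "qYN": [{"fa": 0.025}, {"fa": 0.10}, {"fa": 0.40}],
    "qYNC": [
        {"fa_strict": 0.025, "fa_lax": 0.10},
        {"fa_strict": 0.025, "fa_lax": 0.40},
        {"fa_strict": 0.10, "fa_lax": 0.40},
    ],
    "qYNR": [
        {"yes": 0.025, "no": 0.90},
        {"yes": 0.025, "no": 0.60},
        {"yes": 0.10, "no": 0.60},
    ],
    "qFC": [
        {"interval2": 0.30},
        {"interval2": 0.50},
        {"interval2": 0.70},
    ],
}


@dataclass(frozen=True)
class ObserverState:
    """A simulated observer: sensitivity + decision criteria + lapse."""

    sens: SensitivityParams
    dec: object
    lapse: LapseConfig
    label: str = ""

    def theta(self, task: TaskSpec) -> dict:
        """Model parameter dict in the task's layout."""
        out = {"tau": self.sens.tau, "gamma": self.sens.gamma}
        if task.name == "qYN":
            out["lam"] = self.dec.lam
        elif task.name in ("qYNC", "qYNR"):
            out["lam_strict"] = self.dec.lam_strict
            out["delta_lam"] = self.dec.delta_lam
        else:
            out["lam_fc"] = self.dec.lam_fc
        return out


def observer_from_rates(
    task_name: str,
    rates: dict,
    tau: float = TRUE_TAU,
    gamma: float = TRUE_GAMMA,
    beta: float = DEFAULT_BETA,
    epsilon: float = DEFAULT_EPSILON,
    label: str = "",
) -> ObserverState:
    """Build an observer whose criteria are set by null-response rates.

    Recognised ``rates`` keys: ``fa`` (qYN); ``fa_strict``/``fa_lax``
    (qYNC); ``yes``/``no`` null rates (qYNR); ``interval2`` null rate
    (qFC). Rates are model rates (pre-lapse) mapped through the inverse
    normal CDF.
    """
    sens = SensitivityParams(tau, gamma, beta)
    if task_name == "qYN":
        lam = float(ndtri(1.0 - rates["fa"]))
        dec, k = SimpleCriterion(lam), 2
        auto = f"FA={rates['fa']:.1%}"
    elif task_name == "qYNC":
        lam_strict = float(ndtri(1.0 - rates["fa_strict"]))
        lam_lax = float(ndtri(1.0 - rates["fa_lax"]))
        dec, k = DualCriterion(lam_strict, lam_strict - lam_lax), 2
        auto = f"FA=({rates['fa_strict']:.1%},{rates['fa_lax']:.1%})"
    elif task_name == "qYNR":
        lam_strict = float(ndtri(1.0 - rates["yes"]))
        lam_lax = float(ndtri(rates["no"]))
        dec, k = DualCriterion(lam_strict, lam_strict - lam_lax), 3
        auto = f"null(Y,N)=({rates['yes']:.1%},{rates['no']:.1%})"
    elif task_name == "qFC":
        dec, k = IntervalCriterion(float(ndtri(1.0 - rates["interval2"]))), 2
        auto = f"P(I2|null)={rates['interval2']:.0%}"
    else:
        raise ValueError(f"unknown task {task_name!r}")
    return ObserverState(sens, dec, LapseConfig(epsilon, k), label or auto)


def reference_states(task_name: str, **kwargs) -> list:
    """The three response states used throughout the validation studies."""
    return [observer_from_rates(task_name, r, **kwargs) for r in REFERENCE_RATES[task_name]]


def study_prior(task: TaskSpec, observer: ObserverState) -> PriorSpec:
    """Weak prior centered on the simulated observer's nominal parameters.

    The validation studies assume the experimenter's initial guess equals
    the design's nominal observer state (the 'weak matched' baseline of
    the prior-sensitivity study), with the weak confidences 1.6 for the
    threshold, 6.1 for the steepness and 2.1 for criterion parameters.
    """
    theta = observer.theta(task)
    marginals = {"tau": (theta["tau"], 1.6), "gamma": (theta["gamma"], 6.1)}
    for name in task.param_names[2:]:
        marginals[name] = (theta[name], 2.1)
    return PriorSpec(marginals)


def observer_probabilities(
    observer: ObserverState, task: TaskSpec, condition: StimulusCondition
) -> np.ndarray:
    """Lapse-adjusted response distribution of the observer for one condition."""
    probs = condition_likelihood(
        task, condition, observer.theta(task), beta=observer.sens.beta
    ).ravel()
    if observer.lapse.epsilon != task.lapse.epsilon:
        # undo the task's assumed lapse, apply the observer's actual one
        eps_t, k = task.lapse.epsilon, task.lapse.n_alternatives
        base = (probs - eps_t / k) / (1.0 - eps_t)
        probs = observer.lapse.epsilon / k + (1.0 - observer.lapse.epsilon) * base
    return probs


def simulate_response(
    observer: ObserverState,
    task: TaskSpec,
    condition: StimulusCondition,
    rng: np.random.Generator,
) -> str:
    """Draw one response label from the observer's response distribution."""
    probs = observer_probabilities(observer, task, condition)
    u = rng.random()
    j = int(np.searchsorted(np.cumsum(probs), u))
    return task.response_labels[min(j, task.n_responses - 1)]


def bias_db(tau_hat, tau_true) -> float:
    """Threshold-estimate bias in dB: 10*log10(tau_hat / tau_true)."""
    tau_hat = np.asarray(tau_hat, dtype=float)
    if np.any(tau_hat <= 0) or tau_true <= 0:
        raise ValueError("thresholds must be positive")
    out = 10.0 * np.log10(tau_hat / tau_true)
    return float(out) if out.ndim == 0 else out


def run_session(
    task: TaskSpec,
    observer: ObserverState,
    n_trials: int,
    seed=None,
    grid: Optional[ParameterGrid] = None,
    prior: Optional[PriorSpec] = None,
    grid_preset: str = "simstudy",
    dtype=np.float64,
) -> AdaptiveSession:
    """Run one complete adaptive session against a simulated observer.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the session
    spawns one child stream for stimulus tie-breaks and one for observer
    responses, so identical seeds reproduce the session bit for bit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tie_seq, obs_seq = seq.spawn(2)
    session = AdaptiveSession(
        task,
        grid=grid,
        prior=prior,
        seed=tie_seq,
        stop_rule=("fixed_trials", n_trials),
        dtype=dtype,
        grid_preset=grid_preset,
    )
    obs_rng = np.random.default_rng(obs_seq)
    while not session.finished:
        cond = session.next_condition()
        resp = simulate_response(observer, task, cond, obs_rng)
        session.observe(cond, resp)
    return session


# ---------------------------------------------------------------------------
# batched replication engine
# ---------------------------------------------------------------------------


@dataclass
class BatchResult:
    """Raw per-replicate traces from one batched (task, observer) cell."""

    task: TaskSpec
    observer: ObserverState
    condition_idx: np.ndarray  # (B, T) int32
    response_idx: np.ndarray  # (B, T) int8
    tau_hat: dict  # trial -> (B,) threshold estimates
    null_rates: dict  # (trial, response/state label) -> (B,) posterior-mean rates
    seed: object


def _null_rate_vectors(task: TaskSpec, grid: ParameterGrid) -> dict:
    """Per-node lapse-adjusted null-response rates used for criterion recovery.

    Returns label -> (N,) vectors: the model response probability at d'=0
    ('Yes|strict', 'Yes|lax' for qYNC; 'Yes', 'No' for qYNR; 'Interval2'
    for qFC; 'Yes' for qYN).
    """
    nodes = grid.node_arrays()
    out = {}
    if task.name == "qYN":
        out["Yes"] = condition_likelihood(task, StimulusCondition(0.0), nodes)[0]
    elif task.name == "qYNC":
        for state in ("strict", "lax"):
            cond = StimulusCondition(0.0, cue_state=state)
            out[f"Yes|{state}"] = condition_likelihood(task, cond, nodes)[0]
    elif task.name == "qYNR":
        probs = condition_likelihood(task, StimulusCondition(0.0), nodes)
        out["Yes"] = probs[0]
        out["No"] = probs[2]
    else:
        probs = condition_likelihood(task, StimulusCondition(0.0), nodes)
        out["Interval2"] = probs[1]
    return out


def _run_batch(
    task: TaskSpec,
    observer: ObserverState,
    n_reps: int,
    n_trials: int,
    seed,
    grid: ParameterGrid,
    prior: PriorSpec,
    record_trials: Sequence[int],
    dtype=np.float32,
    record_null_rates: bool = False,
) -> BatchResult:
    """Vectorised replication of ``n_reps`` independent adaptive sessions.

    Mirrors :func:`run_session` trial for trial: per replicate, one child
    stream breaks selection ties and one drives observer responses, in
    the same draw order, so the batch is a faithful stack of sequential
    sessions (verified against the sequential path in the test suite).
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seqs = seq.spawn(n_reps)
    tie_rngs, obs_rngs = [], []
    for s in rep_seqs:
        t, o = s.spawn(2)
        tie_rngs.append(np.random.default_rng(t.spawn(1)[0]))  # matches AdaptiveSession
        obs_rngs.append(np.random.default_rng(o))

    s_n, r_n, n = task.n_conditions, task.n_responses, grid.n_nodes
    sr = s_n * r_n
    nodes = grid.node_arrays()
    # stacked (N, 2*S*R) Fortran-order matrix: [L | L log L] columns,
    # filled condition by condition to keep peak memory at one copy
    m = np.empty((n, 2 * sr), dtype=dtype, order="F")
    for i, cond in enumerate(task.conditions):
        probs = condition_likelihood(task, cond, nodes)  # (R, N) float64
        for j in range(r_n):
            m[:, i * r_n + j] = probs[j]
            m[:, sr + i * r_n + j] = probs[j] * np.log(probs[j])

    prior_post = build_prior(grid, prior)
    p = np.broadcast_to(prior_post.weights.astype(dtype), (n_reps, n)).copy()
    log10tau = np.log10(grid.node_arrays()["tau"]).astype(dtype)

    true_probs = np.stack(
        [observer_probabilities(observer, task, c) for c in task.conditions]
    )  # (S, R)
    true_cum = np.cumsum(true_probs, axis=1)

    null_vecs = (
        {k: v.astype(dtype) for k, v in _null_rate_vectors(task, grid).items()}
        if record_null_rates
        else {}
    )

    record_set = set(int(t) for t in record_trials)
    cond_idx = np.empty((n_reps, n_trials), dtype=np.int32)
    resp_idx = np.empty((n_reps, n_trials), dtype=np.int8)
    tau_hat, null_rates = {}, {}

    if 0 in record_set:  # prior-only checkpoint
        tau_hat[0] = 10.0 ** (p @ log10tau).astype(float)

    for t in range(1, n_trials + 1):
        g = p @ m  # (B, 2*S*R)
        pred = g[:, :sr].reshape(n_reps, s_n, r_n)
        t1 = g[:, sr:].reshape(n_reps, s_n, r_n)
        scores = (pred * np.log(pred) - t1).sum(axis=2)  # E[H] minus const
        chosen = np.argmin(scores, axis=1)
        for b in range(n_reps):
            row = scores[b]
            ties = np.flatnonzero(row == row[chosen[b]])
            if len(ties) > 1:
                chosen[b] = ties[tie_rngs[b].integers(len(ties))]
        u = np.array([obs_rngs[b].random() for b in range(n_reps)])
        resp = np.empty(n_reps, dtype=np.int8)
        for b in range(n_reps):
            resp[b] = np.searchsorted(true_cum[chosen[b]], u[b])
            if resp[b] >= r_n:
                resp[b] = r_n - 1
            col = chosen[b] * r_n + resp[b]
            p[b] *= m[:, col]
            p[b] /= p[b].sum()
        cond_idx[:, t - 1] = chosen
        resp_idx[:, t - 1] = resp
        if t in record_set:
            tau_hat[t] = 10.0 ** (p @ log10tau).astype(float)
            for label, vec in null_vecs.items():
                null_rates[(t, label)] = (p @ vec).astype(float)

    return BatchResult(task, observer, cond_idx, resp_idx, tau_hat, null_rates, seed)


@dataclass
class StudyResult:
    """Tidy per-(state, checkpoint) accuracy/precision summary.

    ``frame`` columns: task, state, checkpoint, bias_db, sd_db, sd_log10,
    n_reps. ``batches`` holds the raw per-replicate traces keyed by state
    label, for histogram and recovery analyses.
    """

    frame: pd.DataFrame
    batches: dict
    n_reps: int
    seed: object
    tau_true: float


def run_study(
    task_name: str,
    observer_states: Optional[Sequence[ObserverState]] = None,
    n_reps: int = 300,
    checkpoints: Sequence[int] = (10, 25, 50, 100),
    seed=None,
    grid_preset: str = "simstudy-coarse",
    prior: Optional[PriorSpec] = None,
    dtype=np.float32,
    record_null_rates: bool = False,
) -> StudyResult:
    """Replicate adaptive sessions and summarise threshold accuracy/precision.

    Runs ``n_reps`` sessions of ``max(checkpoints)`` trials per observer
    state (default: the task's three reference response states), and
    reports, at each checkpoint, the mean bias in dB and the SD of the
    threshold estimates (in dB and in decimal log units).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    task = make_task(
        task_name,
        stimulus_preset="simstudy" if grid_preset == "simstudy" else "simstudy-coarse",
    )
    states = list(observer_states) if observer_states is not None else reference_states(task_name)
    grid = ParameterGrid.from_preset(task, grid_preset)
    checkpoints = sorted(int(c) for c in checkpoints)
    n_trials = max(checkpoints)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    state_seqs = seq.spawn(len(states))

    rows, batches = [], {}
    for state, sseq in zip(states, state_seqs):
        use_prior = prior or study_prior(task, state)
        batch = _run_batch(
            task,
            state,
            n_reps,
            n_trials,
            sseq,
            grid,
            use_prior,
            record_trials=checkpoints,
            dtype=dtype,
            record_null_rates=record_null_rates,
        )
        batches[state.label] = batch
        for cp in checkpoints:
            log_ratio = np.log10(batch.tau_hat[cp] / state.sens.tau)
            rows.append(
                {
                    "task": task_name,
                    "state": state.label,
                    "checkpoint": cp,
                    "bias_db": float(10.0 * log_ratio.mean()),
                    "sd_db": float(10.0 * log_ratio.std(ddof=1)),
                    "sd_log10": float(log_ratio.std(ddof=1)),
                    "n_reps": n_reps,
                }
            )
    frame = pd.DataFrame(rows)
    return StudyResult(frame, batches, n_reps, seed, states[0].sens.tau)


def stimulus_histograms(
    study: StudyResult,
    checkpoints: Sequence[int] = (10, 25, 50, 100),
) -> pd.DataFrame:
    """Ordinary and cumulative presented-stimulus histograms per state.

    For each state and checkpoint ``t``, counts presentations of each
    condition over the first ``t`` trials of every replicate. Columns:
    task, state, checkpoint, condition (label), contrast, cue_state,
    interval, count, cum_fraction (cumulative over ascending contrast
    within each cue state / interval group).
    """
    rows = []
    for label, batch in study.batches.items():
        task = batch.task
        n_trials = batch.condition_idx.shape[1]
        for cp in checkpoints:
            if cp > n_trials:
                continue
            counts = np.bincount(
                batch.condition_idx[:, :cp].ravel(), minlength=task.n_conditions
            )
            for i, cond in enumerate(task.conditions):
                rows.append(
                    {
                        "task": task.name,
                        "state": label,
                        "checkpoint": cp,
                        "condition": cond.label(),
                        "contrast": cond.contrast,
                        "cue_state": cond.cue_state,
                        "interval": cond.interval,
                        "count": int(counts[i]),
                    }
                )
    frame = pd.DataFrame(rows)
    group_cols = ["task", "state", "checkpoint", "cue_state", "interval"]
    frame = frame.sort_values(group_cols + ["contrast"], kind="stable").reset_index(drop=True)
    grouped = frame.groupby(group_cols, dropna=False)["count"]
    csum = grouped.cumsum()
    totals = grouped.transform("sum")
    frame["cum_fraction"] = np.where(totals > 0, csum / totals, 0.0)
    return frame


def criterion_recovery(
    task_name: str,
    observer_states: Optional[Sequence[ObserverState]] = None,
    n_reps: int = 300,
    at_trial: int = 25,
    seed=None,
    grid_preset: str = "simstudy-coarse",
    dtype=np.float32,
) -> pd.DataFrame:
    """Recovered null-stimulus response probabilities (d' = 0 behaviour).

    Returns per state the replicate-mean posterior-mean response rate to
    the null stimulus, alongside the generating observer's true rate.
    """
    study = run_study(
        task_name,
        observer_states,
        n_reps=n_reps,
        checkpoints=(at_trial,),
        seed=seed,
        grid_preset=grid_preset,
        dtype=dtype,
        record_null_rates=True,
    )
    rows = []
    for label, batch in study.batches.items():
        task = batch.task
        true_vals = {}
        theta = batch.observer.theta(task)
        if task.name == "qYNC":
            for state in ("strict", "lax"):
                cond = StimulusCondition(0.0, cue_state=state)
                true_vals[f"Yes|{state}"] = float(
                    condition_likelihood(task, cond, theta)[0]
                )
        elif task.name == "qYNR":
            probs = condition_likelihood(task, StimulusCondition(0.0), theta)
            true_vals["Yes"], true_vals["No"] = float(probs[0]), float(probs[2])
        elif task.name == "qFC":
            true_vals["Interval2"] = float(
                condition_likelihood(task, StimulusCondition(0.0), theta)[1]
            )
        else:
            true_vals["Yes"] = float(
                condition_likelihood(task, StimulusCondition(0.0), theta)[0]
            )
        for (t, resp_label), vals in batch.null_rates.items():
            rows.append(
                {
                    "task": task_name,
                    "state": label,
                    "trial": t,
                    "response": resp_label,
                    "recovered_rate": float(np.mean(vals)),
                    "true_rate": true_vals[resp_label],
                }
            )
    return pd.DataFrame(rows)


#: The four threshold-prior variants of the prior-sensitivity study:
#: (label, tau prior mode, tau prior confidence).
PRIOR_VARIANTS = (
    ("weak matched", 0.10, 1.6),
    ("weak mismatched", 0.009, 1.6),
    ("strict matched", 0.10, 11.5),
    ("strict mismatched", 0.009, 11.5),
)


def prior_mismatch_study(
    prior_variants=PRIOR_VARIANTS,
    n_reps: int = 300,
    n_trials: int = 50,
    seed=None,
    grid_preset: str = "simstudy-coarse",
    dtype=np.float32,
    observer: Optional[ObserverState] = None,
) -> pd.DataFrame:
    """Mean threshold-estimate trajectory under different threshold priors.

    The observer is the intermediate reference state (tau = 10%, gamma = 2,
    FA = 10%); the gamma and criterion priors are held at (2.0, 6.1) and
    (1, 2.1) across variants. Returns tidy rows (variant, trial,
    mean_tau, bias_db, sd_db).
    """
    task = make_task(
        "qYN", stimulus_preset="simstudy" if grid_preset == "simstudy" else "simstudy-coarse"
    )
    grid = ParameterGrid.from_preset(task, grid_preset)
    obs = observer or observer_from_rates("qYN", {"fa": 0.10})
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for (label, mode, conf), vseq in zip(prior_variants, seq.spawn(len(prior_variants))):
        prior = PriorSpec({"tau": (mode, conf), "gamma": (2.0, 6.1), "lam": (1.0, 2.1)})
        batch = _run_batch(
            task,
            obs,
            n_reps,
            n_trials,
            vseq,
            grid,
            prior,
            record_trials=range(1, n_trials + 1),
            dtype=dtype,
        )
        for t in range(1, n_trials + 1):
            log_ratio = np.log10(batch.tau_hat[t] / obs.sens.tau)
            rows.append(
                {
                    "variant": label,
                    "trial": t,
                    "mean_tau": float(np.exp(np.log(batch.tau_hat[t]).mean())),
                    "bias_db": float(10.0 * log_ratio.mean()),
                    "sd_db": float(10.0 * log_ratio.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
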
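"""Joint SDT model fitting for method-of-constant-stimuli (MCS) data.

The MCS presents a fixed set of stimulus conditions many times each (the
validation study used 50 trials per condition across four detection
tasks) and serves as the slow, assumption-light baseline against which
the adaptive methods are validated. This module fits, by maximum
likelihood, the unified SDT model in which a *single* d' psychometric
function (shared threshold tau and steepness gamma; asymptote beta = 5
and lapse epsilon = 2% held fixed) accounts for every task, with
task-specific decision criteria: one each for simple and forced-choice
detection and a (strict, delta) pair each for cued and rated detection
-- up to six criteria when all four tasks are present.

Goodness of fit uses a parametric-bootstrap deviance test against the
saturated multinomial model: tables are simulated at the fitted
parameters, refitted, and the observed deviance is ranked among the
replicate deviances. Parameter variability is estimated the same way
(SD of replicate estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtri

from .sdt import DEFAULT_BETA
from .tasks import StimulusCondition, condition_likelihood, make_task

__all__ = [
    "MCS_TASKS",
    "mcs_conditions",
    "simulate_mcs_table",
    "JointSdtFit",
    "joint_nll",
    "deviance",
    "fit",
    "bootstrap_gof",
    "bootstrap_se",
]

MCS_TASKS = ("qYN", "qYNC", "qYNR", "qFC")

#: Criterion parameters contributed by each task to the joint model.
_TASK_CRITERIA = {
    "qYN": ("lam_simple",),
    "qYNC": ("lam_strict_cued", "delta_cued"),
    "qYNR": ("lam_strict_rated", "delta_rated"),
    "qFC": ("lam_fc",),
}

_REQUIRED_COLUMNS = ("task", "condition_id", "contrast", "response", "count")


def mcs_conditions(task_name: str) -> list:
    """The constant-stimuli condition set of the validation design.

    YN tasks: null contrast plus seven log-linear levels from 8 to 60%
    (doubled over cue states for cued detection). Forced choice: five
    log-linear levels in each interval plus the both-blank condition.
    """
    yn_levels = np.concatenate([[0.0], np.geomspace(0.08, 0.60, 7)])
    if task_name in ("qYN", "qYNR"):
        return [StimulusCondition(c) for c in yn_levels]
    if task_name == "qYNC":
        return [
            StimulusCondition(c, cue_state=state)
            for state in ("lax", "strict")
            for c in yn_levels
        ]
    if task_name == "qFC":
        fc_levels = np.geomspace(0.08, 0.60, 5)
        conds = [StimulusCondition(c, interval=1) for c in fc_levels]
        conds.append(StimulusCondition(0.0))
        conds += [StimulusCondition(c, interval=2) for c in fc_levels]
        return conds
    raise ValueError(f"unknown task {task_name!r}")


@lru_cache(maxsize=None)
def _task_template(task_name: str):
    # stimulus levels are irrelevant here; conditions are supplied explicitly
    return make_task(task_name, contrasts=np.array([0.5]))


def _cell_probabilities(task_name: str, condition: StimulusCondition, params: dict) -> np.ndarray:
    """Model response distribution for one MCS cell under the joint fit."""
    task = _task_template(task_name)
    theta = {"tau": params["tau"], "gamma": params["gamma"]}
    if task_name == "qYN":
        theta["lam"] = params["lam_simple"]
    elif task_name == "qYNC":
        theta["lam_strict"] = params["lam_strict_cued"]
        theta["delta_lam"] = params["delta_cued"]
    elif task_name == "qYNR":
        theta["lam_strict"] = params["lam_strict_rated"]
        theta["delta_lam"] = params["delta_rated"]
    else:
        theta["lam_fc"] = params["lam_fc"]
    return condition_likelihood(
        task, condition, theta, beta=params.get("beta", DEFAULT_BETA)
    ).ravel()


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table is missing columns {missing}")
    if len(table) and (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    unknown = set(table["task"].unique()) - set(MCS_TASKS) if len(table) else set()
    if unknown:
        raise ValueError(f"unknown tasks in table: {sorted(unknown)}")
    return table


def _iter_cells(table: pd.DataFrame):
    """Yield (task_name, condition, responses, counts) per condition cell."""
    for (task_name, cond_id), cell in table.groupby(["task", "condition_id"], sort=True):
        contrast = float(cell["contrast"].iloc[0])
        cue_state = None
        if "cue_state" in cell.columns:
            v = cell["cue_state"].iloc[0]
            cue_state = None if pd.isna(v) else str(v)
        interval = None
        if "interval" in cell.columns:
            v = cell["interval"].iloc[0]
            interval = None if pd.isna(v) else int(v)
        cond = StimulusCondition(contrast, cue_state=cue_state, interval=interval)
        yield task_name, cond, list(cell["response"]), cell["count"].to_numpy(float)


def simulate_mcs_table(
    params: dict,
    n_per_condition: int = 50,
    tasks: Sequence[str] = MCS_TASKS,
    seed=None,
) -> pd.DataFrame:
    """Simulate a full constant-stimuli count table at given joint parameters.

    ``params`` holds tau, gamma and the criteria of the requested tasks
    (see :data:`_TASK_CRITERIA`); each condition receives
    ``n_per_condition`` multinomial trials.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for task_name in tasks:
        task = _task_template(task_name)
        for cond_id, cond in enumerate(mcs_conditions(task_name)):
            probs = _cell_probabilities(task_name, cond, params)
            counts = rng.multinomial(n_per_condition, probs)
            for resp, k in zip(task.response_labels, counts):
                rows.append(
                    {
                        "task": task_name,
                        "condition_id": cond_id,
                        "contrast": cond.contrast,
                        "cue_state": cond.cue_state,
                        "interval": cond.interval,
                        "response": resp,
                        "count": int(k),
                    }
                )
    return pd.DataFrame(rows)


def _compile_cells(table: pd.DataFrame) -> list:
    """Pre-resolve (task, condition, response indices, counts) per cell."""
    cells = []
    for task_name, cond, responses, counts in _iter_cells(table):
        task = _task_template(task_name)
        idx = np.array([task.response_index(r) for r in responses])
        cells.append((task_name, cond, idx, counts))
    return cells


def _nll_compiled(params: dict, cells: list) -> float:
    total = 0.0
    for task_name, cond, idx, counts in cells:
        probs = _cell_probabilities(task_name, cond, params)
        total -= float(counts @ np.log(probs[idx]))
    return total


def joint_nll(params: dict, table: pd.DataFrame) -> float:
    """Negative log-likelihood of the joint SDT model on a count table.

    Sum over all (condition, response) cells of -count * log(model
    probability); the lapse floor keeps model probabilities positive, so
    the result is finite for any admissible parameter vector.
    """
    _validate_table(table)
    return _nll_compiled(params, _compile_cells(table))


@dataclass
class JointSdtFit:
    """Result of the joint maximum-likelihood fit."""

    params: dict
    nll: float
    converged: bool
    n_params: int
    tasks: tuple
    n_restarts: int = 1

    def __getitem__(self, key):
        return self.params[key]


def _param_layout(tasks: Sequence[str]):
    names = ["tau", "gamma"]
    for t in MCS_TASKS:
        if t in tasks:
            names += list(_TASK_CRITERIA[t])
    return names


_BOUNDS = {
    "tau": (-3.2, -0.01),  # log10 tau
    "gamma": (np.log10(0.25), np.log10(12.0)),  # log10 gamma
    "lam_simple": (-3.0, 4.0),
    "lam_strict_cued": (-3.0, 4.0),
    "delta_cued": (0.0, 3.0),
    "lam_strict_rated": (-3.0, 4.0),
    "delta_rated": (0.0, 3.0),
    "lam_fc": (-3.0, 3.0),
}


def _to_vector(params: dict, names) -> np.ndarray:
    x = []
    for n in names:
        v = params[n]
        x.append(np.log10(v) if n in ("tau", "gamma") else v)
    return np.array(x, dtype=float)


def _to_params(x: np.ndarray, names) -> dict:
    out = {}
    for n, v in zip(names, x):
        out[n] = float(10.0**v) if n in ("tau", "gamma") else float(v)
    return out


def _heuristic_start(table: pd.DataFrame, names) -> dict:
    """Data-driven initial point: criteria from observed null-response rates."""
    start = {"tau": 0.1, "gamma": 2.0}

    def null_rate(task_name, response, cue_state=None):
        sub = table[(table["task"] == task_name) & (table["contrast"] == 0.0)]
        if cue_state is not None and "cue_state" in sub.columns:
            sub = sub[sub["cue_state"] == cue_state]
        total = sub["count"].sum()
        if total == 0:
            return None
        k = sub[sub["response"] == response]["count"].sum()
        return min(max(k / total, 0.01), 0.99)

    if "lam_simple" in names:
        fa = null_rate("qYN", "Yes")
        start["lam_simple"] = float(ndtri(1 - fa)) if fa is not None else 1.0
    if "lam_strict_cued" in names:
        fa_s = null_rate("qYNC", "Yes", "strict")
        fa_l = null_rate("qYNC", "Yes", "lax")
        ls = float(ndtri(1 - fa_s)) if fa_s is not None else 1.5
        ll = float(ndtri(1 - fa_l)) if fa_l is not None else 1.0
        start["lam_strict_cued"] = ls
        start["delta_cued"] = max(ls - ll, 0.0)
    if "lam_strict_rated" in names:
        yes = null_rate("qYNR", "Yes")
        no = null_rate("qYNR", "No")
        ls = float(ndtri(1 - yes)) if yes is not None else 1.5
        ll = float(ndtri(no)) if no is not None else 1.0
        start["lam_strict_rated"] = ls
        start["delta_rated"] = max(ls - ll, 0.0)
    if "lam_fc" in names:
        i2 = null_rate("qFC", "Interval2")
        start["lam_fc"] = float(ndtri(1 - i2)) if i2 is not None else 0.0
    return start


def fit(table: pd.DataFrame, n_restarts: int = 8, seed=None) -> JointSdtFit:
    """Maximum-likelihood joint fit with seeded multi-start L-BFGS-B.

    Optimisation runs in transformed coordinates (log10 tau, log10 gamma,
    raw criteria with delta >= 0 box constraints). The first start is a
    data-driven heuristic; the rest jitter it. The best converged restart
    is returned; if no restart converges, the best point is returned with
    ``converged=False``.
    """
    _validate_table(table)
    if len(table) == 0:
        raise ValueError("count table is empty")
    tasks = tuple(t for t in MCS_TASKS if t in set(table["task"]))
    names = _param_layout(tasks)
    bounds = [_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)
    cells = _compile_cells(table)

    def objective(x):
        return _nll_compiled(_to_params(x, names), cells)

    x0 = np.clip(
        _to_vector(_heuristic_start(table, names), names),
        [b[0] for b in bounds],
        [b[1] for b in bounds],
    )
    starts = [x0]
    for _ in range(max(n_restarts - 1, 0)):
        jitter = rng.normal(scale=0.3, size=len(names))
        starts.append(
            np.clip(x0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds])
        )

    best, best_ok = None, False
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        if best is None or (res.success and not best_ok) or (
            res.success == best_ok and res.fun < best.fun
        ):
            best, best_ok = res, bool(res.success)
    return JointSdtFit(
        params=_to_params(best.x, names),
        nll=float(best.fun),
        converged=best_ok,
        n_params=len(names),
        tasks=tasks,
        n_restarts=n_restarts,
    )


def _saturated_nll(table: pd.DataFrame) -> float:
    """NLL of the saturated multinomial model (p_hat = k/n per cell)."""
    total = 0.0
    for _, _, _, counts in _iter_cells(table):
        n = counts.sum()
        if n == 0:
            continue
        k = counts[counts > 0]
        total -= float(k @ np.log(k / n))
    return total


def deviance(fit_result: JointSdtFit, table: pd.DataFrame) -> float:
    """2 * (model NLL - saturated NLL); zero for a perfect fit."""
    return 2.0 * (joint_nll(fit_result.params, table) - _saturated_nll(table))


def _boot_tables(fit_result: JointSdtFit, table: pd.DataFrame, n_boot: int, rng):
    """Parametric-bootstrap tables at the fitted parameters, matching cell totals."""
    for _ in range(n_boot):
        rows = []
        for task_name, cond, responses, counts in _iter_cells(table):
            task = _task_template(task_name)
            probs = _cell_probabilities(task_name, cond, fit_result.params)
            draw = rng.multinomial(int(counts.sum()), probs)
            base = {
                "task": task_name,
                "contrast": cond.contrast,
                "cue_state": cond.cue_state,
                "interval": cond.interval,
            }
            cond_id = f"{cond.label()}"
            for resp, k in zip(task.response_labels, draw):
                rows.append({**base, "condition_id": cond_id, "response": resp, "count": int(k)})
        yield pd.DataFrame(rows)


def bootstrap_gof(
    fit_result: JointSdtFit,
    table: pd.DataFrame,
    n_boot: int = 200,
    seed=None,
    refit_restarts: int = 1,
) -> float:
    """Parametric-bootstrap goodness-of-fit p-value.

    p is the fraction of bootstrap replicates (simulated at the fitted
    model, then refitted) whose deviance meets or exceeds the observed
    deviance; small p rejects the unified-sensitivity model.
    """
    if not fit_result.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is small; the bootstrap p-value will be coarse",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    d_obs = deviance(fit_result, table)
    exceed = 0
    for boot in _boot_tables(fit_result, table, n_boot, rng):
        boot_fit = fit(boot, n_restarts=refit_restarts, seed=rng.integers(2**31 - 1))
        if deviance(boot_fit, boot) >= d_obs:
            exceed += 1
    return exceed / n_boot


def bootstrap_se(
    fit_result: JointSdtFit,
    table: pd.DataFrame,
    n_boot: int = 100,
    seed=None,
    refit_restarts: int = 1,
) -> dict:
    """Parametric-bootstrap standard errors (SD of replicate estimates).

    tau and gamma SEs are reported on the log10 scale (so tau's SE in
    decimal log units is 10x smaller than in dB); criteria on their raw
    scale. Degenerate zero-variance replicate sets raise rather than
    silently returning 0.
    """
    rng = np.random.default_rng(seed)
    reps = {name: [] for name in fit_result.params}
    for boot in _boot_tables(fit_result, table, n_boot, rng):
        boot_fit = fit(boot, n_restarts=refit_restarts, seed=rng.integers(2**31 - 1))
        for name, v in boot_fit.params.items():
            reps[name].append(np.log10(v) if name in ("tau", "gamma") else v)
    out = {}
    for name, vals in reps.items():
        sd = float(np.std(vals, ddof=1))
        out[name] = sd
    if all(v < 1e-12 for v in out.values()):
        raise ValueError(
            "bootstrap produced zero-variance estimates; responses are degenerate"
        )
    return out
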
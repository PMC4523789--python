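"""Configuration and session persistence.

Run configurations round-trip through YAML or JSON; session logs are
written as a plain CSV of trials plus a JSON sidecar carrying the config
snapshot, the final estimate summary, the package version and a config
hash, so the CSV stays purely tabular. Contrast values are serialised as
decimal fractions; strings with a ``%`` suffix are accepted on input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import AdaptiveSession, ParameterGrid, PriorSpec
from .tasks import TASK_NAMES

__all__ = [
    "RunConfig",
    "SessionRecord",
    "load_config",
    "save_config",
    "write_session",
    "read_session",
    "parse_contrast",
    "db_from_ratio",
]

_CONFIG_FIELDS = {
    "task",
    "grid_preset",
    "stimulus_preset",
    "prior",
    "grid",
    "stop_rule",
    "seed",
    "ci_level",
    "n_trials",
}


def parse_contrast(value) -> float:
    """Accept a decimal fraction or a percent string ('12%')."""
    if isinstance(value, str) and value.strip().endswith("%"):
        return float(value.strip()[:-1]) / 100.0
    return float(value)


def db_from_ratio(ratio: float) -> float:
    """10*log10 of a contrast ratio (1 dB = 0.1 decimal log units)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return 10.0 * float(np.log10(ratio))


@dataclass
class RunConfig:
    """Validated configuration of one adaptive run."""

    task: str
    grid_preset: str = "simstudy"
    stimulus_preset: Optional[str] = None
    prior: Optional[dict] = None  # name -> [mode, confidence]
    grid: Optional[dict] = None  # name -> explicit samples (overrides preset)
    stop_rule: tuple = ("fixed_trials", 50)
    seed: Optional[int] = None
    ci_level: float = 0.682

    def __post_init__(self) -> None:
        if self.task not in TASK_NAMES:
            raise ValueError(f"field 'task': unknown task {self.task!r}")
        if self.stimulus_preset is None:
            self.stimulus_preset = (
                "simstudy-coarse" if self.grid_preset == "simstudy-coarse" else "simstudy"
            )
        kind, value = tuple(self.stop_rule)
        if kind not in ("fixed_trials", "ci_width"):
            raise ValueError(f"field 'stop_rule': unknown rule {kind!r}")
        self.stop_rule = (kind, float(value) if kind == "ci_width" else int(value))
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("field 'ci_level': must lie in (0, 1)")
        if self.prior is not None:
            for name, pair in self.prior.items():
                if len(pair) != 2:
                    raise ValueError(
                        f"field 'prior.{name}': expected [mode, confidence]"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stop_rule"] = list(self.stop_rule)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        data = dict(data)
        n_trials = data.pop("n_trials", None)  # alias for a fixed-trials stop rule
        if n_trials is not None and "stop_rule" not in data:
            data["stop_rule"] = ("fixed_trials", int(n_trials))
        if "stop_rule" in data:
            data["stop_rule"] = tuple(data["stop_rule"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def make_session(self) -> AdaptiveSession:
        from .tasks import make_task

        task = make_task(self.task, stimulus_preset=self.stimulus_preset)
        grid = (
            ParameterGrid({k: np.asarray(v, float) for k, v in self.grid.items()})
            if self.grid
            else ParameterGrid.from_preset(task, self.grid_preset)
        )
        prior = (
            PriorSpec({k: (parse_contrast(m) if k == "tau" else float(m), float(c))
                       for k, (m, c) in self.prior.items()})
            if self.prior
            else None
        )
        return AdaptiveSession(
            task,
            grid=grid,
            prior=prior,
            seed=self.seed,
            stop_rule=self.stop_rule,
            ci_level=self.ci_level,
        )


def load_config(path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    if "task" not in data:
        raise ValueError("field 'task': missing (one of %s)" % (TASK_NAMES,))
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class SessionRecord:
    """An ordered adaptive-session log plus its config and final summary."""

    config: dict
    trials: pd.DataFrame
    summary: dict

    @classmethod
    def from_session(cls, session: AdaptiveSession, config: Optional[RunConfig] = None):
        rows = []
        for t in session.trials:
            row = {
                "trial_index": t.index,
                "contrast": t.condition.contrast,
                "cue_state": t.condition.cue_state if t.condition.cue_state is not None else np.nan,
                "interval": t.condition.interval if t.condition.interval is not None else np.nan,
                "signed_contrast": t.condition.signed_contrast,
                "response": t.response,
                "entropy": t.entropy,
            }
            for name, v in t.estimates.items():
                row[f"est_{name}"] = v
            for name, (lo, hi) in t.ci.items():
                row[f"ci_lo_{name}"] = lo
                row[f"ci_hi_{name}"] = hi
            rows.append(row)
        summ = session.estimate()
        return cls(
            config=config.to_dict() if config else {"task": session.task.name},
            trials=pd.DataFrame(rows),
            summary={
                "estimates": summ.estimates,
                "ci": {k: list(v) for k, v in summ.ci.items()},
                "ci_level": summ.ci_level,
                "entropy": summ.entropy,
            },
        )


def write_session(record: SessionRecord, csv_path) -> None:
    """Write the trial log as CSV with a JSON sidecar (.json next to it)."""
    csv_path = Path(csv_path)
    record.trials.to_csv(csv_path, index=False)
    cfg = RunConfig.from_dict(record.config) if "task" in record.config else None
    sidecar = {
        "version": __version__,
        "config": record.config,
        "config_hash": cfg.config_hash() if cfg else None,
        "n_trials": int(len(record.trials)),
        "summary": record.summary,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_session(csv_path) -> SessionRecord:
    """Read a session written by :func:`write_session`; checks completeness."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing session sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    try:
        trials = pd.read_csv(csv_path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed session CSV {csv_path}: {err}") from err
    if len(trials) != sidecar["n_trials"]:
        raise ValueError(
            f"session CSV truncated: {len(trials)} trials, sidecar records "
            f"{sidecar['n_trials']}"
        )
    if len(trials) and not (trials["trial_index"] == np.arange(1, len(trials) + 1)).all():
        raise ValueError("trial indices are not contiguous from 1")
    return SessionRecord(config=sidecar["config"], trials=trials, summary=sidecar["summary"])
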
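"""Events tables, run configuration and result serialization.

Events follow the BIDS events convention: a tab-separated table with
columns onset, duration, trial_type, response, response_time; missing
values are written as "n/a".  Onsets are seconds from the first
retained volume (steady state), times are seconds, responses are finger
indices 1-4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .units import Trial

__all__ = [
    "EVENTS_COLUMNS",
    "read_events",
    "write_events",
    "trials_to_events",
    "events_to_trials",
    "RunConfig",
]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "response",
                  "response_time"]
NA = "n/a"


def trials_to_events(trials, duration: float = 1.0) -> pd.DataFrame:
    """Trial list -> BIDS-style events frame (null trials keep n/a cells)."""
    rows = []
    for t in trials:
        rows.append({
            "onset": t.onset,
            "duration": duration,
            "trial_type": t.condition,
            "response": t.response if t.response is not None else NA,
            "response_time": t.rt if t.rt is not None else NA,
        })
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def events_to_trials(table: pd.DataFrame) -> list:
    trials = []
    for _, row in table.iterrows():
        resp = row["response"]
        rt = row["response_time"]
        trials.append(Trial(
            onset=float(row["onset"]),
            condition=str(row["trial_type"]),
            response=None if _is_na(resp) else int(resp),
            rt=None if _is_na(rt) else float(rt),
        ))
    return trials


def _is_na(v) -> bool:
    return (isinstance(v, str) and v == NA) or pd.isna(v)


def write_events(table, path) -> None:
    """Write an events table (or Trial list) as tab-separated text."""
    if not isinstance(table, pd.DataFrame):
        table = trials_to_events(table)
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_events(path) -> pd.DataFrame:
    """Read and validate a BIDS-style events TSV."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    for col in EVENTS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    rt = pd.to_numeric(df["response_time"], errors="coerce")
    bad = df.index[(~rt.isna()) & (rt <= 0)]
    if len(bad):
        raise ValueError(f"non-positive response_time at row {bad[0] + 1}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be non-decreasing")
    df["response_time"] = rt
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    # normalize to the canonical missing marker for round-trip identity
    df["response"] = df["response"].astype("Int64")
    return df[EVENTS_COLUMNS + [c for c in df.columns
                                if c not in EVENTS_COLUMNS]]


@dataclass
class RunConfig:
    """Flat configuration for a reproducible run.

    Every field has a default; unknown keys in a config file are
    rejected so typos cannot silently fall back to defaults.
    """

    # generative model (see simulate.RaceSimConfig)
    mu_chosen: float = 1.7
    mu_specified: float = 1.9
    sigma_rate: float = 0.3
    between_subject_sd: float = 0.1
    k: int = 4
    n_trials: int = 123
    soa: float = 2.5
    proportions: tuple = (1 / 3, 1 / 3, 1 / 3)
    repetition_suppression: float = 0.021
    error_rate: float = 0.0
    tr: float = 2.0
    theta: float = 1.0
    first_move_variant: bool = False
    # BOLD ground truth
    beta_task: float = 1.0
    beta_eaa: float = 1.0
    beta_cvs: float = 0.0
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    # analysis
    model_id: int = 1
    fit_mode: str = "direct"
    n_perm: int = 5000
    fdr_q: float = 0.05
    seed: int | None = None  # stochastic commands refuse to run without one

    _TUPLE_FIELDS = ("proportions",)

    def to_file(self, path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in self._TUPLE_FIELDS:
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            kwargs[key] = cls._parse(key, val)
        return cls(**kwargs)

    @classmethod
    def _parse(cls, key, val):
        f = {f.name: f for f in fields(cls)}[key]
        if key == "seed":
            return None if val == "None" else int(val)
        if key in cls._TUPLE_FIELDS:
            return tuple(float(eval(x, {"__builtins__": {}}))
                         if "/" in x else float(x)
                         for x in val.split(","))
        if f.type == "bool" or isinstance(f.default, bool):
            return val.lower() in ("1", "true", "yes")
        if isinstance(f.default, int):
            return int(val)
        if isinstance(f.default, float):
            return float(val)
        return val

    def sim_config(self):
        from .simulate import RaceSimConfig
        return RaceSimConfig(
            mu_chosen=self.mu_chosen, mu_specified=self.mu_specified,
            sigma_rate=self.sigma_rate,
            between_subject_sd=self.between_subject_sd, k=self.k,
            n_trials=self.n_trials, soa=self.soa,
            proportions=self.proportions,
            repetition_suppression=self.repetition_suppression,
            error_rate=self.error_rate, tr=self.tr, theta=self.theta,
            seed=self.seed, first_move_variant=self.first_move_variant)

    def bold_truth(self):
        from .simulate import BoldGroundTruth
        betas = {"TASK": self.beta_task, "EAA": self.beta_eaa,
                 "CvS": self.beta_cvs}
        return BoldGroundTruth(betas=betas, ar1_rho=self.ar1_rho,
                               noise_sd=self.noise_sd,
                               drift_amplitude=self.drift_amplitude)

    def dump_json(self, path) -> None:
        d = asdict(self)
        d["proportions"] = list(d["proportions"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
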
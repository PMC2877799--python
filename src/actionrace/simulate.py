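"""Synthetic experiments with known ground truth.

Generates the three layers the analysis consumes: a randomized trial
schedule (chosen / specified / null in fixed proportions at a constant
stimulus onset asynchrony), race-driven behaviour (responses and RTs
produced by the same accumulator model the analysis assumes, including
a repetition-suppression bias on the previously chosen unit), and BOLD
time series equal to design x known betas plus slow drift and AR(1)
noise.

Default condition mean rates are 1.7 Hz (chosen) and 1.9 Hz
(specified) with a 0.1 Hz between-subject SD.  These are targets for
the *observed* mean reciprocal RT per condition; on chosen trials the
observed speed is the maximum of k unit rates, so the generator places
the unit-level mean a_k standard deviations lower.  Trials come in thirds of
123 at a 2.5 s onset asynchrony with a 2 s volume time.  The default
repetition-suppression decrement of 0.021 Hz makes the model repeat the
previous choice at ~93% of the 4-choice chance rate (the decrement is
the root of P(suppressed unit wins) = 0.93/4 under the race with
sigma = 0.3 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .units import DecisionUnitParams, Trial
from .race import max_normal_moments, simulate_race

__all__ = [
    "RaceSimConfig",
    "BoldGroundTruth",
    "SubjectBehaviour",
    "generate_schedule",
    "generate_subject",
    "generate_bold",
]


@dataclass
class RaceSimConfig:
    """Full generative recipe for one synthetic experiment."""

    mu_chosen: float = 1.7          # mean chosen drift rate (Hz)
    mu_specified: float = 1.9       # mean specified drift rate (Hz)
    sigma_rate: float = 0.3         # within-subject trial-to-trial rate SD (Hz)
    between_subject_sd: float = 0.1  # SD of subject-level mean rates (Hz)
    k: int = 4                      # competitors on chosen trials
    n_trials: int = 123
    soa: float = 2.5                # stimulus onset asynchrony (s)
    proportions: tuple = (1 / 3, 1 / 3, 1 / 3)  # chosen, specified, null
    repetition_suppression: float = 0.021  # rate decrement on prev. choice (Hz)
    error_rate: float = 0.0         # wrong-finger rate on specified trials
    tr: float = 2.0                 # volume repetition time (s)
    theta: float = 1.0
    seed: int | None = None
    first_move_variant: bool = False  # follow-up design with flagged singles

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.soa <= 0:
            raise ValueError("soa must be > 0")
        counts = [p * self.n_trials for p in self.proportions]
        if any(abs(c - round(c)) > 1e-6 for c in counts):
            raise ValueError(
                f"n_trials={self.n_trials} is not divisible by the "
                f"proportions {self.proportions}")

    @property
    def condition_counts(self) -> dict:
        names = ("chosen", "specified", "null")
        return {n: int(round(p * self.n_trials))
                for n, p in zip(names, self.proportions)}

    @property
    def n_volumes(self) -> int:
        """Volumes needed to cover the schedule plus hemodynamic decay."""
        return int(np.ceil((self.n_trials * self.soa + 30.0) / self.tr))


@dataclass
class BoldGroundTruth:
    """Signal and noise parameters for synthetic BOLD."""

    betas: dict = field(default_factory=dict)  # regressor name -> effect size
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0

    def __post_init__(self):
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SubjectBehaviour:
    """One synthetic subject: filled trials plus generating parameters."""

    trials: list
    params_chosen: DecisionUnitParams
    params_specified: DecisionUnitParams
    roles: list | None = None  # first-move variant trial roles

    @property
    def truth(self) -> dict:
        a_k, _ = max_normal_moments(self.params_chosen.k)
        return {
            "mu_chosen_unit": self.params_chosen.mu,
            "mu_chosen_observed": self.params_chosen.mu
            + a_k * self.params_chosen.sigma,
            "mu_specified": self.params_specified.mu,
            "sigma_rate": self.params_chosen.sigma,
            "k": self.params_chosen.k,
            "theta": self.params_chosen.theta,
        }


def generate_schedule(cfg: RaceSimConfig, rng=None) -> list:
    """Randomized trial schedule: onsets 0, soa, 2*soa, ... with the
    configured condition proportions uniformly shuffled."""
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    labels = []
    for name, count in cfg.condition_counts.items():
        labels += [name] * count
    labels = np.array(labels)
    rng.shuffle(labels)
    return [Trial(onset=i * cfg.soa, condition=c)
            for i, c in enumerate(labels)]


def _assign_roles(trials, first_condition, cfg, rng):
    """Tag a follow-up-design schedule: the first responsive trial takes
    the given condition, and one isolated chosen and one isolated
    specified trial later in the run are flagged as single-trial events;
    every other responsive trial is pooled."""
    roles = ["null" if t.condition == "null" else "other" for t in trials]
    responsive = [i for i, t in enumerate(trials) if t.condition != "null"]
    first = responsive[0]
    trials[first].condition = first_condition
    roles[first] = "first"
    # isolated singles 2-4 min into the run
    lo, hi = 120.0, 240.0
    window = [i for i in responsive[1:] if lo <= trials[i].onset <= hi]
    if len(window) < 2:
        window = responsive[1:]
    chosen_pool = [i for i in window if trials[i].condition == "chosen"]
    spec_pool = [i for i in window if trials[i].condition == "specified"]
    if chosen_pool:
        roles[rng.choice(chosen_pool)] = "later_chosen"
    if spec_pool:
        roles[rng.choice(spec_pool)] = "later_specified"
    return roles


def generate_subject(cfg: RaceSimConfig, rng=None,
                     first_condition: str | None = None) -> SubjectBehaviour:
    """Simulate one subject's behaviour with the race model.

    Subject-level mean rates are drawn around the condition means with
    SD ``between_subject_sd``.  Specified trials run a k = 1 race for a
    uniformly cued finger; chosen trials run a k = 4 race with the unit
    matching the previous chosen response handicapped by the
    repetition-suppression decrement.  Optional errors turn a specified
    trial into an error trial with a uniformly wrong response.
    """
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    trials = generate_schedule(cfg, rng)
    roles = None
    if cfg.first_move_variant:
        if first_condition is None:
            first_condition = ("chosen", "specified")[rng.integers(2)]
        roles = _assign_roles(trials, first_condition, cfg, rng)

    mu_c = cfg.mu_chosen + cfg.between_subject_sd * rng.standard_normal()
    mu_s = cfg.mu_specified + cfg.between_subject_sd * rng.standard_normal()
    # cfg means are targets for the OBSERVED mean reciprocal RT; on chosen
    # trials the observed rate is the maximum of k unit rates, so the
    # unit-level mean sits a_k standard deviations below the target
    # (otherwise chosen responses would come out faster than specified,
    # the opposite of what free-choice behaviour shows).
    a_k, _ = max_normal_moments(cfg.k)
    p_chosen = DecisionUnitParams(mu=mu_c - a_k * cfg.sigma_rate,
                                  sigma=cfg.sigma_rate,
                                  theta=cfg.theta, k=cfg.k)
    p_spec = DecisionUnitParams(mu=mu_s, sigma=cfg.sigma_rate,
                                theta=cfg.theta, k=1)

    prev_choice = None
    for t in trials:
        if t.condition == "null":
            continue
        if t.condition == "specified":
            cue = int(rng.integers(1, 5))
            draw = simulate_race(p_spec, rng=rng)
            t.rt = draw.rt
            t.response = cue
            if cfg.error_rate > 0 and rng.random() < cfg.error_rate:
                wrong = [f for f in (1, 2, 3, 4) if f != cue]
                t.response = int(rng.choice(wrong))
                t.condition = "error"
        else:  # chosen
            bias = np.zeros(cfg.k)
            if prev_choice is not None and cfg.repetition_suppression > 0:
                bias[prev_choice - 1] = -cfg.repetition_suppression
            draw = simulate_race(p_chosen, bias=bias, rng=rng)
            t.rt = draw.rt
            t.response = draw.winner_index + 1
            prev_choice = t.response
    return SubjectBehaviour(trials=trials, params_chosen=p_chosen,
                            params_specified=p_spec, roles=roles)


def _ar1_noise(n, rho, sd, rng):
    """Stationary AR(1) series with innovation SD ``sd``."""
    x = np.empty(n)
    if sd == 0:
        return np.zeros(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho * rho))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def generate_bold(design, truth, rng=None):
    """Synthesize BOLD: y = X @ betas + drift + AR(1) noise.

    Parameters
    ----------
    design : DesignMatrix or pandas.DataFrame
        Design built for the subject's schedule (rows = volumes).
    truth : BoldGroundTruth or list of BoldGroundTruth
        One per voxel; a list yields a (volumes, voxels) array whose
        columns can carry distinct beta maps (e.g. an EAA-responsive
        and a categorically responsive synthetic region).
    """
    X = design.frame if hasattr(design, "frame") else design
    rng = np.random.default_rng(rng)
    truths = truth if isinstance(truth, (list, tuple)) else [truth]
    n = X.shape[0]
    t = np.arange(n, dtype=float)
    ys = []
    for tr_ in truths:
        unknown = set(tr_.betas) - set(X.columns)
        if unknown:
            raise ValueError(f"betas reference unknown regressors: {sorted(unknown)}")
        y = np.zeros(n)
        for name, b in tr_.betas.items():
            y += b * X[name].to_numpy()
        if tr_.drift_amplitude:
            y += tr_.drift_amplitude * np.cos(2 * np.pi * t / n)
        y += _ar1_noise(n, tr_.ar1_rho, tr_.noise_sd, rng)
        ys.append(y)
    out = np.column_stack(ys)
    return out[:, 0] if not isinstance(truth, (list, tuple)) else out
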
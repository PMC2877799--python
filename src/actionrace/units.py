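"""Core domain types for the race model of action selection.

All rates are in Hz (threshold-fractions per second), all times in
seconds, and accumulated activity in activity-units x seconds with the
response threshold fixed at 1 by convention (only theta/beta is
observable from reaction times, so the threshold scale is a free choice
that cancels in mean-centered regressors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONDITIONS = ("chosen", "specified", "null", "error")
#: conditions carrying a response and a reaction time
RESPONSE_CONDITIONS = ("chosen", "specified", "error")


@dataclass(frozen=True)
class DecisionUnitParams:
    """Parameters of one condition's decision units.

    mu, sigma
        Mean and SD of the Gaussian drift-rate distribution (Hz).
    theta
        Response threshold (activity units); 1 by convention.
    k
        Number of competing units racing on a trial (4 for free choice,
        1 for a cued response).
    """

    mu: float
    sigma: float
    theta: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not (isinstance(self.k, int) and self.k >= 1):
            raise ValueError(f"k must be an integer >= 1, got {self.k}")


@dataclass
class Trial:
    """One response event.

    rt and response are present iff the trial carries a response
    (chosen, specified or error); null trials have neither.
    """

    onset: float
    condition: str
    response: int | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        self.condition = str(self.condition)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        has_rt = self.rt is not None
        if has_rt and self.condition not in RESPONSE_CONDITIONS:
            raise ValueError(f"condition {self.condition!r} cannot carry rt")
        if has_rt and not (self.rt > 0):
            raise ValueError(f"rt must be > 0, got {self.rt}")
        if (self.response is not None) != has_rt:
            raise ValueError("response must be present iff rt is present")
        if self.response is not None and self.response not in (1, 2, 3, 4):
            raise ValueError(f"response must be in 1..4, got {self.response}")

    @property
    def is_complete(self) -> bool:
        """True once a responsive trial has its response/RT filled
        (responsive trials are created unfilled by the scheduler)."""
        needs_rt = self.condition in RESPONSE_CONDITIONS
        return (self.rt is not None) == needs_rt


@dataclass(frozen=True)
class TrialEAA:
    """Per-trial decomposition of expected accumulated activity.

    beta_star
        Winning drift rate theta/RT (Hz).
    z_star
        Standardized truncation point (beta_star - mu)/sigma.
    expected_loser_rate
        E[beta_L | beta_L < beta_star], floored at 0 (Hz).
    eaa_winner, eaa_losers, eaa_total
        Accumulated activity of the winner (triangle theta*RT/2), the
        summed k-1 losers, and their sum (activity x s).
    """

    beta_star: float
    z_star: float
    expected_loser_rate: float
    eaa_winner: float
    eaa_losers: float
    eaa_total: float


@dataclass(frozen=True)
class RaceDraw:
    """Outcome of one simulated race."""

    rates: tuple[float, ...]
    winner_index: int
    rt: float
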
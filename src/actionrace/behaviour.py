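"""Sequential-choice redundancy and reaction-time summaries.

Free choices are rarely random: the immediately preceding response
shapes the next one (typically repetitions are suppressed).  The
departure from an unconstrained random 4-choice sequence is quantified
by Shannon's equitability index

    E = H / Hmax
      = [sum_ij (n_ij/n) ln(n_ij/n)] / [2 sum_i (n_i/(n+1)) ln(n_i/(n+1))]

where n_ij counts trials on which response j immediately followed
response i, n is the number of sequential pairs and n_i the per-response
marginal counts over the n+1 contributing trials.  Both sums are
negative, so E is positive; E -> 1 for an infinite unconstrained random
sequence and is below 1 both for finite random sequences and (further)
for sequentially dependent choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairCountMatrix",
    "EquitabilityResult",
    "pair_counts",
    "equitability",
    "equitability_from_proportions",
    "repetition_rate_ratio",
    "random_equitability_null",
    "reciprocal_rt_summary",
]

N_RESPONSES = 4


@dataclass(frozen=True)
class PairCountMatrix:
    """Counts of ordered sequential response pairs within one condition."""

    counts: np.ndarray  # 4x4, counts[i-1, j-1] = # times j followed i
    n: int              # total pairs = len(sequence) - 1
    marginals: np.ndarray  # per-response counts over the n+1 trials


@dataclass(frozen=True)
class EquitabilityResult:
    e: float        # equitability, H/Hmax (0 by convention if Hmax = 0)
    h_pairs: float  # plug-in sequential-pair information (nats)
    h_max: float    # marginal-based maximum (nats)
    degenerate: bool = False  # True when Hmax = 0 (all responses identical)


def pair_counts(responses) -> PairCountMatrix:
    """Count ordered consecutive response pairs.

    ``responses`` is the temporally ordered response sequence of a
    single condition (pairs are formed between consecutive trials of
    that condition, skipping any interleaved trials of other types).
    """
    r = np.asarray(list(responses), dtype=int)
    if r.size < 2:
        raise ValueError("need at least 2 responses to form pairs")
    if np.any((r < 1) | (r > N_RESPONSES)):
        raise ValueError("responses must be finger indices in 1..4")
    counts = np.zeros((N_RESPONSES, N_RESPONSES), dtype=int)
    np.add.at(counts, (r[:-1] - 1, r[1:] - 1), 1)
    marginals = np.bincount(r - 1, minlength=N_RESPONSES)
    return PairCountMatrix(counts=counts, n=r.size - 1, marginals=marginals)


def _plogp(p: np.ndarray) -> np.ndarray:
    """p*ln(p) with the convention 0*ln(0) = 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def equitability_from_proportions(pair_props, marginal_props) -> EquitabilityResult:
    """Equitability evaluated directly on pair and marginal proportions.

    Useful for limits that no finite count matrix realizes exactly, e.g.
    the infinite uniform random sequence (all 16 pair cells 1/16, all 4
    marginals 1/4), whose equitability is exactly 1.
    """
    pp = np.asarray(pair_props, dtype=float)
    mp_ = np.asarray(marginal_props, dtype=float)
    h_pairs = float(np.sum(_plogp(pp)))
    h_max = float(2.0 * np.sum(_plogp(mp_)))
    if h_max == 0.0:
        warnings.warn("degenerate sequence: Hmax = 0, returning e = 0")
        return EquitabilityResult(e=0.0, h_pairs=h_pairs, h_max=h_max,
                                  degenerate=True)
    return EquitabilityResult(e=h_pairs / h_max, h_pairs=h_pairs, h_max=h_max)


def equitability(pc: PairCountMatrix) -> EquitabilityResult:
    """Shannon equitability E = H/Hmax of a pair-count matrix."""
    return equitability_from_proportions(
        pc.counts / pc.n, pc.marginals / (pc.n + 1))


def repetition_rate_ratio(responses) -> float:
    """Observed repetition rate relative to the 4-choice chance rate 1/4.

    1.0 for unconstrained random responding; below 1 when repetitions of
    the previous response are suppressed.
    """
    r = np.asarray(list(responses), dtype=int)
    if r.size < 2:
        raise ValueError("need at least 2 responses")
    rep = float(np.mean(r[:-1] == r[1:]))
    return rep / 0.25


def random_equitability_null(sequence_length: int, n_sims: int = 1000,
                             rng=None) -> dict:
    """Null distribution of equitability for uniform random sequences.

    Simulates ``n_sims`` independent uniform 4-choice sequences of the
    given length and returns summary statistics of their equitability.
    Finite sequences have mean below 1 (plug-in entropy bias); the mean
    rises toward 1 with length.
    """
    if sequence_length < 2:
        raise ValueError("sequence_length must be >= 2")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    es = np.empty(n_sims)
    for s in range(n_sims):
        seq = rng.integers(1, N_RESPONSES + 1, size=sequence_length)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es[s] = equitability(pair_counts(seq)).e
    q = np.quantile(es, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean": float(es.mean()),
        "sd": float(es.std(ddof=1)) if n_sims > 1 else 0.0,
        "q2.5": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
        "q75": float(q[3]), "q97.5": float(q[4]),
        "values": es,
    }


def reciprocal_rt_summary(trials) -> pd.DataFrame:
    """Mean and variance of reciprocal RT per condition x finger cell.

    ``trials`` is an iterable of Trial (or any objects with condition,
    response, rt).  Returns one row per occupied (condition, response)
    cell plus a pooled row per condition (response = 0); cells with a
    single RT report variance as NaN.
    """
    rows = [(t.condition, t.response, 1.0 / t.rt)
            for t in trials if t.rt is not None and t.condition != "error"]
    if not rows:
        return pd.DataFrame(
            columns=["condition", "response", "n", "mean_rate", "var_rate"])
    df = pd.DataFrame(rows, columns=["condition", "response", "rate"])
    per_cell = (df.groupby(["condition", "response"])["rate"]
                .agg(n="size", mean_rate="mean", var_rate="var")
                .reset_index())
    pooled = (df.groupby("condition")["rate"]
              .agg(n="size", mean_rate="mean", var_rate="var")
              .reset_index())
    pooled.insert(1, "response", 0)
    out = pd.concat([per_cell, pooled], ignore_index=True)
    return out.sort_values(["condition", "response"]).reset_index(drop=True)
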
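"""First- and second-level GLMs for the race-model fMRI analysis.

First level: events are 1 s boxcars convolved with a canonical
double-gamma hemodynamic response; parametric modulators (trial-wise
expected accumulated activity, the categorical chosen-vs-specified
code, optionally absolute RT) are mean-centered over their contributing
events before convolution and are NOT serially orthogonalized — the
modulators compete for shared variance and their sample covariance is
recorded in the design metadata instead.  A discrete-cosine basis
implements the 128 s high-pass filter, and serial correlation is
handled by AR(1) prewhitening with the lag-1 Yule-Walker coefficient of
the OLS residuals.

Three design variants are supported:

* model 1 — TASK (all responsive events) + EAA modulator + CvS
  (+1 chosen / -1 specified) modulator, errors modelled separately;
* model 2 — model 1 plus a mean-centered absolute-RT modulator;
* model 3 — the follow-up design: FIRST move, one later single chosen
  and one later single specified trial, all OTHER moves, and an
  OTHER x CvS modulator.

Second level: one-sample (and two-sample) t tests over per-subject
contrast values, Benjamini-Hochberg FDR across units, and an
SnPM-style permutation test correlating per-subject contrasts with a
behavioural covariate by rank correlation, family-wise corrected with
the max-statistic null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hrf",
    "DesignMatrix",
    "build_design",
    "GLMResult",
    "FirstLevelGLM",
    "fit_glm",
    "second_level_t",
    "two_sample_t",
    "permutation_correlation",
    "fdr_bh",
    "GroupResult",
]

OVERSAMPLE = 16          # convolution grid = TR / OVERSAMPLE
HRF_SUPPORT = 32.0       # s
DEFAULT_HP_CUTOFF = 128.0  # s
DEFAULT_EVENT_DURATION = 1.0  # s (cue duration)


def hrf(duration: float = HRF_SUPPORT, dt: float = 0.125) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Response gamma with shape 6 and unit scale (mode at 5 s), undershoot
    gamma with shape 16 (mode at 15 s) weighted 1/6.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, duration, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Named, convolved, high-pass-filtered regressors on the volume grid."""

    frame: pd.DataFrame       # rows = volumes, columns = regressors
    volume_times: np.ndarray  # s
    metadata: dict = field(default_factory=dict)

    @property
    def columns(self):
        return list(self.frame.columns)

    def to_csv(self, path):
        out = self.frame.copy()
        out.insert(0, "time", self.volume_times)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        t = df.pop("time").to_numpy()
        return cls(frame=df, volume_times=t)


def _dct_highpass_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """DCT-II drift regressors for periods longer than ``cutoff`` s."""
    order = int(np.floor(2.0 * n * tr / cutoff))
    i = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _mean_center(values: np.ndarray) -> np.ndarray:
    return values - values.mean()


def _event_columns(trials, model_id, eaa, roles):
    """Yield (name, events) where events is a list of (onset, amplitude)."""
    resp = [t for t in trials if t.condition in ("chosen", "specified")]
    errors = [t for t in trials if t.condition == "error"]
    eaa_by_id = {id(t): e for t, e in eaa} if eaa else {}

    cols = {}
    if model_id in (1, 2):
        if not resp:
            raise ValueError("no chosen/specified events to model")
        onsets = np.array([t.onset for t in resp])
        cols["TASK"] = (onsets, np.ones(len(resp)))
        eaa_vals = np.array([eaa_by_id[id(t)].eaa_total for t in resp])
        cols["EAA"] = (onsets, _mean_center(eaa_vals))
        cvs = np.array([1.0 if t.condition == "chosen" else -1.0 for t in resp])
        cols["CvS"] = (onsets, _mean_center(cvs))
        if model_id == 2:
            rts = np.array([t.rt for t in resp])
            cols["RT"] = (onsets, _mean_center(rts))
    elif model_id == 3:
        if roles is None:
            raise ValueError("model 3 requires trial roles "
                             "(first/later_chosen/later_specified/other)")
        groups = {"FIRST": "first", "LATER_CHOSEN": "later_chosen",
                  "LATER_SPECIFIED": "later_specified", "OTHER": "other"}
        for name, role in groups.items():
            sel = [t for t, r in zip(trials, roles) if r == role]
            if sel:
                cols[name] = (np.array([t.onset for t in sel]),
                              np.ones(len(sel)))
        others = [t for t, r in zip(trials, roles) if r == "other"]
        if others:
            cvs = np.array([1.0 if t.condition == "chosen" else -1.0
                            for t in others])
            cols["OTHERxCvS"] = (np.array([t.onset for t in others]),
                                 _mean_center(cvs))
    else:
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")

    if errors:
        cols["ERR"] = (np.array([t.onset for t in errors]),
                       np.ones(len(errors)))
    return cols


def build_design(subject, model_id, eaa=None, tr=2.0, n_volumes=None,
                 event_duration=DEFAULT_EVENT_DURATION, stick=False,
                 hp_cutoff=DEFAULT_HP_CUTOFF, orthogonalize=False) -> DesignMatrix:
    """Construct a first-level design matrix for one subject.

    Parameters
    ----------
    subject : SubjectBehaviour or list of Trial
        The trial schedule (with responses/RTs filled for responsive
        trials).  Model 3 needs the subject's trial roles.
    model_id : {1, 2, 3}
    eaa : list of (Trial, TrialEAA)
        Required for models 1-2; aligned to the responsive trials.
    tr : float
        Volume repetition time (s).
    n_volumes : int
        Number of volumes; must cover the schedule.
    event_duration : float
        Boxcar length (s); ``stick=True`` uses delta sticks instead.
    orthogonalize : bool
        If True, serially orthogonalize modulators in design order
        (TASK -> EAA -> CvS -> RT); default leaves them competing and
        records their covariance in the metadata.
    """
    trials = getattr(subject, "trials", subject)
    roles = getattr(subject, "roles", None)
    if n_volumes is None:
        raise ValueError("n_volumes is required")
    if model_id in (1, 2) and eaa is None:
        raise ValueError("models 1 and 2 require per-trial EAA values")

    run_length = n_volumes * tr
    last_onset = max(t.onset for t in trials)
    if last_onset >= run_length:
        raise ValueError(
            f"schedule extends to {last_onset:.1f}s but {n_volumes} volumes "
            f"cover only {run_length:.1f}s")

    dt = tr / OVERSAMPLE
    n_fine = n_volumes * OVERSAMPLE
    kernel = hrf(HRF_SUPPORT, dt)
    dur_samples = 1 if stick else max(1, int(round(event_duration / dt)))

    cols = _event_columns(trials, model_id, eaa, roles)
    data = {}
    dropped = []
    for name, (onsets, amps) in cols.items():
        fine = np.zeros(n_fine)
        idx = np.round(onsets / dt).astype(int)
        for i, a in zip(idx, amps):
            fine[i:i + dur_samples] += a
        conv = np.convolve(fine, kernel)[:n_fine]
        col = conv[::OVERSAMPLE]
        if np.allclose(col, 0.0):
            dropped.append(name)
            warnings.warn(f"regressor {name} is all zero and was dropped")
            continue
        data[name] = col

    frame = pd.DataFrame(data)
    if orthogonalize:
        order = [c for c in ("TASK", "EAA", "CvS", "RT") if c in frame]
        for j, name in enumerate(order[1:], start=1):
            prev = frame[order[:j]].to_numpy()
            v = frame[name].to_numpy()
            coef, *_ = np.linalg.lstsq(prev, v, rcond=None)
            frame[name] = v - prev @ coef

    event_cols = list(frame.columns)
    drifts = _dct_highpass_basis(n_volumes, tr, hp_cutoff)
    for k in range(drifts.shape[1]):
        frame[f"drift_{k + 1}"] = drifts[:, k]
    frame["constant"] = 1.0

    modulators = [c for c in ("EAA", "CvS", "RT", "OTHERxCvS") if c in frame]
    meta = {
        "tr": tr, "hp_cutoff": hp_cutoff, "model_id": model_id,
        "event_duration": 0.0 if stick else event_duration,
        "orthogonalize": orthogonalize, "dropped": dropped,
        "event_columns": event_cols,
        "modulator_covariance":
            frame[modulators].cov().to_dict() if len(modulators) > 1 else {},
    }
    return DesignMatrix(frame=frame,
                        volume_times=np.arange(n_volumes) * tr,
                        metadata=meta)


@dataclass
class GLMResult:
    """Fitted first-level model for one time series."""

    betas: pd.Series
    resid_var: float
    ar1_rho: float
    dof: int
    contrasts: dict = field(default_factory=dict)  # name -> (estimate, t, p)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns adding no independent direction, in order
        culprits, basis = [], np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            trial_ = np.column_stack([basis, X[:, j]])
            if np.linalg.matrix_rank(trial_) == basis.shape[1]:
                culprits.append(name)
            else:
                basis = trial_
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {culprits}")


def _yule_walker_rho(e: np.ndarray) -> float:
    denom = float(np.dot(e, e))
    if denom <= 0 or not np.isfinite(denom):
        return 0.0  # perfect fit: nothing to whiten
    rho = float(np.dot(e[1:], e[:-1]) / denom)
    return float(np.clip(rho, -0.99, 0.99))


class FirstLevelGLM(BaseEstimator):
    """AR(1)-prewhitened least-squares GLM.

    ``fit(X, y)`` estimates the lag-1 residual autocorrelation by
    Yule-Walker on an initial OLS fit, transforms data and design with
    the AR(1) whitening filter, and refits.

    Parameters
    ----------
    ar1 : bool
        If False, plain OLS (rho fixed at 0).

    Attributes
    ----------
    coef_ : pandas.Series of fitted betas per column
    ar1_rho_ : estimated autocorrelation used for whitening
    sigma2_ : whitened residual variance
    dof_ : residual degrees of freedom (volumes - rank)
    """

    def __init__(self, ar1: bool = True):
        self.ar1 = ar1

    def fit(self, X, y):
        frame = X.frame if isinstance(X, DesignMatrix) else pd.DataFrame(X)
        Xm = frame.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != Xm.shape[0]:
            raise ValueError("y and design have different numbers of rows")
        _check_rank(Xm, list(frame.columns))

        beta_ols, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        rho = 0.0
        if self.ar1:
            e = y - Xm @ beta_ols
            # residuals at numerical-noise scale carry no real serial
            # structure; whitening them would be pure round-off
            if np.dot(e, e) > 1e-18 * max(1.0, float(np.dot(y, y))):
                rho = _yule_walker_rho(e)
        Xw, yw = self._whiten(Xm, rho), self._whiten(y, rho)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)

        n, p = Xm.shape
        resid = yw - Xw @ beta
        self.dof_ = n - p
        self.resid_ = resid  # whitened residuals
        self.sigma2_ = float(resid @ resid / self.dof_)
        self.ar1_rho_ = rho
        self.coef_ = pd.Series(beta, index=frame.columns)
        self._xtx_inv = np.linalg.inv(Xw.T @ Xw)
        self._columns = list(frame.columns)
        return self

    @staticmethod
    def _whiten(a, rho):
        if rho == 0.0:
            return a
        out = a.astype(float).copy()
        out[1:] = a[1:] - rho * a[:-1]
        out[0] = a[0] * np.sqrt(1.0 - rho * rho)
        return out

    def contrast(self, weights):
        """Contrast estimate, t statistic and two-sided p.

        ``weights`` is either a full-length vector or a mapping from
        column name to weight (unnamed columns get 0).
        """
        if isinstance(weights, dict):
            c = np.array([weights.get(name, 0.0) for name in self._columns])
        else:
            c = np.asarray(weights, dtype=float)
        est = float(c @ self.coef_.to_numpy())
        se = np.sqrt(self.sigma2_ * c @ self._xtx_inv @ c)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), self.dof_)
        return est, float(t), float(p)


def fit_glm(y, X, contrasts=None, ar1=True) -> GLMResult:
    """Fit one voxel/ROI time series; thin wrapper over FirstLevelGLM."""
    model = FirstLevelGLM(ar1=ar1).fit(X, y)
    out = GLMResult(betas=model.coef_, resid_var=model.sigma2_,
                    ar1_rho=model.ar1_rho_, dof=model.dof_)
    for name, w in (contrasts or {}).items():
        out.contrasts[name] = model.contrast(w)
    return out


@dataclass
class GroupResult:
    """Second-level inference over units (voxels/ROIs)."""

    statistic: np.ndarray   # t or rank-correlation per unit
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray | None = None  # permutation FWE
    rejected: np.ndarray | None = None     # FDR decision
    fdr_threshold: float | None = None
    n_perm: int | None = None
    dof: int | None = None


def second_level_t(values) -> dict:
    """One-sample t of per-subject contrast values against 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 subjects")
    sd = v.std(ddof=1)
    if sd == 0:
        if np.all(v == 0):
            return {"t": 0.0, "p": 1.0, "dof": v.size - 1,
                    "mean": 0.0, "degenerate": True}
        return {"t": np.nan, "p": np.nan, "dof": v.size - 1,
                "mean": float(v.mean()), "degenerate": True}
    t = v.mean() / (sd / np.sqrt(v.size))
    p = 2.0 * stats.t.sf(abs(t), v.size - 1)
    return {"t": float(t), "p": float(p), "dof": v.size - 1,
            "mean": float(v.mean()), "degenerate": False}


def two_sample_t(a, b) -> dict:
    """Independent-groups t (equal variance) for between-group contrasts."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    t, p = stats.ttest_ind(a, b)
    return {"t": float(t), "p": float(p), "dof": a.size + b.size - 2,
            "mean_diff": float(a.mean() - b.mean())}


def _rank(a: np.ndarray, axis=-1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def permutation_correlation(subject_contrasts, covariate, n_perm=5000,
                            rng=None) -> GroupResult:
    """SnPM-style permutation test of a monotonic covariate relation.

    Spearman rank correlation between a per-subject behavioural
    covariate and per-subject contrast values at each unit; the null is
    built by permuting the covariate across subjects, and family-wise
    corrected p values use the maximum |rho| over units.  The observed
    labelling counts as one member of the null, so p >= 1/(n_perm+1).
    Two-sided throughout.
    """
    C = np.asarray(subject_contrasts, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.ndim != 2:
        raise ValueError("subject_contrasts must be (subjects, units)")
    cov = np.asarray(covariate, dtype=float)
    n_sub, n_units = C.shape
    if cov.shape != (n_sub,):
        raise ValueError("covariate length must equal the subject count")
    if n_sub < 6:
        raise ValueError("need at least 6 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; correlation undefined")

    rng = np.random.default_rng(rng)
    rc = _rank(cov)
    rC = _rank(C, axis=0)
    rc = (rc - rc.mean()) / rc.std()
    rC = (rC - rC.mean(axis=0)) / rC.std(axis=0)

    obs = np.abs(rc @ rC) / n_sub                       # |spearman| per unit
    perm_idx = np.array([rng.permutation(n_sub) for _ in range(n_perm)])
    perm_r = np.abs(rc[perm_idx] @ rC) / n_sub          # (n_perm, units)
    perm_max = perm_r.max(axis=1)

    p_unc = (1 + (perm_r >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    p_fwe = (1 + (perm_max[:, None] >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    rho_signed = (rc @ rC) / n_sub
    return GroupResult(statistic=rho_signed, p_uncorrected=p_unc,
                       p_corrected=p_fwe, n_perm=n_perm)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns (reject mask, p threshold)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    thresh = float(p[reject].max()) if reject.any() else 0.0
    return reject, thresh
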
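"""Neurophysiological predictors from pretreatment neurofeedback sessions.

Two predictor families are derived from the first training session:

* **EEG** — mean fronto-central high-beta power (23-28 Hz, uV^2) during
  passive-viewing, regulation, and transfer trials (three predictors).
* **fNIRS** — per trial type, the percentage of trials classified as
  oxygenation (trial-wise GLM beta > 0.2) or deoxygenation (beta < -0.2)
  of prefrontal oxyhemoglobin, averaged over the two recording channels
  (six predictors).

The trial-wise GLM regresses the oxyhemoglobin series on a boxcar for the
trial convolved with a canonical two-gamma hemodynamic response function,
with intercept, linear drift, and a lumped all-other-trials regressor as
nuisance terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

__all__ = [
    "HrfParams",
    "Hrf",
    "FnirsSession",
    "EegSession",
    "TrialBeta",
    "two_gamma_hrf",
    "build_trial_design",
    "fit_trial_glm",
    "average_channels",
    "classify_trial",
    "fnirs_predictors",
    "band_power",
    "eeg_predictors",
    "predictor_table",
]

TRIAL_TYPES = ("passive_viewing", "regulation", "transfer")

#: classification threshold on the trial beta: > +0.2 oxygenation,
#: < -0.2 deoxygenation, otherwise neither
BETA_THRESHOLD = 0.2


@dataclass(frozen=True)
class HrfParams:
    """Canonical two-gamma HRF parameters (seconds).

    The kernel is a difference of two gamma densities parameterised so the
    positive lobe peaks at ``peak_delay`` and the undershoot at
    ``undershoot_delay``, the undershoot scaled by ``undershoot_ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion_1: float = 1.0
    dispersion_2: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def validate(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "dispersion_1",
                     "dispersion_2", "undershoot_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HRF parameter {name!r} must be positive")


@dataclass
class Hrf:
    """Sampled HRF kernel, peak-normalised to 1."""

    times: np.ndarray
    kernel: np.ndarray
    params: HrfParams


@dataclass
class FnirsSession:
    """Two-channel oxyhemoglobin series plus the trial schedule.

    ``series`` has shape (n_samples, 2); ``schedule`` has columns
    trial_id, type, onset_s, duration_s with strictly increasing onsets.
    """

    fs: float
    series: np.ndarray
    schedule: pd.DataFrame

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != 2:
            raise ValueError("series must have shape (n_samples, 2)")
        onsets = self.schedule["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("schedule onsets must be strictly increasing")
        ends = onsets + self.schedule["duration_s"].to_numpy()
        if np.any(ends > self.series.shape[0] / self.fs + 1e-9):
            raise ValueError("trial extends beyond the recorded series")

    @property
    def n_samples(self) -> int:
        return self.series.shape[0]


@dataclass
class EegSession:
    """Trial-wise fronto-central high-beta power (uV^2) by trial type."""

    powers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.powers = {k: np.asarray(v, dtype=float) for k, v in self.powers.items()}
        for k, v in self.powers.items():
            if v.size and np.any(v <= 0):
                raise ValueError(f"non-positive power in trial type {k!r}")


@dataclass(frozen=True)
class TrialBeta:
    trial_id: int
    type: str
    beta: float


def two_gamma_hrf(fs: float, length_s: float = 32.0,
                  params: HrfParams | None = None) -> Hrf:
    """Sample the canonical two-gamma HRF at rate ``fs`` over ``length_s``.

    The positive lobe is a gamma density with mode at ``peak_delay`` and the
    undershoot a gamma density with mode at ``undershoot_delay``; the kernel
    is normalised so its maximum equals 1 and its value at t=0 is 0.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if length_s < 30:
        raise ValueError("length_s must be at least 30 s to span the undershoot")
    p = params or HrfParams()
    p.validate()
    t = np.arange(0.0, length_s, 1.0 / fs)
    # shape a, scale b chosen so the mode (a-1)b sits at the stated delay
    a1 = p.peak_delay / p.dispersion_1 + 1.0
    a2 = p.undershoot_delay / p.dispersion_2 + 1.0
    k = (stats.gamma.pdf(t, a1, scale=p.dispersion_1)
         - p.undershoot_ratio * stats.gamma.pdf(t, a2, scale=p.dispersion_2))
    k = k / np.max(k)
    return Hrf(times=t, kernel=k, params=p)


def _boxcar(onset_s: float, duration_s: float, fs: float, n_samples: int) -> np.ndarray:
    i0 = int(round(onset_s * fs))
    i1 = int(round((onset_s + duration_s) * fs))
    box = np.zeros(n_samples)
    box[max(i0, 0):min(i1, n_samples)] = 1.0
    return box


def hrf_regressor(schedule: pd.DataFrame, trial_ids, fs: float,
                  n_samples: int, hrf: Hrf) -> np.ndarray:
    """Boxcar(s) for the given trials convolved with the HRF kernel.

    Discrete convolution (no dt scaling): a long boxcar plateaus at the sum
    of the kernel samples. Regressors are additive over disjoint trials.
    """
    sched = schedule.set_index("trial_id")
    box = np.zeros(n_samples)
    for tid in np.atleast_1d(trial_ids):
        if tid not in sched.index:
            raise KeyError(f"trial_id {tid} not in schedule")
        row = sched.loc[tid]
        box += _boxcar(float(row["onset_s"]), float(row["duration_s"]), fs, n_samples)
    return np.convolve(box, hrf.kernel)[:n_samples]


def build_trial_design(schedule: pd.DataFrame, trial_id: int, fs: float,
                       n_samples: int, hrf: Hrf) -> pd.DataFrame:
    """Design matrix for one trial's GLM over the full series.

    Columns: ``trial`` (the trial's boxcar x HRF regressor), nuisance
    ``others`` (all remaining trials, lumped), ``intercept`` and linear
    ``drift``. The caller selects the fit window.
    """
    if trial_id not in set(schedule["trial_id"]):
        raise KeyError(f"trial_id {trial_id} not in schedule")
    trial = hrf_regressor(schedule, [trial_id], fs, n_samples, hrf)
    other_ids = [t for t in schedule["trial_id"] if t != trial_id]
    if other_ids:
        others = hrf_regressor(schedule, other_ids, fs, n_samples, hrf)
    else:
        others = np.zeros(n_samples)
    t = np.arange(n_samples) / fs
    design = pd.DataFrame({
        "trial": trial,
        "others": others,
        "intercept": np.ones(n_samples),
        "drift": t - t.mean(),
    })
    return design


def fit_trial_glm(series: np.ndarray, design: pd.DataFrame) -> float:
    """OLS coefficient of the ``trial`` regressor, controlling for nuisance.

    Raises on rank-deficient designs (after dropping all-zero nuisance
    columns, which carry no information).
    """
    y = np.asarray(series, dtype=float)
    X = design.to_numpy(dtype=float)
    if len(y) != len(X):
        raise ValueError("series and design lengths differ")
    keep = [i for i in range(X.shape[1])
            if design.columns[i] == "trial" or np.any(X[:, i] != 0.0)]
    Xk = X[:, keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient trial design")
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    return float(coef[keep.index(design.columns.get_loc("trial"))])


def average_channels(beta_ch1: float, beta_ch2: float) -> float:
    """Arithmetic mean of the two adjacent channels' betas."""
    if not (np.isfinite(beta_ch1) and np.isfinite(beta_ch2)):
        raise ValueError("channel betas must be finite")
    return (beta_ch1 + beta_ch2) / 2.0


def classify_trial(beta: float, threshold: float = BETA_THRESHOLD) -> str:
    """Oxygenation if beta > +threshold, deoxygenation if beta < -threshold,
    otherwise neither (strict inequalities; the boundary counts as neither)."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta > threshold:
        return "oxygenation"
    if beta < -threshold:
        return "deoxygenation"
    return "neither"


def trial_betas(session: FnirsSession, hrf: Hrf,
                window: tuple[float, float] = (5.0, 15.0)) -> list[TrialBeta]:
    """Channel-averaged trial betas for every trial in the schedule.

    Each trial's GLM is fit on the window [onset - window[0],
    onset + duration + window[1]] to capture the hemodynamic lag.
    """
    pre_s, post_s = window
    out: list[TrialBeta] = []
    n = session.n_samples
    # cache each trial's regressor once; the lumped nuisance is total - trial
    regs = {int(tid): hrf_regressor(session.schedule, [tid], session.fs, n, hrf)
            for tid in session.schedule["trial_id"]}
    total = sum(regs.values())
    t = np.arange(n) / session.fs
    drift = t - t.mean()
    for _, row in session.schedule.iterrows():
        tid = int(row["trial_id"])
        design = pd.DataFrame({
            "trial": regs[tid],
            "others": total - regs[tid],
            "intercept": np.ones(n),
            "drift": drift,
        })
        i0 = max(int((row["onset_s"] - pre_s) * session.fs), 0)
        i1 = min(int((row["onset_s"] + row["duration_s"] + post_s) * session.fs), n)
        betas = [fit_trial_glm(session.series[i0:i1, ch],
                               design.iloc[i0:i1]) for ch in (0, 1)]
        out.append(TrialBeta(trial_id=tid, type=row["type"],
                             beta=average_channels(*betas)))
    return out


def fnirs_predictors(session: FnirsSession, hrf: Hrf,
                     threshold: float = BETA_THRESHOLD) -> dict[str, float]:
    """Six fNIRS predictors: oxygenation/deoxygenation percentage per type.

    Percentages are relative to the number of trials of that type; a type
    absent from the schedule yields NaN (absent), not 0.
    """
    betas = trial_betas(session, hrf)
    out: dict[str, float] = {}
    for ttype in TRIAL_TYPES:
        tb = [b.beta for b in betas if b.type == ttype]
        key = _SHORT_TYPE[ttype]
        if not tb:
            out[f"fnirs_oxy_{key}"] = np.nan
            out[f"fnirs_deoxy_{key}"] = np.nan
            continue
        classes = [classify_trial(b, threshold) for b in tb]
        out[f"fnirs_oxy_{key}"] = 100.0 * classes.count("oxygenation") / len(tb)
        out[f"fnirs_deoxy_{key}"] = 100.0 * classes.count("deoxygenation") / len(tb)
    return out


_SHORT_TYPE = {"passive_viewing": "passive", "regulation": "regulation",
               "transfer": "transfer"}


def band_power(signal: np.ndarray, fs: float,
               band: tuple[float, float] = (23.0, 28.0)) -> float:
    """Band power (signal units squared) from an averaged periodogram.

    Welch estimate with 2 s Hann segments at 50% overlap; the band power is
    the PSD integrated over [band[0], band[1]].
    """
    lo, hi = band
    if fs <= 2 * hi:
        raise ValueError(f"fs={fs} must exceed twice the band upper edge {hi}")
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    nperseg = int(round(2 * fs))
    freqs, psd = sp_signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=nperseg // 2, detrend="constant")
    sel = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[sel]) * df)


def eeg_predictors(session: EegSession) -> dict[str, float]:
    """Mean high-beta power per trial type; empty types are NaN (absent)."""
    out: dict[str, float] = {}
    for ttype in TRIAL_TYPES:
        key = _SHORT_TYPE[ttype]
        vals = session.powers.get(ttype, np.array([]))
        out[f"eeg_{key}"] = float(np.mean(vals)) if len(vals) else np.nan
    return out


EEG_PREDICTORS = ("eeg_passive", "eeg_regulation", "eeg_transfer")
FNIRS_PREDICTORS = ("fnirs_oxy_passive", "fnirs_deoxy_passive",
                    "fnirs_oxy_regulation", "fnirs_deoxy_regulation",
                    "fnirs_oxy_transfer", "fnirs_deoxy_transfer")


def predictor_table(arms: pd.Series,
                    eeg_sessions: dict[int, EegSession],
                    fnirs_sessions: dict[int, FnirsSession],
                    hrf: Hrf) -> pd.DataFrame:
    """One row per participant: arm plus the nine predictors.

    EEG fields are present only for EEG-arm participants, fNIRS fields only
    for fNIRS-arm participants; the rest are NaN.
    """
    rows = []
    for pid, arm in arms.items():
        row: dict[str, float] = {"participant_id": pid, "arm": arm}
        if arm == "EEG":
            row.update(eeg_predictors(eeg_sessions[pid]))
        elif arm == "FNIRS":
            row.update(fnirs_predictors(fnirs_sessions[pid], hrf))
        else:
            raise ValueError(f"unknown arm {arm!r}")
        rows.append(row)
    cols = ["participant_id", "arm", *EEG_PREDICTORS, *FNIRS_PREDICTORS]
    return pd.DataFrame(rows).reindex(columns=cols)
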
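"""Synthetic neurofeedback trial cohorts.

Generates seeded cohorts with the statistical structure the outcome-
prediction analysis assumes: two arms (EEG-NF n=24, fNIRS-NF n=23 by
default), sociodemographics, baseline/posttreatment/follow-up outcomes,
weekly binge counts, per-participant latent traits that drive both the
neurophysiological sessions and the outcomes, and MCAR/MAR missingness.

Objective binge-eating episode (OBE) counts follow a negative binomial
whose log-mean is linear in z-scored baseline OBE and the latent traits;
abstinence is derived as (count == 0). Continuous outcomes are Gaussian on
the analogous linear predictor. The generating coefficients are retained
as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import neurophys
from .neurophys import EegSession, FnirsSession, Hrf, two_gamma_hrf

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "FnirsScheduleSpec",
    "TRAITS",
    "generate_cohort",
    "generate_eeg_session",
    "generate_fnirs_session",
    "generate_sessions",
    "inject_missingness",
]

TRAITS = ("attention", "regulation", "control")

#: default effects of the latent traits on the outcome linear predictors,
#: oriented as in the trial: higher food-cue attention and better control
#: recruitment predict fewer binges, weaker regulation ability predicts more
DEFAULT_TRUE_COEFFICIENTS = {
    "attention": -0.35,
    "regulation": 0.30,
    "control": -0.30,
}

#: posttreatment / follow-up columns eligible for masking; arm, baseline
#: OBE and the neurophysiological predictors are never masked
ELIGIBLE_MISSING_COLUMNS = (
    "obe_post", "obe_followup",
    "edeq_post", "edeq_followup",
    "fcq_post", "fcq_followup",
    "phq_post", "phq_followup",
    "sf12m_post", "sf12m_followup",
    "bmi_post", "bmi_followup",
)


@dataclass(frozen=True)
class CohortConfig:
    n_eeg: int = 24
    n_fnirs: int = 23
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS))
    nb_dispersion: float = 2.0
    missing_rate: float = 0.10
    missing_mechanism: str = "MCAR"
    seed: int = 42

    def validate(self) -> None:
        if self.n_eeg < 2:
            raise ValueError("n_eeg must be >= 2")
        if self.n_fnirs < 2:
            raise ValueError("n_fnirs must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be 'MCAR' or 'MAR'")
        unknown = set(self.true_coefficients) - set(TRAITS)
        if unknown:
            raise ValueError(f"true_coefficients has unknown traits: {unknown}")


@dataclass
class CohortDataset:
    """Participant-level table plus hidden complete-data ground truth.

    ``table`` may contain NaN after missingness injection; ``truth`` always
    holds the pre-masking values. ``true_coefficients`` are the generating
    trait effects, retained for recovery tests.
    """

    table: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    @property
    def true_coefficients(self) -> dict[str, float]:
        return dict(self.config.true_coefficients)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture (size=dispersion)."""
    lam = rng.gamma(shape=dispersion, scale=np.asarray(mean) / dispersion)
    return rng.poisson(lam)


def generate_cohort(config: CohortConfig) -> tuple[CohortDataset, pd.DataFrame]:
    """Generate a cohort and its latent traits; deterministic given the seed.

    Returns (dataset, traits) where traits has one standard-normal column
    per latent trait (attention response, regulation ability, control
    recruitment).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    n = config.n_eeg + config.n_fnirs
    pid = np.arange(1, n + 1)
    arm = np.array(["EEG"] * config.n_eeg + ["FNIRS"] * config.n_fnirs)

    traits = pd.DataFrame({t: rng.standard_normal(n) for t in TRAITS},
                          index=pd.Index(pid, name="participant_id"))
    coefs = {**{t: 0.0 for t in TRAITS}, **config.true_coefficients}
    trait_lp = sum(coefs[t] * traits[t].to_numpy() for t in TRAITS)

    # baseline characteristics, magnitudes matched to the trial's descriptives
    sex_female = rng.random(n) < 0.81
    age = np.clip(rng.normal(47.1, 13.3, n), 20, 78)
    education = rng.choice([1, 2, 3], size=n, p=[0.2, 0.27, 0.53])
    profession = rng.choice([1, 2, 3, 4], size=n, p=[0.47, 0.19, 0.09, 0.25])
    illness_years = np.clip(rng.gamma(1.2, 8.5, n), 0.2, 50)
    bmi0 = np.clip(rng.normal(36.7, 5.0, n), 25.5, 44.9)
    whr0 = np.clip(rng.normal(0.885, 0.085, n), 0.65, 1.15)
    obe0 = _nb_counts(rng, np.full(n, 13.0), 2.2) + 1  # everyone binges at entry
    z_obe0 = (obe0 - obe0.mean()) / obe0.std()
    edeq0 = np.clip(rng.normal(2.85, 0.95, n), 0.2, 5.9)
    fcq0 = np.clip(rng.normal(58.0, 12.0, n), 16, 75)
    phq0 = np.clip(rng.normal(9.0, 4.1, n), 0, 26)
    gad0 = np.clip(rng.normal(6.3, 4.1, n), 0, 21)
    sf12m0 = np.clip(rng.normal(42.5, 10.7, n), 12, 70)
    sf12p0 = np.clip(rng.normal(43.1, 9.6, n), 12, 70)

    # count outcomes: log-mean linear in z-scored baseline OBE + traits
    eta_post = math.log(2.5) + 0.40 * z_obe0 + trait_lp
    eta_fu = math.log(2.2) + 0.35 * z_obe0 + 0.9 * trait_lp
    obe_post = _nb_counts(rng, np.exp(eta_post), config.nb_dispersion)
    obe_fu = _nb_counts(rng, np.exp(eta_fu), config.nb_dispersion)

    def cont_outcome(base: np.ndarray, retain: float, trait_scale: float,
                     noise_sd: float, lo: float, hi: float) -> np.ndarray:
        mu = base.mean() * (1 - retain) + retain * base + trait_scale * trait_lp
        return np.clip(mu + rng.normal(0, noise_sd, n), lo, hi)

    edeq1 = cont_outcome(edeq0, 0.55, 0.45, 0.55, 0.0, 6.0)
    edeq2 = cont_outcome(edeq0, 0.50, 0.40, 0.60, 0.0, 6.0)
    fcq1 = cont_outcome(fcq0, 0.60, 5.0, 6.0, 15, 75)
    fcq2 = cont_outcome(fcq0, 0.55, 4.5, 6.5, 15, 75)
    phq1 = cont_outcome(phq0, 0.55, 1.8, 2.2, 0, 27)
    phq2 = cont_outcome(phq0, 0.50, 1.6, 2.4, 0, 27)
    gad1 = cont_outcome(gad0, 0.55, 1.5, 2.0, 0, 21)
    gad2 = cont_outcome(gad0, 0.50, 1.4, 2.1, 0, 21)
    sf12m1 = cont_outcome(sf12m0, 0.60, -4.0, 5.0, 10, 72)
    sf12m2 = cont_outcome(sf12m0, 0.55, -3.6, 5.5, 10, 72)
    sf12p1 = cont_outcome(sf12p0, 0.65, -3.0, 4.5, 10, 72)
    sf12p2 = cont_outcome(sf12p0, 0.60, -2.8, 5.0, 10, 72)
    bmi1 = cont_outcome(bmi0, 0.97, 0.25, 0.6, 24, 46)
    bmi2 = cont_outcome(bmi0, 0.95, 0.30, 0.8, 24, 46)
    whr1 = cont_outcome(whr0, 0.95, 0.004, 0.015, 0.6, 1.2)
    whr2 = cont_outcome(whr0, 0.93, 0.005, 0.018, 0.6, 1.2)

    # weekly OBE counts: thin the baseline weekly rate toward the
    # posttreatment rate with a participant-specific geometric decay
    decay = ((obe_post + 0.5) / (obe0 + 0.5)) ** (1.0 / 8.0)
    weekly = {}
    for w in range(1, 9):
        mean_w = (obe0 / 4.0) * decay ** w
        weekly[f"obe_week{w}"] = rng.poisson(mean_w)

    table = pd.DataFrame({
        "participant_id": pid,
        "arm": arm,
        "sex_female": sex_female.astype(int),
        "age": age,
        "education": education,
        "profession": profession,
        "illness_years": illness_years,
        "obe_baseline": obe0,
        "edeq_baseline": edeq0, "fcq_baseline": fcq0,
        "phq_baseline": phq0, "gad_baseline": gad0,
        "sf12m_baseline": sf12m0, "sf12p_baseline": sf12p0,
        "bmi_baseline": bmi0, "whr_baseline": whr0,
        **weekly,
        "obe_post": obe_post, "obe_followup": obe_fu,
        "edeq_post": edeq1, "edeq_followup": edeq2,
        "fcq_post": fcq1, "fcq_followup": fcq2,
        "phq_post": phq1, "phq_followup": phq2,
        "gad_post": gad1, "gad_followup": gad2,
        "sf12m_post": sf12m1, "sf12m_followup": sf12m2,
        "sf12p_post": sf12p1, "sf12p_followup": sf12p2,
        "bmi_post": bmi1, "bmi_followup": bmi2,
        "whr_post": whr1, "whr_followup": whr2,
    })
    dataset = CohortDataset(table=table, truth=table.copy(), config=config)
    return dataset, traits


@dataclass(frozen=True)
class FnirsScheduleSpec:
    """Trial schedule for an fNIRS session: 12 regulation, 12 mirror
    (passive-viewing), and 12 transfer trials of 30 s each by default,
    regulation/mirror alternating followed by the transfer block."""

    n_regulation: int = 12
    n_passive: int = 12
    n_transfer: int = 12
    trial_duration_s: float = 30.0
    inter_trial_s: float = 20.0
    lead_in_s: float = 30.0
    tail_s: float = 60.0

    def validate(self) -> None:
        if min(self.n_regulation, self.n_passive, self.n_transfer) < 1:
            raise ValueError("all trial counts must be >= 1")
        if self.trial_duration_s <= 0 or self.inter_trial_s < 0:
            raise ValueError("invalid trial timing")

    def build(self) -> pd.DataFrame:
        self.validate()
        types: list[str] = []
        for i in range(max(self.n_regulation, self.n_passive)):
            if i < self.n_regulation:
                types.append("regulation")
            if i < self.n_passive:
                types.append("passive_viewing")
        types += ["transfer"] * self.n_transfer
        onsets = self.lead_in_s + np.arange(len(types)) * (
            self.trial_duration_s + self.inter_trial_s)
        return pd.DataFrame({
            "trial_id": np.arange(len(types)),
            "type": types,
            "onset_s": onsets,
            "duration_s": self.trial_duration_s,
        })

    def duration_s(self) -> float:
        sched = self.build()
        return float(sched["onset_s"].iloc[-1] + self.trial_duration_s + self.tail_s)


#: latent-trait links for per-trial oxyhemoglobin amplitudes: means chosen
#: so that, with amplitude SD 0.35 and the +/-0.2 threshold, oxygenation /
#: deoxygenation percentages land in the trial's descriptive range
_FNIRS_AMPLITUDE_MEAN = {
    "passive_viewing": lambda tr: 0.08 + 0.10 * tr["attention"],
    "regulation": lambda tr: -0.05 + 0.22 * tr["control"],
    "transfer": lambda tr: 0.02 + 0.22 * tr["control"],
}


def generate_fnirs_session(traits: pd.Series,
                           schedule_spec: FnirsScheduleSpec | None = None,
                           noise_sd: float = 0.2,
                           fs: float = 10.0,
                           seed: int = 0,
                           drift_slope: float = 5e-4,
                           amplitude_sd: float = 0.35,
                           amplitudes: np.ndarray | None = None,
                           hrf: Hrf | None = None) -> FnirsSession:
    """Simulate a two-channel oxyhemoglobin session.

    Each trial contributes amplitude x (boxcar convolved with the HRF); a
    linear drift and white noise are added per channel. Amplitudes are drawn
    around trait-linked means per trial type unless ``amplitudes`` (one per
    scheduled trial) overrides them — both channels share the amplitudes, so
    a noiseless session recovers them exactly through the trial GLM.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    spec = schedule_spec or FnirsScheduleSpec()
    schedule = spec.build()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0F0]))
    n_samples = int(round(spec.duration_s() * fs))
    kernel = hrf or two_gamma_hrf(fs)

    if amplitudes is None:
        means = np.array([_FNIRS_AMPLITUDE_MEAN[t](traits)
                          for t in schedule["type"]])
        amplitudes = means + rng.normal(0, amplitude_sd, len(schedule))
    else:
        amplitudes = np.asarray(amplitudes, dtype=float)
        if len(amplitudes) != len(schedule):
            raise ValueError("amplitudes must match the number of scheduled trials")

    clean = np.zeros(n_samples)
    for amp, tid in zip(amplitudes, schedule["trial_id"]):
        clean += amp * neurophys.hrf_regressor(schedule, [tid], fs, n_samples, kernel)
    t = np.arange(n_samples) / fs
    series = np.empty((n_samples, 2))
    for ch in range(2):
        drift = drift_slope * rng.standard_normal() * (t - t.mean())
        series[:, ch] = clean + drift + rng.normal(0, noise_sd, n_samples)
    return FnirsSession(fs=fs, series=series, schedule=schedule)


#: trait links for log high-beta power; magnitudes target the trial's
#: descriptive means (passive ~6.1, regulation ~4.9, transfer ~5.2 uV^2)
_EEG_LOG_MEAN = {
    "passive_viewing": lambda tr: math.log(6.0) + 0.30 * tr["attention"],
    "regulation": lambda tr: math.log(4.9) - 0.30 * tr["regulation"],
    "transfer": lambda tr: math.log(5.2) - 0.30 * tr["control"],
}


def generate_eeg_session(traits: pd.Series, n_passive: int = 3,
                         n_regulation: int = 12, n_transfer: int = 6,
                         seed: int = 0, power_sd: float = 0.25) -> EegSession:
    """Draw trial-wise high-beta powers, log-normal around trait-linked means."""
    counts = {"passive_viewing": n_passive, "regulation": n_regulation,
              "transfer": n_transfer}
    for name, c in counts.items():
        if c < 1:
            raise ValueError(f"trial count for {name} must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEE61]))
    powers = {}
    for ttype, c in counts.items():
        mu = _EEG_LOG_MEAN[ttype](traits)
        powers[ttype] = np.exp(rng.normal(mu, power_sd, c))
    return EegSession(powers=powers)


def generate_sessions(dataset: CohortDataset, traits: pd.DataFrame,
                      schedule_spec: FnirsScheduleSpec | None = None,
                      fnirs_noise_sd: float = 0.2, fs: float = 10.0,
                      seed: int | None = None,
                      ) -> tuple[dict[int, EegSession], dict[int, FnirsSession]]:
    """Per-participant pretreatment sessions for each arm."""
    seed = dataset.config.seed if seed is None else seed
    eeg: dict[int, EegSession] = {}
    fnirs: dict[int, FnirsSession] = {}
    for pid, arm in zip(dataset.table["participant_id"], dataset.table["arm"]):
        tr = traits.loc[pid]
        if arm == "EEG":
            eeg[pid] = generate_eeg_session(tr, seed=seed * 100003 + pid)
        else:
            fnirs[pid] = generate_fnirs_session(
                tr, schedule_spec=schedule_spec, noise_sd=fnirs_noise_sd,
                fs=fs, seed=seed * 100003 + pid)
    return eeg, fnirs


def inject_missingness(dataset: CohortDataset, rate: float | None = None,
                       mechanism: str | None = None,
                       seed: int | None = None,
                       mar_slope: float = 1.5) -> CohortDataset:
    """Mask eligible outcome cells; the pre-masking table stays in ``truth``.

    MCAR masks each eligible cell independently with probability ``rate``.
    MAR makes the masking probability a logistic function of arm and
    z-scored baseline OBE (slope ``mar_slope``), with the intercept solved
    so the expected masked fraction equals ``rate``. Arm, baseline OBE and
    neurophysiological predictors are never masked.
    """
    cfg = dataset.config
    rate = cfg.missing_rate if rate is None else rate
    mechanism = cfg.missing_mechanism if mechanism is None else mechanism
    seed = cfg.seed if seed is None else seed
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if mechanism not in ("MCAR", "MAR"):
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")
    table = dataset.truth.copy()
    if rate == 0:
        return CohortDataset(table=table, truth=dataset.truth.copy(), config=cfg)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3155]))
    n = len(table)
    cols = [c for c in ELIGIBLE_MISSING_COLUMNS if c in table.columns]
    if mechanism == "MCAR":
        p_row = np.full(n, rate)
    else:
        obe0 = table["obe_baseline"].to_numpy(dtype=float)
        z = (obe0 - obe0.mean()) / obe0.std()
        driver = mar_slope * z + 0.3 * (table["arm"].to_numpy() == "EEG")
        # solve the intercept so the mean masking probability equals rate
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if np.mean(1 / (1 + np.exp(-(mid + driver)))) < rate:
                lo = mid
            else:
                hi = mid
        p_row = 1 / (1 + np.exp(-((lo + hi) / 2 + driver)))
    mask = rng.random((n, len(cols))) < p_row[:, None]
    for j, c in enumerate(cols):
        table[c] = table[c].astype(float)
        table.loc[mask[:, j], c] = np.nan
    return CohortDataset(table=table, truth=dataset.truth.copy(), config=cfg)
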
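"""Missing-data handling: Little's MCAR test, MICE with predictive mean
matching, and Rubin's rule for pooling multiply imputed estimates.

Little's test compares pattern-wise observed means against EM estimates of
the grand mean and covariance under a multivariate-normal working model;
under MCAR the statistic is asymptotically chi-square with
sum(observed variables per pattern) - (number of variables) degrees of
freedom.

Imputation follows the chained-equations scheme with predictive mean
matching (PMM): each incomplete variable is regressed on all others,
coefficients are drawn from their approximate posterior, and each missing
cell receives the observed value of one of the k donors with the closest
predicted value. Neurophysiological predictor columns and the arm label are
never imputed (they are individual to each participant) and pass through
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "McarTestResult",
    "ImputationStack",
    "littles_mcar_test",
    "mice_pmm",
    "rubin_pool",
]


@dataclass
class McarTestResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int
    applicable: bool = True

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "n_patterns": self.n_patterns,
                "applicable": self.applicable}


def _em_mvnorm(X: np.ndarray, max_iter: int = 200, tol: float = 1e-6
               ) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing entries."""
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X, mu)
    sigma = np.cov(Xc, rowvar=False, bias=True) + 1e-8 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(obs, axis=0):
        rows = np.where((obs == key).all(axis=1))[0]
        patterns[key.tobytes()] = (key, rows)

    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in patterns.values():
            o = np.where(key)[0]
            m = np.where(~key)[0]
            Xr = X[rows]
            if len(m) == 0:
                sum_x += Xr.sum(axis=0)
                sum_xx += Xr.T @ Xr
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            reg = np.linalg.solve(Soo, Smo.T).T          # (|m|, |o|)
            cond_cov = sigma[np.ix_(m, m)] - reg @ Smo.T
            Xf = Xr.copy()
            Xf[:, m] = mu[m] + (Xr[:, o] - mu[o]) @ reg.T
            sum_x += Xf.sum(axis=0)
            sum_xx += Xf.T @ Xf
            sum_xx[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new += 1e-10 * np.eye(p)
        delta = max(np.max(np.abs(mu_new - mu)),
                    np.max(np.abs(sigma_new - sigma)))
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def littles_mcar_test(table: pd.DataFrame) -> McarTestResult:
    """Little's chi-square test that missingness is completely at random.

    Applies to the numeric columns of ``table``; rows missing everything are
    dropped. With a single missingness pattern the test is not applicable
    (df = 0).
    """
    num = table.select_dtypes(include=[np.number])
    X = num.to_numpy(dtype=float)
    X = X[~np.isnan(X).all(axis=1)]
    n, p = X.shape
    obs = ~np.isnan(X)
    pattern_keys = np.unique(obs, axis=0)
    n_patterns = len(pattern_keys)
    if n_patterns < 2:
        return McarTestResult(statistic=0.0, df=0, p_value=float("nan"),
                              n_patterns=n_patterns, applicable=False)

    mu, sigma = _em_mvnorm(X)
    d2 = 0.0
    df = -p
    for key in pattern_keys:
        rows = (obs == key).all(axis=1)
        o = np.where(key)[0]
        if len(o) == 0:
            continue
        n_j = int(rows.sum())
        ybar = X[np.ix_(rows, o)].mean(axis=0)
        diff = ybar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        d2 += n_j * float(diff @ np.linalg.solve(Soo, diff))
        df += len(o)
    p_value = float(stats.chi2.sf(d2, df)) if df > 0 else float("nan")
    return McarTestResult(statistic=float(d2), df=int(df), p_value=p_value,
                          n_patterns=n_patterns, applicable=df > 0)


@dataclass
class ImputationStack:
    """m completed copies of an incomplete table plus provenance.

    Non-imputed cells are identical across copies; ``mask`` flags the cells
    that were imputed.
    """

    datasets: list[pd.DataFrame]
    m: int
    n_iterations: int
    seed: int
    mask: pd.DataFrame

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, start=1):
            df.to_csv(directory / f"imputation_{i}.csv", index=False)
        prov = {"m": self.m, "n_iterations": self.n_iterations,
                "seed": self.seed,
                "imputed_cells": {c: self.mask.index[self.mask[c]].tolist()
                                  for c in self.mask.columns if self.mask[c].any()}}
        (directory / "provenance.json").write_text(json.dumps(prov, indent=2))


def _bayes_draw_regression(Xo: np.ndarray, yo: np.ndarray,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Return (beta_hat, beta_star): the LS fit and a posterior draw."""
    n_obs, q = Xo.shape
    S = Xo.T @ Xo + 1e-6 * np.eye(q)
    Sinv = np.linalg.inv(S)
    beta_hat = Sinv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n_obs - q, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * Sinv
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(q))
    beta_star = beta_hat + L @ rng.standard_normal(q)
    return beta_hat, beta_star


def mice_pmm(table: pd.DataFrame, m: int = 5, n_iterations: int = 10,
             seed: int = 42, k_donors: int = 5,
             never_impute: tuple[str, ...] = ("participant_id", "arm"),
             ) -> ImputationStack:
    """Multiple imputation by chained equations with predictive mean matching.

    Numeric columns with missing values are visited in order of ascending
    missingness count; each is regressed on all other numeric analysis
    columns (current completions), coefficients drawn from their approximate
    posterior, and every missing cell filled with the observed value of one
    of the ``k_donors`` closest-prediction donors. ``m`` independent streams
    are produced, reproducibly seeded.

    Columns named in ``never_impute``, non-numeric columns, and numeric
    columns that are incomplete only because they do not apply to a
    participant's arm (any column ending in the neurophysiological predictor
    prefixes ``eeg_``/``fnirs_``) pass through untouched.
    """
    protected = set(never_impute) | {
        c for c in table.columns if c.startswith(("eeg_", "fnirs_"))}
    num_cols = [c for c in table.columns
                if c not in protected and pd.api.types.is_numeric_dtype(table[c])]
    work_template = table[num_cols].astype(float)

    miss_counts = work_template.isna().sum()
    targets = [c for c in num_cols if miss_counts[c] > 0]
    for c in targets:
        n_obs = int((~work_template[c].isna()).sum())
        if n_obs == 0:
            raise ValueError(f"column {c!r} is entirely missing")
        if n_obs < k_donors:
            raise ValueError(f"column {c!r} has fewer than k_donors={k_donors} "
                             "observed values")
    targets.sort(key=lambda c: (int(miss_counts[c]), num_cols.index(c)))
    mask = table.isna() & table.columns.isin(num_cols)

    datasets = []
    for imp in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), imp]))
        work = work_template.copy()
        for c in targets:
            mis = work[c].isna()
            obs_vals = work.loc[~mis, c].to_numpy()
            work.loc[mis, c] = rng.choice(obs_vals, size=int(mis.sum()))
        if targets:
            for _ in range(n_iterations):
                for c in targets:
                    mis = work_template[c].isna().to_numpy()
                    others = [v for v in num_cols if v != c]
                    Xall = np.column_stack([np.ones(len(work)),
                                            work[others].to_numpy()])
                    yo = work_template.loc[~mis, c].to_numpy()
                    beta_hat, beta_star = _bayes_draw_regression(
                        Xall[~mis], yo, rng)
                    pred_obs = Xall[~mis] @ beta_hat
                    pred_mis = Xall[mis] @ beta_star
                    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
                    kk = min(k_donors, dist.shape[1])
                    donors = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
                    pick = donors[np.arange(len(pred_mis)),
                                  rng.integers(0, kk, size=len(pred_mis))]
                    work.loc[mis, c] = yo[pick]
        completed = table.copy()
        for c in num_cols:
            completed[c] = work[c].to_numpy()
        datasets.append(completed)
    return ImputationStack(datasets=datasets, m=m, n_iterations=n_iterations,
                           seed=seed, mask=mask)


def rubin_pool(estimates, variances) -> tuple[float, float]:
    """Rubin's rule: pooled estimate and total variance across imputations.

    total = W + (1 + 1/m) B, with W the mean within-imputation variance and
    B the between-imputation variance of the estimates.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and equal length")
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rule requires m >= 2 imputations")
    pooled = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    return pooled, W + (1.0 + 1.0 / m) * B
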
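"""Bayesian outcome models with empirical-Bayes priors.

The workflow mirrors the trial's analysis plan: metric predictors and
Gaussian outcomes are z-standardised, dichotomous and ordinal predictors
are effect coded (-0.5, 0.5; cumulative contrasts for ordinal levels),
normal priors are centred on frequentist maximum-likelihood estimates with
a common scale per predictor family, models are sampled by Hamiltonian
Monte Carlo, convergence is checked via R-hat and effective sample size,
fits across multiple imputations are pooled by chain concatenation (or
Rubin's rule when diagnostics fail), and explained variance is summarised
by the Bayesian R-squared and its leave-one-predictor-out increment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import sampler
from .families import get_family
from .missingness import rubin_pool

logger = logging.getLogger(__name__)

__all__ = [
    "McmcSettings",
    "ModelSpec",
    "StandardizedDesign",
    "PriorSet",
    "PosteriorFit",
    "ConvergenceVerdict",
    "standardize",
    "FrequentistFit",
    "frequentist_mle",
    "fit_model_stack",
    "empirical_bayes_priors",
    "fit_model",
    "diagnose",
    "pool_fits",
    "bayes_r2",
    "incremental_r2",
]

WEAK_PRIOR = (0.0, 2.5)  # fallback when a frequentist fit does not converge


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; the defaults are the analysis' production settings.

    ``max_depth`` applies to tree-based samplers; the fixed-length HMC used
    here records it as not applicable in the provenance.
    """

    iterations: int = 8000
    burn_in: int = 4000
    chains: int = 8
    target_accept: float = 0.8
    max_depth: int = 15
    seed: int = 42

    @classmethod
    def fast(cls, seed: int = 42) -> "McmcSettings":
        """Reduced profile for tests and quick runs."""
        return cls(iterations=2000, burn_in=1000, chains=4, seed=seed)

    @property
    def kept(self) -> int:
        return self.iterations - self.burn_in


@dataclass(frozen=True)
class ModelSpec:
    """One outcome model: family, removable predictors, fixed covariates."""

    outcome: str
    family: str
    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    arm: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        overlap = set(self.predictors) & set(self.covariates)
        if overlap:
            raise ValueError(f"terms cannot be both predictor and covariate: "
                             f"{sorted(overlap)}")
        get_family(self.family)

    def without(self, predictor: str) -> "ModelSpec":
        if predictor not in self.predictors:
            raise ValueError(f"{predictor!r} is not a predictor of this model")
        return replace(self, predictors=tuple(p for p in self.predictors
                                              if p != predictor))

    @property
    def terms(self) -> tuple[str, ...]:
        return self.covariates + self.predictors


@dataclass
class StandardizedDesign:
    """Model-ready columns plus the applied scaling parameters.

    ``term_columns`` maps each original variable to its design column(s)
    (ordinal variables expand into cumulative contrasts).
    """

    table: pd.DataFrame
    term_columns: dict[str, list[str]]
    roles: dict[str, str]
    scaling: dict[str, tuple[float, float]]

    def matrix(self, terms) -> tuple[np.ndarray, list[str]]:
        cols: list[str] = []
        for t in terms:
            cols.extend(self.term_columns[t])
        X = np.column_stack([np.ones(len(self.table))]
                            + [self.table[c].to_numpy(dtype=float) for c in cols])
        return X, ["intercept"] + cols

    def outcome(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


def standardize(table: pd.DataFrame, roles: dict[str, str]) -> StandardizedDesign:
    """Apply the analysis' variable coding.

    Roles: ``metric`` -> z-scored (sample SD); ``binary`` -> effect coded
    (-0.5, 0.5); ``ordinal`` -> cumulative (-0.5, 0.5) contrasts, one per
    threshold; ``count``, ``binary_outcome``, ``unit`` and ``passthrough``
    -> unchanged (counts for negative-binomial outcomes stay counts).
    """
    out: dict[str, np.ndarray] = {}
    term_columns: dict[str, list[str]] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for var, role in roles.items():
        x = table[var]
        if role == "metric":
            vals = x.to_numpy(dtype=float)
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"metric column {var!r} has zero variance")
            out[var] = (vals - mu) / sd
            scaling[var] = (mu, sd)
            term_columns[var] = [var]
        elif role == "binary":
            levels = sorted(pd.unique(x.dropna()))
            if len(levels) != 2:
                raise ValueError(f"binary column {var!r} must have exactly two "
                                 f"levels, found {levels}")
            out[var] = np.where(x == levels[1], 0.5, -0.5)
            term_columns[var] = [var]
        elif role == "ordinal":
            levels = sorted(pd.unique(x.dropna()))
            if len(levels) < 2:
                raise ValueError(f"ordinal column {var!r} needs >= 2 levels")
            cols = []
            for j, thr in enumerate(levels[:-1], start=1):
                name = f"{var}_ge{j + 1}"
                out[name] = np.where(x > thr, 0.5, -0.5)
                cols.append(name)
            term_columns[var] = cols
        elif role in ("count", "binary_outcome", "unit", "passthrough"):
            out[var] = x.to_numpy(dtype=float)
            term_columns[var] = [var]
        else:
            raise ValueError(f"unknown role {role!r} for column {var!r}")
    design = pd.DataFrame(out, index=table.index)
    return StandardizedDesign(table=design, term_columns=term_columns,
                              roles=dict(roles), scaling=scaling)


@dataclass
class PriorSet:
    """Normal priors per coefficient plus a log-normal auxiliary prior.

    ``coef`` maps design-column names to (location, base scale); the
    effective scale is base scale x ``scale_multiplier``.
    """

    coef: dict[str, tuple[float, float]]
    aux: tuple[float, float] = (0.0, 1.0)
    scale_multiplier: float = 1.0
    fallbacks: tuple[str, ...] = ()

    def scaled(self, multiplier: float) -> "PriorSet":
        return PriorSet(coef=dict(self.coef), aux=self.aux,
                        scale_multiplier=multiplier, fallbacks=self.fallbacks)

    def location_scale(self, col: str) -> tuple[float, float]:
        loc, base = self.coef[col]
        return loc, base * self.scale_multiplier

    def aux_location_scale(self) -> tuple[float, float]:
        return self.aux[0], self.aux[1] * self.scale_multiplier


@dataclass
class FrequentistFit:
    coef: dict[str, tuple[float, float]]   # column -> (mle, se)
    aux: float | None
    converged: bool


def frequentist_mle(spec: ModelSpec, design: StandardizedDesign) -> FrequentistFit:
    """Maximum-likelihood fit of the full model, for prior construction."""
    import statsmodels.api as sm

    X, names = design.matrix(spec.terms)
    y = design.outcome(spec.outcome)
    aux = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if spec.family == "gaussian":
                res = sm.OLS(y, X).fit()
                params, bse = res.params, res.bse
                aux = float(np.sqrt(res.scale))
            elif spec.family == "bernoulli_logit":
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", False):
                    raise RuntimeError("Logit MLE did not converge")
                params, bse = res.params, res.bse
            elif spec.family == "negative_binomial":
                from statsmodels.discrete.discrete_model import NegativeBinomial
                res = NegativeBinomial(y, X).fit(disp=0, maxiter=200)
                params, bse = res.params[:-1], res.bse[:-1]
                alpha = float(res.params[-1])
                aux = 1.0 / max(alpha, 1e-3)      # NB2: Var = mu + alpha mu^2
            elif spec.family == "beta":
                from statsmodels.othermod.betareg import BetaModel
                res = BetaModel(y, X).fit(disp=0, maxiter=200)
                params, bse = res.params[:-1], res.bse[:-1]
                aux = float(np.exp(res.params[-1]))  # precision is log-linked
            else:  # pragma: no cover
                raise ValueError(spec.family)
        coef = {}
        ok = True
        for i, name in enumerate(names):
            mle, se = float(params[i]), float(bse[i])
            if not (np.isfinite(mle) and np.isfinite(se) and se < 50):
                ok = False
                mle, se = np.nan, np.nan
            coef[name] = (mle, se)
        return FrequentistFit(coef=coef, aux=aux, converged=ok)
    except Exception as exc:
        logger.warning("frequentist MLE failed for outcome %s (%s): %s; "
                       "weak priors will be used", spec.outcome, spec.family, exc)
        return FrequentistFit(coef={n: (np.nan, np.nan) for n in names},
                              aux=None, converged=False)


def empirical_bayes_priors(freq_fit: FrequentistFit,
                           column_family: dict[str, str],
                           scale_multiplier: float = 1.0,
                           aux_scale: float = 1.0) -> PriorSet:
    """Empirical-Bayes normal priors from frequentist MLEs.

    Locations are the MLEs. Columns sharing a predictor-family label get a
    common scale, max(SD of the family's MLEs, mean of their SEs); a
    single-member family falls back to its SE. Non-converged coefficients
    get the weak (0, 2.5) prior and are recorded in ``fallbacks``.
    """
    groups: dict[str, list[str]] = {}
    for col in freq_fit.coef:
        groups.setdefault(column_family.get(col, col), []).append(col)

    coef: dict[str, tuple[float, float]] = {}
    fallbacks: list[str] = []
    for label, cols in groups.items():
        mles = np.array([freq_fit.coef[c][0] for c in cols])
        ses = np.array([freq_fit.coef[c][1] for c in cols])
        good = np.isfinite(mles) & np.isfinite(ses)
        if good.sum() >= 2:
            scale = max(float(np.std(mles[good], ddof=1)),
                        float(np.mean(ses[good])))
        elif good.sum() == 1:
            scale = float(ses[good][0])
        else:
            scale = WEAK_PRIOR[1]
        if scale <= 0 or not np.isfinite(scale):
            scale = WEAK_PRIOR[1]
        for c, ok in zip(cols, good):
            if ok:
                coef[c] = (float(freq_fit.coef[c][0]), scale)
            else:
                coef[c] = WEAK_PRIOR
                fallbacks.append(c)
    if fallbacks:
        logger.info("weak priors substituted for %s", fallbacks)
    if freq_fit.aux is not None and np.isfinite(freq_fit.aux) and freq_fit.aux > 0:
        aux = (float(np.log(freq_fit.aux)), aux_scale)
    else:
        aux = (0.0, aux_scale)
    return PriorSet(coef=coef, aux=aux, scale_multiplier=scale_multiplier,
                    fallbacks=tuple(fallbacks))


@dataclass
class PosteriorFit:
    """Posterior draws with summaries, diagnostics and provenance.

    ``draws`` has shape (chains, kept iterations, parameters); ``loglik``
    holds pointwise log-likelihood draws (chains, kept, n) for LOO.
    """

    spec: ModelSpec
    param_names: list[str]
    coef_names: list[str]
    draws: np.ndarray | None
    summary: pd.DataFrame
    loglik: np.ndarray | None
    X: np.ndarray | None
    y: np.ndarray | None
    provenance: dict
    source_fits: list["PosteriorFit"] | None = None

    def cri_excludes_zero(self, term_columns: dict[str, list[str]] | None = None
                          ) -> dict[str, bool]:
        """Per predictor: does the 95% CrI exclude 0 (all of its columns)?"""
        out = {}
        for pred in self.spec.predictors:
            cols = (term_columns or {}).get(pred, [pred])
            flags = []
            for c in cols:
                row = self.summary.loc[c]
                flags.append(row["cri_lower"] > 0 or row["cri_upper"] < 0)
            out[pred] = all(flags)
        return out

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _summarize(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    flat = draws.reshape(-1, draws.shape[-1])
    return pd.DataFrame({
        "mean": flat.mean(axis=0),
        "sd": flat.std(axis=0, ddof=1),
        "cri_lower": np.percentile(flat, 2.5, axis=0),
        "cri_upper": np.percentile(flat, 97.5, axis=0),
    }, index=pd.Index(names, name="parameter"))


def _make_logpost(family, X, y, loc, scale, aux_loc, aux_scale):
    p = X.shape[1]

    def logp_and_grad(theta):
        theta = np.atleast_2d(theta)
        beta = theta[:, :p]
        eta = beta @ X.T
        if family.has_aux:
            u = theta[:, p]
            lp = family.loglik(y, eta, u).sum(axis=-1)
            d_eta = family.d_eta(y, eta, u)
            g_aux = family.d_logaux(y, eta, u).sum(axis=-1)
            g_aux = g_aux - (u - aux_loc) / aux_scale ** 2
        else:
            lp = family.loglik(y, eta).sum(axis=-1)
            d_eta = family.d_eta(y, eta)
            g_aux = None
        lp = lp - 0.5 * (((beta - loc) / scale) ** 2).sum(axis=1)
        if family.has_aux:
            lp = lp - 0.5 * ((theta[:, p] - aux_loc) / aux_scale) ** 2
        g_beta = d_eta @ X - (beta - loc) / scale ** 2
        grad = np.concatenate(
            [g_beta, g_aux[:, None]] if family.has_aux else [g_beta], axis=1)
        return lp, grad

    return logp_and_grad


@dataclass
class _Prepared:
    family: object
    X: np.ndarray
    y: np.ndarray
    coef_names: list[str]
    param_names: list[str]
    loc: np.ndarray
    scale: np.ndarray
    aux_loc: float
    aux_scale: float
    logpost: object
    x_map: np.ndarray
    inv_mass: np.ndarray


def _prepare(spec: ModelSpec, design: StandardizedDesign,
             priors: PriorSet) -> _Prepared:
    """Validate, build the log posterior and its Laplace preconditioner."""
    family = get_family(spec.family)
    X, coef_names = design.matrix(spec.terms)
    y = design.outcome(spec.outcome)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design contains missing values; impute first")
    family.check_outcome(y)
    missing_priors = [c for c in coef_names if c not in priors.coef]
    if missing_priors:
        raise ValueError(f"priors missing for coefficients: {missing_priors}")

    loc = np.array([priors.location_scale(c)[0] for c in coef_names])
    scale = np.array([priors.location_scale(c)[1] for c in coef_names])
    aux_loc, aux_scale = priors.aux_location_scale()
    logpost = _make_logpost(family, X, y, loc, scale, aux_loc, aux_scale)

    p = X.shape[1]
    dim = p + int(family.has_aux)
    param_names = list(coef_names) + (
        [f"log_{family.aux_name}"] if family.has_aux else [])

    def neg(theta):
        lp, g = logpost(theta[None, :])
        return -lp[0], -g[0]

    x_init = np.concatenate([loc, [aux_loc]] if family.has_aux else [loc])
    opt = optimize.minimize(neg, x_init, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    if not np.all(np.isfinite(opt.x)):
        raise FloatingPointError(
            f"non-finite posterior mode for outcome {spec.outcome!r}")
    x_map = opt.x

    # diagonal Laplace curvature -> inverse mass
    h = 1e-4
    hess_diag = np.empty(dim)
    for i in range(dim):
        e = np.zeros(dim)
        e[i] = h
        _, gp = logpost((x_map + e)[None, :])
        _, gm = logpost((x_map - e)[None, :])
        hess_diag[i] = -(gp[0, i] - gm[0, i]) / (2 * h)
    inv_mass = np.clip(1.0 / np.clip(hess_diag, 1e-6, None), 1e-6, 1e3)
    return _Prepared(family=family, X=X, y=y, coef_names=coef_names,
                     param_names=param_names, loc=loc, scale=scale,
                     aux_loc=aux_loc, aux_scale=aux_scale, logpost=logpost,
                     x_map=x_map, inv_mass=inv_mass)


def _finalize_fit(spec, prep: _Prepared, draws: np.ndarray, priors: PriorSet,
                  mcmc: McmcSettings, accept_rate: float, divergences: int,
                  imputation_index: int | None) -> PosteriorFit:
    p = prep.X.shape[1]
    dim = draws.shape[-1]
    flat = draws.reshape(-1, dim)
    if prep.family.has_aux:
        ll = prep.family.loglik(prep.y, flat[:, :p] @ prep.X.T, flat[:, p])
    else:
        ll = prep.family.loglik(prep.y, flat[:, :p] @ prep.X.T)
    loglik = ll.reshape(draws.shape[0], draws.shape[1], len(prep.y))
    summary = _summarize(draws, prep.param_names)
    provenance = {
        "sampler": "hmc", "iterations": mcmc.iterations,
        "burn_in": mcmc.burn_in, "chains": mcmc.chains,
        "target_accept": mcmc.target_accept,
        "max_depth": "n/a (fixed-length leapfrog)",
        "seed": mcmc.seed, "imputation_index": imputation_index,
        "accept_rate": accept_rate,
        "divergences": divergences,
        "scale_multiplier": priors.scale_multiplier,
        "pooling": "none",
    }
    return PosteriorFit(spec=spec, param_names=prep.param_names,
                        coef_names=prep.coef_names, draws=draws,
                        summary=summary, loglik=loglik, X=prep.X, y=prep.y,
                        provenance=provenance)


def fit_model(spec: ModelSpec, design: StandardizedDesign, priors: PriorSet,
              mcmc: McmcSettings | None = None,
              imputation_index: int | None = None) -> PosteriorFit:
    """Sample the posterior of one outcome model by HMC.

    The design must be complete (post-imputation); priors must cover every
    coefficient column. Link functions are log (negative binomial), logit
    (Bernoulli and beta mean) and identity (Gaussian).
    """
    mcmc = mcmc or McmcSettings()
    prep = _prepare(spec, design, priors)
    dim = len(prep.param_names)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(mcmc.seed), 0xBA7E5, imputation_index or 0]))
    x0 = prep.x_map[None, :] + 0.1 * np.sqrt(prep.inv_mass)[None, :] * \
        rng.standard_normal((mcmc.chains, dim))
    res = sampler.run_hmc(prep.logpost, x0, mcmc.iterations, mcmc.burn_in,
                          rng, inv_mass=prep.inv_mass,
                          target_accept=mcmc.target_accept)
    return _finalize_fit(spec, prep, res.draws, priors, mcmc,
                         float(res.accept_rate.mean()), res.n_divergent,
                         imputation_index)


def fit_model_stack(spec: ModelSpec, designs: list[StandardizedDesign],
                    priors: PriorSet, mcmc: McmcSettings | None = None
                    ) -> list[PosteriorFit]:
    """Fit the same model on every imputed design in one batched HMC run.

    Chains are partitioned across imputations (m x chains in total), each
    chain targeting its own completed dataset's posterior; this amortises
    the sampler's per-iteration cost over the whole stack and is the
    workhorse behind elimination and sensitivity loops.
    """
    mcmc = mcmc or McmcSettings()
    if len(designs) == 1:
        return [fit_model(spec, designs[0], priors, mcmc, imputation_index=0)]
    preps = [_prepare(spec, d, priors) for d in designs]
    family = preps[0].family
    p = preps[0].X.shape[1]
    dim = len(preps[0].param_names)
    m = len(preps)
    C = m * mcmc.chains
    g = np.repeat(np.arange(m), mcmc.chains)
    Xc = np.stack([pr.X for pr in preps])[g]       # (C, n, p)
    yc = np.stack([pr.y for pr in preps])[g]       # (C, n)
    loc, scale = preps[0].loc, preps[0].scale
    aux_loc, aux_scale = preps[0].aux_loc, preps[0].aux_scale

    def logpost(theta):
        beta = theta[:, :p]
        eta = np.einsum("cnp,cp->cn", Xc, beta)
        if family.has_aux:
            u = theta[:, p]
            lp = family.loglik(yc, eta, u).sum(axis=-1)
            d_eta = family.d_eta(yc, eta, u)
            g_aux = family.d_logaux(yc, eta, u).sum(axis=-1)
            g_aux = g_aux - (u - aux_loc) / aux_scale ** 2
        else:
            lp = family.loglik(yc, eta).sum(axis=-1)
            d_eta = family.d_eta(yc, eta)
            g_aux = None
        lp = lp - 0.5 * (((beta - loc) / scale) ** 2).sum(axis=1)
        if family.has_aux:
            lp = lp - 0.5 * ((theta[:, p] - aux_loc) / aux_scale) ** 2
        g_beta = np.einsum("cn,cnp->cp", d_eta, Xc) - (beta - loc) / scale ** 2
        grad = np.concatenate(
            [g_beta, g_aux[:, None]] if family.has_aux else [g_beta], axis=1)
        return lp, grad

    inv_mass = np.stack([pr.inv_mass for pr in preps])[g]
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(mcmc.seed), 0x57ACC]))
    x0 = np.stack([pr.x_map for pr in preps])[g]
    x0 = x0 + 0.1 * np.sqrt(inv_mass) * rng.standard_normal((C, dim))
    res = sampler.run_hmc(logpost, x0, mcmc.iterations, mcmc.burn_in, rng,
                          inv_mass=inv_mass, target_accept=mcmc.target_accept)
    fits = []
    for i, prep in enumerate(preps):
        sl = slice(i * mcmc.chains, (i + 1) * mcmc.chains)
        fits.append(_finalize_fit(
            spec, prep, res.draws[sl], priors, mcmc,
            float(res.accept_rate[sl].mean()), res.n_divergent, i))
    return fits


@dataclass
class ConvergenceVerdict:
    passed: bool
    indeterminate: bool
    max_rhat: float
    min_ess: float


def diagnose(fit: PosteriorFit, ess_threshold: float = 1000.0,
             rhat_threshold: float = 1.1) -> ConvergenceVerdict:
    """Pass iff every parameter has ESS >= 1000 and R-hat < 1.1.

    With a single chain R-hat is undefined and the verdict indeterminate.
    """
    import arviz as az

    draws = fit.draws
    if draws is None:
        raise ValueError("fit has no draws (Rubin-pooled summaries only)")
    if draws.shape[0] < 2:
        return ConvergenceVerdict(passed=False, indeterminate=True,
                                  max_rhat=float("nan"), min_ess=float("nan"))
    data = {name: draws[:, :, i] for i, name in enumerate(fit.param_names)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(data)
        ess = az.ess(data)
    max_rhat = float(max(rhat[k].item() for k in rhat.data_vars))
    min_ess = float(min(ess[k].item() for k in ess.data_vars))
    return ConvergenceVerdict(passed=max_rhat < rhat_threshold
                              and min_ess >= ess_threshold,
                              indeterminate=False,
                              max_rhat=max_rhat, min_ess=min_ess)


def pool_fits(fits: list[PosteriorFit],
              ess_threshold: float = 1000.0) -> PosteriorFit:
    """Pool per-imputation fits.

    If every fit passes convergence diagnostics, the pooled posterior is the
    chain concatenation (m x chains chains). Otherwise coefficients are
    pooled by Rubin's rule on posterior means and variances, and only
    summaries are available (CrI from the t reference with Barnard-Rubin
    degrees of freedom).
    """
    if not fits:
        raise ValueError("no fits to pool")
    spec = fits[0].spec
    for f in fits[1:]:
        if f.spec != spec or f.param_names != fits[0].param_names:
            raise ValueError("fits must share the model spec to be pooled")
    if len(fits) == 1:
        return fits[0]

    verdicts = [diagnose(f, ess_threshold=ess_threshold) for f in fits]
    if all(v.passed for v in verdicts):
        draws = np.concatenate([f.draws for f in fits], axis=0)
        summary = _summarize(draws, fits[0].param_names)
        prov = dict(fits[0].provenance)
        prov.update(pooling="combine", n_imputations=len(fits))
        return PosteriorFit(spec=spec, param_names=fits[0].param_names,
                            coef_names=fits[0].coef_names, draws=draws,
                            summary=summary, loglik=None, X=None, y=None,
                            provenance=prov, source_fits=list(fits))

    m = len(fits)
    rows = []
    for name in fits[0].param_names:
        est = [f.summary.loc[name, "mean"] for f in fits]
        var = [f.summary.loc[name, "sd"] ** 2 for f in fits]
        pooled, total = rubin_pool(est, var)
        B = float(np.var(est, ddof=1))
        W = float(np.mean(var))
        if B > 0:
            df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        else:
            df = np.inf
        half = stats.t.ppf(0.975, df) * np.sqrt(total)
        rows.append((pooled, np.sqrt(total), pooled - half, pooled + half))
    summary = pd.DataFrame(rows, columns=["mean", "sd", "cri_lower", "cri_upper"],
                           index=pd.Index(fits[0].param_names, name="parameter"))
    prov = dict(fits[0].provenance)
    prov.update(pooling="rubin", n_imputations=m)
    return PosteriorFit(spec=spec, param_names=fits[0].param_names,
                        coef_names=fits[0].coef_names, draws=None,
                        summary=summary, loglik=None, X=None, y=None,
                        provenance=prov, source_fits=list(fits))


def _r2_draws_single(fit: PosteriorFit) -> np.ndarray:
    family = get_family(fit.spec.family)
    p = fit.X.shape[1]
    flat = fit.flat_draws
    eta = flat[:, :p] @ fit.X.T
    mu = family.mean(eta)
    var_fit = mu.var(axis=-1, ddof=1)
    if family.has_aux:
        resid = family.resid_variance(eta, flat[:, p]).mean(axis=-1)
    else:
        resid = family.resid_variance(eta).mean(axis=-1)
    return var_fit / (var_fit + resid)


def bayes_r2(fit: PosteriorFit, design: StandardizedDesign | None = None
             ) -> tuple[np.ndarray, pd.Series]:
    """Draw-wise Bayesian R-squared: Var(fitted) / (Var(fitted) + expected
    residual variance), on the response scale. Returns (draws, summary)."""
    if fit.X is not None:
        r2 = _r2_draws_single(fit)
    elif fit.source_fits is not None and fit.provenance.get("pooling") == "combine":
        r2 = np.concatenate([_r2_draws_single(f) for f in fit.source_fits])
    else:
        raise ValueError("Bayesian R2 needs draws with their design "
                         "(not available for Rubin-pooled fits)")
    summary = pd.Series({
        "mean": r2.mean(), "sd": r2.std(ddof=1),
        "cri_lower": np.percentile(r2, 2.5),
        "cri_upper": np.percentile(r2, 97.5),
    })
    return r2, summary


def incremental_r2(fit_full: PosteriorFit, fit_reduced: PosteriorFit,
                   design: StandardizedDesign | None = None
                   ) -> tuple[np.ndarray, pd.Series, dict]:
    """Delta R2 for the one predictor dropped between the two fits.

    Per matched draw index, Delta R2 = max(R2_full - R2_reduced, 0); the
    unclipped summary is returned in the diagnostics dict.
    """
    removed = set(fit_full.spec.predictors) - set(fit_reduced.spec.predictors)
    same_rest = (fit_full.spec.outcome == fit_reduced.spec.outcome
                 and fit_full.spec.family == fit_reduced.spec.family
                 and fit_full.spec.covariates == fit_reduced.spec.covariates)
    if len(removed) != 1 or not same_rest or \
            set(fit_reduced.spec.predictors) - set(fit_full.spec.predictors):
        raise ValueError("specs must differ by exactly one predictor")
    r2f, _ = bayes_r2(fit_full)
    r2r, _ = bayes_r2(fit_reduced)
    k = min(len(r2f), len(r2r))
    raw = r2f[:k] - r2r[:k]
    delta = np.maximum(raw, 0.0)
    summary = pd.Series({
        "mean": delta.mean(), "sd": delta.std(ddof=1),
        "cri_lower": np.percentile(delta, 2.5),
        "cri_upper": np.percentile(delta, 97.5),
    })
    diag = {"predictor": removed.pop(), "unclipped_mean": float(raw.mean()),
            "unclipped_cri": (float(np.percentile(raw, 2.5)),
                              float(np.percentile(raw, 97.5)))}
    return delta, summary, diag
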
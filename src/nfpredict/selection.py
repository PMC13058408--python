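"""Predictor selection and robustness.

Collinearity screening by (adjusted) generalized variance inflation
factors, backward elimination of predictors whose 95% credible interval
includes 0 (starting with the posterior mean closest to 0, covariates never
removed) guarded by leave-one-out expected log predictive density — an ELPD
drop > 4 after an exclusion reinstates the predictor permanently — and a
prior-sensitivity suite at scale multipliers {1, 2, 0.5} whose conjunction
yields the influential-predictor verdict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sampler as _sampler
from .bayes import (McmcSettings, ModelSpec, PosteriorFit, PriorSet,
                    StandardizedDesign, _make_logpost, _summarize, fit_model,
                    fit_model_stack, pool_fits)
from .families import get_family

logger = logging.getLogger(__name__)

__all__ = [
    "gvif_filter",
    "LooResult",
    "loo_elpd",
    "pooled_elpd",
    "EliminationTrace",
    "backward_eliminate",
    "sensitivity_suite",
    "RobustnessVerdict",
    "robustness_verdict",
]

GVIF_THRESHOLD = 5.0
ELPD_GUARD = 4.0
SENSITIVITY_MULTIPLIERS = (1.0, 2.0, 0.5)


def _gvif(R: pd.DataFrame, cols: list[str]) -> float:
    others = [c for c in R.columns if c not in cols]
    if not others:
        return 1.0
    det_all = np.linalg.det(R.to_numpy())
    if det_all < 1e-12:
        return float("inf")
    det_1 = np.linalg.det(R.loc[cols, cols].to_numpy())
    det_2 = np.linalg.det(R.loc[others, others].to_numpy())
    return float(det_1 * det_2 / det_all)


def gvif_filter(design: StandardizedDesign, predictors,
                covariates=(), threshold: float = GVIF_THRESHOLD
                ) -> tuple[list[str], list[dict]]:
    """Iteratively drop the predictor with the highest collinearity criterion.

    Single-column terms are judged on the plain VIF, multi-column terms on
    GVIF^(1/(2 df)) squared, both against the same threshold. Covariates
    enter the correlation structure but are never removed. Exact duplicates
    are removed first with an explicit log entry.
    """
    retained = list(predictors)
    removal_log: list[dict] = []

    def columns_of(terms):
        cols = []
        for t in terms:
            cols.extend(design.term_columns[t])
        return cols

    # perfectly collinear duplicates go first
    seen: dict[bytes, str] = {}
    for t in list(covariates) + retained:
        for c in design.term_columns[t]:
            key = design.table[c].to_numpy().tobytes()
            if key in seen and t in retained:
                retained.remove(t)
                removal_log.append({"predictor": t, "criterion": float("inf"),
                                    "reason": f"exact duplicate of {seen[key]!r}"})
                break
            seen.setdefault(key, t)

    while retained:
        cols = columns_of(list(covariates) + retained)
        R = pd.DataFrame(np.corrcoef(design.table[cols].to_numpy(), rowvar=False),
                         index=cols, columns=cols)
        crit = {}
        for t in retained:
            tcols = design.term_columns[t]
            g = _gvif(R, tcols)
            d = len(tcols)
            crit[t] = g if d == 1 else (g ** (1.0 / (2 * d))) ** 2
        worst = max(crit, key=lambda t: crit[t])
        if crit[worst] <= threshold:
            break
        retained.remove(worst)
        removal_log.append({"predictor": worst, "criterion": crit[worst],
                            "reason": f"criterion {crit[worst]:.2f} > {threshold}"})
    return retained, removal_log


@dataclass
class LooResult:
    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray | None
    method: str


def _psis_loo(fit: PosteriorFit) -> LooResult:
    import arviz as az

    idata = az.from_dict(
        posterior={"theta": fit.draws[:, :, :1]},
        log_likelihood={"y": fit.loglik})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(elpd=float(res.elpd_loo), se=float(res.se),
                     pointwise=np.asarray(res.loo_i.values),
                     pareto_k=np.asarray(res.pareto_k.values), method="psis")


def _exact_refits(fit: PosteriorFit, indices, priors: PriorSet,
                  mcmc: McmcSettings) -> dict[int, float]:
    """Exact leave-one-out elpd for the given observations.

    All refits run as one batched HMC: each group of chains targets the
    posterior with one observation held out, initialised and preconditioned
    from the full-data fit.
    """
    from scipy.special import logsumexp

    indices = [int(i) for i in indices]
    family = get_family(fit.spec.family)
    n = len(fit.y)
    p = fit.X.shape[1]
    dim = len(fit.param_names)
    loc = np.array([priors.location_scale(c)[0] for c in fit.coef_names])
    scale = np.array([priors.location_scale(c)[1] for c in fit.coef_names])
    aux_loc, aux_scale = priors.aux_location_scale()

    G = len(indices)
    C = G * mcmc.chains
    g = np.repeat(np.arange(G), mcmc.chains)
    keep_rows = np.stack([np.arange(n) != i for i in indices])   # (G, n)
    Xs = np.stack([fit.X[keep_rows[j]] for j in range(G)])       # (G, n-1, p)
    ys = np.stack([fit.y[keep_rows[j]] for j in range(G)])
    Xc, yc = Xs[g], ys[g]

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

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(mcmc.seed), 0x100E, *indices]))
    x0 = np.tile(fit.flat_draws.mean(axis=0), (C, 1))
    x0 += 0.05 * rng.standard_normal(x0.shape)
    res = _sampler.run_hmc(logpost, x0, mcmc.iterations, mcmc.burn_in, rng,
                           inv_mass=fit.flat_draws.var(axis=0) + 1e-8,
                           target_accept=mcmc.target_accept)
    out = {}
    for j, i in enumerate(indices):
        flat = res.draws[j * mcmc.chains:(j + 1) * mcmc.chains].reshape(-1, dim)
        eta_i = flat[:, :p] @ fit.X[i]
        if family.has_aux:
            ll_i = family.loglik(fit.y[i], eta_i[:, None], flat[:, p])[:, 0]
        else:
            ll_i = family.loglik(fit.y[i], eta_i[:, None])[:, 0]
        out[i] = float(logsumexp(ll_i) - np.log(len(ll_i)))
    return out


def loo_elpd(fit: PosteriorFit, priors: PriorSet | None = None,
             mcmc: McmcSettings | None = None,
             k_threshold: float = 0.7, max_exact_n: int = 50) -> LooResult:
    """LOO expected log predictive density by Pareto-smoothed importance
    sampling; observations whose Pareto k exceeds ``k_threshold`` are
    re-evaluated by exact refits when n <= ``max_exact_n`` and the prior/
    sampler context is supplied."""
    if fit.loglik is None:
        raise ValueError("fit has no pointwise log-likelihood draws")
    res = _psis_loo(fit)
    flagged = np.where(res.pareto_k > k_threshold)[0]
    n = fit.loglik.shape[-1]
    if len(flagged) and n <= max_exact_n and priors is not None and mcmc is not None:
        pw = res.pointwise.copy()
        for i, v in _exact_refits(fit, flagged, priors, mcmc).items():
            pw[i] = v
        return LooResult(elpd=float(pw.sum()),
                         se=float(np.sqrt(n * pw.var(ddof=1))),
                         pointwise=pw, pareto_k=res.pareto_k,
                         method="psis+exact_refit")
    return res


def exact_loo(fit: PosteriorFit, priors: PriorSet, mcmc: McmcSettings
              ) -> LooResult:
    """Brute-force leave-one-out: one refit per observation."""
    n = len(fit.y)
    vals = _exact_refits(fit, range(n), priors, mcmc)
    pw = np.array([vals[i] for i in range(n)])
    return LooResult(elpd=float(pw.sum()), se=float(np.sqrt(n * pw.var(ddof=1))),
                     pointwise=pw, pareto_k=None, method="exact_refit")


def pooled_elpd(fits: list[PosteriorFit], priors: PriorSet | None = None,
                mcmc: McmcSettings | None = None) -> tuple[float, float]:
    """ELPD pooled across imputations: the mean of the per-imputation LOO
    elpd values (each imputation scores its own completed data)."""
    results = [loo_elpd(f, priors, mcmc) for f in fits]
    elpd = float(np.mean([r.elpd for r in results]))
    se = float(np.mean([r.se for r in results]))
    return elpd, se


@dataclass
class EliminationTrace:
    steps: list[dict] = field(default_factory=list)
    final_spec: ModelSpec | None = None
    final_fit: PosteriorFit | None = None
    final_fits: list[PosteriorFit] | None = None
    final_elpd: float = float("nan")
    final_elpd_se: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _fit_stack(spec: ModelSpec, designs: list[StandardizedDesign],
               priors: PriorSet, mcmc: McmcSettings, cache: dict | None = None):
    key = (spec, priors.scale_multiplier)
    if cache is not None and key in cache:
        return cache[key]
    fits = fit_model_stack(spec, designs, priors, mcmc)
    pooled = pool_fits(fits)
    elpd, se = pooled_elpd(fits, priors, mcmc)
    out = (pooled, fits, elpd, se)
    if cache is not None:
        cache[key] = out
    return out


def backward_eliminate(spec: ModelSpec, designs: list[StandardizedDesign],
                       priors: PriorSet, mcmc: McmcSettings | None = None,
                       elpd_guard: float = ELPD_GUARD,
                       cache: dict | None = None
                       ) -> tuple[ModelSpec, EliminationTrace]:
    """Stepwise CrI-based backward elimination with the ELPD guard.

    Among predictors whose pooled 95% CrI includes 0, the one with posterior
    mean closest to 0 is removed; if the pooled LOO-ELPD drops by more than
    ``elpd_guard``, it is reinstated and never reconsidered. Covariates are
    never candidates. An empty final predictor set is legal.
    """
    mcmc = mcmc or McmcSettings()
    term_columns = designs[0].term_columns
    trace = EliminationTrace()
    current = spec
    pooled, fits, elpd, se = _fit_stack(current, designs, priors, mcmc, cache)
    reinstated: set[str] = set()

    while current.predictors:
        excludes = pooled.cri_excludes_zero(term_columns)
        candidates = [p for p in current.predictors
                      if p not in reinstated and not excludes[p]]
        if not candidates:
            break

        def closeness(p):
            cols = term_columns.get(p, [p])
            return min(abs(pooled.summary.loc[c, "mean"]) for c in cols)

        cand = min(candidates, key=closeness)
        cols = term_columns.get(cand, [cand])
        cand_mean = float(pooled.summary.loc[cols[0], "mean"])
        cand_cri = (float(pooled.summary.loc[cols[0], "cri_lower"]),
                    float(pooled.summary.loc[cols[0], "cri_upper"]))
        reduced = current.without(cand)
        pooled_r, fits_r, elpd_r, se_r = _fit_stack(reduced, designs, priors,
                                                    mcmc, cache)
        step = {"candidate": cand, "posterior_mean": cand_mean,
                "cri_lower": cand_cri[0], "cri_upper": cand_cri[1],
                "elpd_before": elpd, "elpd_before_se": se,
                "elpd_after": elpd_r, "elpd_after_se": se_r}
        if elpd - elpd_r > elpd_guard:
            step["action"] = "reinstated"
            reinstated.add(cand)
            logger.info("reinstated %s (ELPD drop %.2f > %.1f)",
                        cand, elpd - elpd_r, elpd_guard)
        else:
            step["action"] = "removed"
            current, pooled, fits, elpd, se = reduced, pooled_r, fits_r, elpd_r, se_r
        trace.steps.append(step)

    for p in reinstated:
        trace.steps.append({"candidate": p, "action": "retained",
                            "posterior_mean": float("nan"),
                            "cri_lower": float("nan"), "cri_upper": float("nan"),
                            "elpd_before": elpd, "elpd_before_se": se,
                            "elpd_after": elpd, "elpd_after_se": se})
    trace.final_spec = current
    trace.final_fit = pooled
    trace.final_fits = fits
    trace.final_elpd, trace.final_elpd_se = elpd, se
    return current, trace


def sensitivity_suite(final_spec: ModelSpec, designs: list[StandardizedDesign],
                      priors: PriorSet, mcmc: McmcSettings | None = None,
                      multipliers=SENSITIVITY_MULTIPLIERS,
                      cache: dict | None = None) -> dict[float, PosteriorFit]:
    """Refit the final model at prior-scale multipliers {1, 2, 0.5}."""
    mcmc = mcmc or McmcSettings()
    out: dict[float, PosteriorFit] = {}
    for mult in multipliers:
        pooled, _, _, _ = _fit_stack(final_spec, designs,
                                     priors.scaled(mult), mcmc, cache)
        out[mult] = pooled
    return out


@dataclass
class RobustnessVerdict:
    """Per predictor: CrI-excludes-zero at each multiplier; influential is
    the conjunction over the main and both sensitivity analyses."""

    table: pd.DataFrame

    def influential(self, predictor: str) -> bool:
        return bool(self.table.loc[predictor, "influential"])


def robustness_verdict(fits: dict[float, PosteriorFit],
                       term_columns: dict[str, list[str]] | None = None
                       ) -> RobustnessVerdict:
    specs = {f.spec for f in fits.values()}
    if len(specs) != 1:
        raise ValueError("sensitivity fits must share the final model spec")
    missing = set(SENSITIVITY_MULTIPLIERS) - set(fits)
    if missing:
        raise ValueError(f"missing sensitivity multipliers: {sorted(missing)}")
    spec = specs.pop()
    rows = {}
    for pred in spec.predictors:
        flags = {m: fits[m].cri_excludes_zero(term_columns)[pred]
                 for m in SENSITIVITY_MULTIPLIERS}
        rows[pred] = {"excludes_zero_main": flags[1.0],
                      "excludes_zero_doubled": flags[2.0],
                      "excludes_zero_halved": flags[0.5],
                      "influential": all(flags.values())}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "predictor"
    return RobustnessVerdict(table=table)
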
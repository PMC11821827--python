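"""Zero-one-inflated beta (ZOIB) Bayesian regression.

The ZOIB distribution on [0, 1] mixes point masses at 0 and 1 with a beta
density on (0, 1):

    P(Y = 0)        = p01 * (1 - cond_one)
    P(Y = 1)        = p01 * cond_one
    f(y), 0 < y < 1 = (1 - p01) * Beta(y; mu * phi, (1 - mu) * phi)

where ``p01`` is the total point-mass probability, ``cond_one`` the
conditional probability of a one given a point mass, and the beta component
is mean/precision parameterized (mean ``mu`` in (0, 1), precision
``phi`` > 0). The commonly used zero-inflation/one-inflation weights map as
``zoi = p01`` and ``coi = cond_one``.

Regression links ``mu`` to predictors through a logit: categorical designs
(trait-category severity models) or numeric designs (impacted-FE counts per
driver class). Priors: flat on coefficients, Student-t(3, 0, 2.5) on the
intercept, Gamma(0.01, 0.01) on phi, Beta(1, 1) on the point-mass
probabilities.

Sampling: the point-mass probabilities are conjugate given the observed
zero/one counts and are drawn exactly by Gibbs; the beta-regression block
(intercept, coefficients, log phi) is updated by componentwise random-walk
Metropolis with Robbins-Monro scale adaptation during warmup. Several
Metropolis sweeps are performed per recorded draw, so that a fixed chain
plan (chains x draws, warmup) yields well-mixed retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit
from scipy.stats import beta as beta_dist

from .trait_data import MortalityRecord, TraitTable, ValidationError

__all__ = [
    "ChainPlan",
    "SEVERITY_PLAN",
    "VOLUME_PLAN",
    "ZOIBPosterior",
    "SeverityByCategory",
    "ConvergenceError",
    "SingleCategoryError",
    "zoib_logdensity",
    "zoib_rvs",
    "split_rhat",
    "bayes_r2",
    "fit_zoib",
    "fit_severity_model",
    "fit_volume_model",
]

RHAT_THRESHOLD = 1.01


class ConvergenceError(RuntimeError):
    """Raised when chains fail the split R-hat contract after the chain plan."""


class SingleCategoryError(ValueError):
    """Raised when a trait has fewer than two observed categories."""


@dataclass(frozen=True)
class ChainPlan:
    """MCMC budget: per-chain iterations (including warmup) and warmup length."""

    chains: int = 2
    draws: int = 2000
    warmup: int = 1000
    sweeps: int = 5  # Metropolis sweeps per recorded draw

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws <= self.warmup or self.warmup < 0:
            raise ValidationError(f"invalid chain plan {self}")

    @property
    def kept_per_chain(self) -> int:
        return self.draws - self.warmup


SEVERITY_PLAN = ChainPlan(chains=2, draws=2000, warmup=1000)
VOLUME_PLAN = ChainPlan(chains=2, draws=3000, warmup=1000, sweeps=25)


def zoib_logdensity(y, mu, phi, p01, cond_one):
    """Pointwise log-density of the ZOIB distribution (vectorized over y).

    ``y`` in [0, 1]; ``mu`` in (0, 1); ``phi`` > 0; ``p01``, ``cond_one``
    in [0, 1]. Point masses use exact log-probabilities (log 0 = -inf when
    a mass is absent).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("y outside [0, 1]")
    if not (0 < mu < 1) or phi <= 0 or not (0 <= p01 <= 1) or not (0 <= cond_one <= 1):
        raise ValidationError("ZOIB parameters out of range")
    with np.errstate(divide="ignore"):
        out = np.where(
            y == 0,
            np.log(p01 * (1 - cond_one)),
            np.where(
                y == 1,
                np.log(p01 * cond_one),
                np.log1p(-p01) + beta_dist.logpdf(y, mu * phi, (1 - mu) * phi),
            ),
        )
    return out if out.ndim else float(out)


def zoib_rvs(rng: np.random.Generator, mu, phi, p01, cond_one, size=None):
    """Draw from the ZOIB distribution; ``mu`` may be an array of means."""
    mu = np.asarray(mu, dtype=float)
    shape = mu.shape if size is None else size
    u = rng.random(shape)
    y = rng.beta(mu * phi, (1 - mu) * phi, size=shape)
    y = np.where(u < p01, np.where(rng.random(shape) < cond_one, 1.0, 0.0), y)
    return y


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat of one parameter's draws (chains x draws).

    Constant chains return 1.0 by convention (with a warning): a parameter
    with no variation carries no convergence information.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError(f"need >= 2 chains of draws, got shape {x.shape}")
    if x.shape[1] < 4:
        raise ValidationError("need >= 4 draws per chain for split R-hat")
    if np.ptp(x) == 0:
        warnings.warn("constant chains: split R-hat undefined, returning 1.0", stacklevel=2)
        return 1.0
    import arviz as az

    return float(az.rhat(az.convert_to_dataset(x), method="rank")["x"])


def bayes_r2(fitted_draws: np.ndarray, response: np.ndarray) -> dict:
    """Bayesian R-squared: per-draw var(fitted) / (var(fitted) + var(residual)).

    ``fitted_draws`` is (draws, n_obs); residuals are response minus fitted.
    Returns the draws with median and central 95% interval.
    """
    fitted = np.atleast_2d(np.asarray(fitted_draws, dtype=float))
    y = np.asarray(response, dtype=float)
    var_fit = fitted.var(axis=1)
    if np.all(var_fit < 1e-18):  # constant fitted values up to rounding
        raise ValidationError("zero-variance fitted values: R-squared undefined")
    var_res = (y[np.newaxis, :] - fitted).var(axis=1)
    r2 = var_fit / (var_fit + var_res)
    return {
        "draws": r2,
        "median": float(np.median(r2)),
        "q2.5": float(np.quantile(r2, 0.025)),
        "q97.5": float(np.quantile(r2, 0.975)),
    }


@dataclass
class ZOIBPosterior:
    """Posterior draws and diagnostics for a fitted ZOIB regression."""

    draws: dict[str, np.ndarray]  # name -> (chains, kept_draws)
    rhat: dict[str, float]
    plan: ChainPlan
    seed: int
    coef_names: tuple[str, ...]
    r2: dict | None = None
    category_mean_draws: dict[str, np.ndarray] | None = None  # category -> flat draws (%)

    @property
    def n_retained(self) -> int:
        return self.plan.chains * self.plan.kept_per_chain

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        d = self.flat(name)
        return float(np.quantile(d, lo)), float(np.quantile(d, 1 - lo))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in self.draws.items():
            flat = d.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": self.rhat[name],
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SeverityByCategory:
    """Posterior mean mortality (%) with 95% credible interval, per category."""

    trait: str
    category: str
    mean_percent: float
    ci_low: float
    ci_high: float


def _log_t3(x: float, scale: float = 2.5) -> float:
    # Student-t(df=3, loc=0, scale) log-density up to the constant
    return -2.0 * np.log1p((x / scale) ** 2 / 3.0)


def _make_logpost(Z, n_g, sly, sl1my, means_mode: bool):
    """Log posterior of the continuous block given per-group beta stats.

    ``means_mode``: theta = (eta_1..eta_G, log phi) with a Student-t prior on
    the reference-group eta (the intercept) and flat priors on the contrasts
    — a reparameterization of reference coding with unit Jacobian, used for
    saturated categorical designs where it removes the intercept/coefficient
    posterior correlation. Otherwise theta = (intercept, coefs, log phi)
    with eta = intercept + Z @ coefs.
    """

    def logpost(theta):
        log_phi = theta[-1]
        if abs(log_phi) > 30:
            return -np.inf
        phi = np.exp(log_phi)
        if means_mode:
            eta = theta[:-1]
            intercept = theta[0]
        else:
            intercept = theta[0]
            coefs = theta[1:-1]
            eta = intercept + (Z @ coefs if Z.shape[1] else 0.0)
        mu = np.clip(expit(np.clip(eta, -35, 35)), 1e-12, 1 - 1e-12)
        a = mu * phi
        b = (1 - mu) * phi
        ll = np.sum((a - 1) * sly + (b - 1) * sl1my - n_g * betaln(a, b))
        # priors: flat coefs; t3 intercept; Gamma(0.01, 0.01) on phi + log-Jacobian
        lp = _log_t3(intercept) + 0.01 * log_phi - 0.01 * phi + log_phi
        return ll + lp

    return logpost


def _sample_zoib(
    y: np.ndarray,
    group_idx: np.ndarray,
    Z: np.ndarray,
    plan: ChainPlan,
    seed: int,
    coef_names: Sequence[str],
    means_mode: bool = False,
) -> dict[str, np.ndarray]:
    """Run the Gibbs + adaptive-Metropolis sampler; return (chains, kept) draws.

    Warmup runs componentwise random-walk Metropolis with Robbins-Monro
    scale adaptation for its first half, then switches to joint proposals
    whose covariance is estimated from the warmup history (Haario-style
    adaptive Metropolis); the covariance is frozen at the end of warmup.
    """
    y = np.asarray(y, dtype=float)
    n0 = int(np.sum(y == 0))
    n1 = int(np.sum(y == 1))
    cont = (y > 0) & (y < 1)
    ncont = int(cont.sum())
    G = Z.shape[0]
    n_g = np.zeros(G)
    sly = np.zeros(G)
    sl1my = np.zeros(G)
    np.add.at(n_g, group_idx[cont], 1.0)
    np.add.at(sly, group_idx[cont], np.log(y[cont]))
    np.add.at(sl1my, group_idx[cont], np.log1p(-y[cont]))

    p = Z.shape[1]
    d = p + 2  # continuous-block dimension
    names = ["intercept", *coef_names, "log_phi"]
    assert len(names) == d
    logpost = _make_logpost(Z, n_g, sly, sl1my, means_mode)
    kept = plan.kept_per_chain
    store = {nm: np.empty((plan.chains, kept)) for nm in [*names[:-1], "phi", "p01", "cond_one"]}

    # crude but safe initialization around the empirical continuous mean
    if ncont:
        ybar = float(np.clip(y[cont].mean(), 0.01, 0.99))
    else:
        ybar = 0.5
    eta0 = np.log(ybar / (1 - ybar))
    phase1 = plan.warmup // 2
    seeds = np.random.SeedSequence(seed).spawn(plan.chains)
    for c in range(plan.chains):
        rng = np.random.default_rng(seeds[c])
        theta = np.empty(d)
        if means_mode:
            theta[:-1] = eta0 + rng.normal(0, 0.5, size=d - 1)
        else:
            theta[0] = eta0 + rng.normal(0, 0.5)
            theta[1:-1] = rng.normal(0, 0.5, size=p)
        theta[-1] = np.log(5.0) + rng.normal(0, 0.5)
        scales = np.full(d, 0.3)
        lp = logpost(theta)
        acc = np.zeros(d)
        tries = np.zeros(d)
        history = np.empty((plan.warmup - phase1, d))
        chol = None
        log_lambda = 0.0  # global scale of the joint kernel, adapted in warmup
        for it in range(plan.draws):
            # means_mode posteriors are near-independent across parameters:
            # componentwise kernels mix best there. Correlated coefficient
            # designs switch to a covariance-adapted joint kernel mid-warmup.
            if means_mode or it < phase1:
                # componentwise warmup with scale adaptation; a few sweeps
                # suffice here, the joint kernel does the post-warmup mixing
                n_sweeps = plan.sweeps if means_mode else min(plan.sweeps, 3)
                for _ in range(n_sweeps):
                    for j in range(d):
                        prop = theta.copy()
                        prop[j] += rng.normal(0, scales[j])
                        lp_prop = logpost(prop)
                        tries[j] += 1
                        if np.log(rng.random()) < lp_prop - lp:
                            theta, lp = prop, lp_prop
                            acc[j] += 1
                if it < plan.warmup and (it + 1) % 25 == 0:
                    rate = acc / np.maximum(tries, 1)
                    scales *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    scales = np.clip(scales, 1e-4, 10.0)
                    acc[:] = 0
                    tries[:] = 0
            else:
                if it == phase1 or (phase1 < it < plan.warmup and (it + 1) % 100 == 0):
                    sample = history[: it - phase1]
                    if len(sample) >= 50:
                        cov = np.cov(sample.T) + 1e-8 * np.eye(d)
                    else:
                        cov = np.diag(scales**2)
                    chol = np.linalg.cholesky((2.38**2 / d) * cov)
                for _ in range(plan.sweeps):
                    prop = theta + np.exp(log_lambda) * (chol @ rng.normal(size=d))
                    lp_prop = logpost(prop)
                    accepted = np.log(rng.random()) < lp_prop - lp
                    if accepted:
                        theta, lp = prop, lp_prop
                    if it < plan.warmup:
                        log_lambda += 0.05 * ((1.0 if accepted else 0.0) - 0.23)
                        log_lambda = float(np.clip(log_lambda, -5.0, 3.0))
            if phase1 <= it < plan.warmup:
                history[it - phase1] = theta
            if it >= plan.warmup:
                k = it - plan.warmup
                # conjugate point-mass block: exact posterior draws
                p01 = rng.beta(1 + n0 + n1, 1 + ncont)
                cond_one = rng.beta(1 + n1, 1 + n0)
                if means_mode:
                    store["intercept"][c, k] = theta[0]
                    for j, nm in enumerate(names[1:-1], start=1):
                        store[nm][c, k] = theta[j] - theta[0]
                else:
                    for nm, val in zip(names[:-1], theta[:-1]):
                        store[nm][c, k] = val
                store["phi"][c, k] = np.exp(theta[-1])
                store["p01"][c, k] = p01
                store["cond_one"][c, k] = cond_one
    return store


def _diagnose(draws: dict[str, np.ndarray]) -> dict[str, float]:
    return {name: split_rhat(d) for name, d in draws.items()}


def _check_convergence(
    rhat: dict[str, float], context: str, threshold: float = RHAT_THRESHOLD
) -> None:
    bad = {k: v for k, v in rhat.items() if v > threshold}
    if bad:
        raise ConvergenceError(
            f"{context}: split R-hat above {threshold} for "
            + ", ".join(f"{k}={v:.4f}" for k, v in bad.items())
        )


def fit_zoib(
    y: np.ndarray,
    categories: Sequence[str],
    plan: ChainPlan = SEVERITY_PLAN,
    seed: int = 0,
    rhat_threshold: float = RHAT_THRESHOLD,
) -> ZOIBPosterior:
    """Fit a ZOIB regression of a [0, 1] response on a categorical predictor.

    The core the severity models wrap: responses need not be discretized.
    Reference coding uses the first category in sorted order; coefficient
    names are ``b[<category>]``.
    """
    y = np.asarray(y, dtype=float)
    cats = [str(c) for c in categories]
    if len(cats) != len(y):
        raise ValidationError("categories must match response length")
    observed = sorted(set(cats))
    if len(observed) < 2:
        raise SingleCategoryError(f"only {len(observed)} observed category; cannot contrast")
    cat_index = {c: i for i, c in enumerate(observed)}
    group_idx = np.array([cat_index[c] for c in cats])
    G = len(observed)
    Z = np.zeros((G, G - 1))
    for i in range(1, G):
        Z[i, i - 1] = 1.0
    coef_names = [f"b[{c}]" for c in observed[1:]]
    draws = _sample_zoib(y, group_idx, Z, plan, seed, coef_names, means_mode=True)
    rhat = _diagnose(draws)
    _check_convergence(rhat, "ZOIB categorical model", rhat_threshold)
    return ZOIBPosterior(
        draws=draws, rhat=rhat, plan=plan, seed=seed, coef_names=tuple(coef_names)
    )


def fit_severity_model(
    records: Sequence[MortalityRecord],
    table: TraitTable,
    trait_code: str,
    plan: ChainPlan = SEVERITY_PLAN,
    seed: int = 0,
    rhat_threshold: float = RHAT_THRESHOLD,
) -> tuple[ZOIBPosterior, list[SeverityByCategory]]:
    """Fit the per-trait mortality-severity ZOIB regression.

    The response is percent mortality / 100 per record; the predictor is the
    record species' category for the given trait (reference coding, first
    observed category in vocabulary order as reference). Returns the
    posterior and the per-category posterior mean mortality on the percent
    scale: the mixture mean E[Y | category] = p01 * cond_one +
    (1 - p01) * mu_category, summarized with 95% credible intervals.
    """
    trait = table.schema[trait_code]
    records = list(records)
    if not records:
        raise ValidationError("no records to fit")
    cats = []
    for rec in records:
        if rec.species not in table:
            raise ValidationError(f"record species {rec.species!r} absent from trait table")
        sig = table.signature(rec.species)
        cats.append(sig[table.schema.codes.index(trait_code)])
    observed = [c for c in trait.categories if c in set(cats)]
    if len(observed) < 2:
        raise SingleCategoryError(
            f"trait {trait_code}: only {len(observed)} observed category; cannot contrast"
        )
    y = np.array([r.percent_mortality for r in records], dtype=float) / 100.0
    cat_index = {c: i for i, c in enumerate(observed)}
    group_idx = np.array([cat_index[c] for c in cats])
    G = len(observed)
    Z = np.zeros((G, G - 1))
    for i in range(1, G):
        Z[i, i - 1] = 1.0
    coef_names = [f"b[{trait_code}:{c}]" for c in observed[1:]]
    draws = _sample_zoib(y, group_idx, Z, plan, seed, coef_names, means_mode=True)
    rhat = _diagnose(draws)
    _check_convergence(rhat, f"severity model for trait {trait_code}", rhat_threshold)

    # per-category mixture-mean draws, percent scale
    flat_int = draws["intercept"].reshape(-1)
    flat_p01 = draws["p01"].reshape(-1)
    flat_cone = draws["cond_one"].reshape(-1)
    cat_means: dict[str, np.ndarray] = {}
    fitted = np.empty((flat_int.size, len(records)))
    for c in observed:
        eta = flat_int.copy()
        if cat_index[c] > 0:
            eta = eta + draws[coef_names[cat_index[c] - 1]].reshape(-1)
        mu = expit(eta)
        mean = flat_p01 * flat_cone + (1 - flat_p01) * mu
        cat_means[c] = mean * 100.0
    for i, c in enumerate(cats):
        fitted[:, i] = cat_means[c] / 100.0
    r2 = bayes_r2(fitted, y)
    post = ZOIBPosterior(
        draws=draws,
        rhat=rhat,
        plan=plan,
        seed=seed,
        coef_names=tuple(coef_names),
        r2={k: v for k, v in r2.items() if k != "draws"},
        category_mean_draws=cat_means,
    )
    rows = []
    for c in observed:
        d = cat_means[c]
        rows.append(
            SeverityByCategory(
                trait=trait_code,
                category=c,
                mean_percent=float(d.mean()),
                ci_low=float(np.quantile(d, 0.025)),
                ci_high=float(np.quantile(d, 0.975)),
            )
        )
    return post, rows


def fit_volume_model(
    fractions: np.ndarray,
    driver_fe_counts: pd.DataFrame,
    plan: ChainPlan = VOLUME_PLAN,
    seed: int = 0,
    rhat_threshold: float = RHAT_THRESHOLD,
) -> ZOIBPosterior:
    """Fit the impacted-volume ZOIB regression over years.

    ``fractions`` are annual impacted volume fractions in [0, 1];
    ``driver_fe_counts`` is a year x driver-class table of impacted-FE
    counts serving as numeric predictors (logit link on the beta mean).
    """
    y = np.asarray(fractions, dtype=float)
    if len(y) < 10:
        raise ValidationError(f"need >= 10 annual observations, got {len(y)}")
    if np.all(y == 0):
        raise ValidationError("all-zero response: volume model degenerate")
    X = driver_fe_counts.to_numpy(dtype=float)
    if X.shape[0] != len(y):
        raise ValidationError("predictor rows must match response length")
    # drop all-zero predictor columns (driver classes never observed)
    keep = np.ptp(X, axis=0) > 0
    X = X[:, keep]
    coef_names = [f"b[{c}]" for c, k in zip(driver_fe_counts.columns, keep) if k]
    group_idx = np.arange(len(y))
    # center predictors for sampling health; intercept draws mapped back below
    colmeans = X.mean(axis=0)
    draws = _sample_zoib(y, group_idx, X - colmeans, plan, seed, coef_names)
    if coef_names:
        B_all = np.stack([draws[nm] for nm in coef_names], axis=-1)
        draws["intercept"] = draws["intercept"] - B_all @ colmeans
    rhat = _diagnose(draws)
    _check_convergence(rhat, "volume model", rhat_threshold)
    flat_int = draws["intercept"].reshape(-1)
    flat_p01 = draws["p01"].reshape(-1)
    flat_cone = draws["cond_one"].reshape(-1)
    B = np.column_stack([draws[nm].reshape(-1) for nm in coef_names]) if coef_names else None
    eta = flat_int[:, None] + (B @ X.T if B is not None else 0.0)
    mu = expit(eta)
    fitted = flat_p01[:, None] * flat_cone[:, None] + (1 - flat_p01[:, None]) * mu
    r2 = bayes_r2(fitted, y)
    return ZOIBPosterior(
        draws=draws,
        rhat=rhat,
        plan=plan,
        seed=seed,
        coef_names=tuple(coef_names),
        r2={k: v for k, v in r2.items() if k != "draws"},
    )
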
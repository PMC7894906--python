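"""Fully Bayesian hierarchical model with subject-specific variances.

Model: ``y_ij | mu_i, sigma_i^2 ~ N(mu_i, sigma_i^2)``,
``mu_i ~ N(mu, tau^2)``, ``mu ~ N(0, nu^2)``, and inverse-gamma priors on
``sigma_i^2`` and ``tau^2``.  All four full conditionals are conjugate, so
the model is fitted by a Gibbs sampler that only touches per-subject
sufficient statistics; dynamic reference ranges come from empirical
quantiles of the posterior predictive sample of the next observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import Hyperparameters, ObservationTable, ReferenceBand
from .errors import DataError, NumericalError
from .static_range import tolerance_interval
from .zscore import pooled_within_subject_variance

__all__ = [
    "GibbsConfig",
    "GibbsState",
    "PosteriorDraws",
    "sample_mu",
    "sample_tau2",
    "sample_sigma2_i",
    "sample_mu_i",
    "gibbs_fit",
    "posterior_predictive",
    "predictive_score_bayes",
    "dynamic_band_bayes",
]


@dataclass(frozen=True)
class GibbsConfig:
    n_iter: int = 4000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise DataError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise DataError("thin must be >= 1")


@dataclass
class GibbsState:
    """Current parameter values plus the fixed per-subject suff stats."""

    mu: float
    tau2: float
    mu_i: np.ndarray
    sigma2_i: np.ndarray
    n: np.ndarray  # n_i
    s1: np.ndarray  # sum_j y_ij
    s2: np.ndarray  # sum_j y_ij^2
    subject_ids: list[str]

    @property
    def I(self) -> int:
        return len(self.subject_ids)

    def position(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise DataError(f"unknown subject {subject_id!r}") from None


@dataclass
class PosteriorDraws:
    """Retained post-burn-in Gibbs draws (one row per draw)."""

    mu: np.ndarray
    tau2: np.ndarray
    mu_i: np.ndarray  # (draws, subjects)
    sigma2_i: np.ndarray  # (draws, subjects)
    subject_ids: list[str]

    @property
    def n_draws(self) -> int:
        return self.mu.size

    def position(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise DataError(f"unknown subject {subject_id!r}") from None


# -- full-conditional parameterisations (shared by unit ops and the loop) ----


def _mu_conditional(mu_i: np.ndarray, tau2: float, nu: float) -> tuple[float, float]:
    prec = 1.0 / nu**2 + mu_i.size / tau2
    mean = (mu_i.sum() / tau2) / prec
    return mean, 1.0 / prec


def _tau2_conditional(mu: float, mu_i: np.ndarray, hyper: Hyperparameters) -> tuple[float, float]:
    shape = hyper.alpha2 + mu_i.size / 2.0
    scale = hyper.beta2 + 0.5 * float(np.sum((mu_i - mu) ** 2))
    return shape, scale


def _sigma2_conditionals(state: GibbsState, hyper: Hyperparameters) -> tuple[np.ndarray, np.ndarray]:
    shape = hyper.alpha1 + state.n / 2.0
    ss = state.s2 - 2.0 * state.mu_i * state.s1 + state.n * state.mu_i**2
    scale = hyper.beta1 + 0.5 * np.maximum(ss, 0.0)
    return shape, scale


def _mu_i_conditionals(state: GibbsState) -> tuple[np.ndarray, np.ndarray]:
    prec = 1.0 / state.tau2 + state.n / state.sigma2_i
    mean = (state.mu / state.tau2 + state.s1 / state.sigma2_i) / prec
    return mean, 1.0 / prec


def _invgamma_draw(shape, scale, rng: np.random.Generator):
    return scale / rng.standard_gamma(shape)


def sample_mu(state: GibbsState, hyper: Hyperparameters, rng: np.random.Generator) -> float:
    """Draw the grand mean from its normal full conditional."""
    mean, var = _mu_conditional(state.mu_i, state.tau2, hyper.nu)
    return float(mean + np.sqrt(var) * rng.standard_normal())


def sample_tau2(state: GibbsState, hyper: Hyperparameters, rng: np.random.Generator) -> float:
    """Draw the between-subject variance from its inverse-gamma conditional."""
    shape, scale = _tau2_conditional(state.mu, state.mu_i, hyper)
    return float(_invgamma_draw(shape, scale, rng))


def sample_sigma2_i(
    state: GibbsState, hyper: Hyperparameters, subject_id: str, rng: np.random.Generator
) -> float:
    """Draw one subject's within-subject variance (inverse-gamma conditional)."""
    k = state.position(subject_id)
    shape, scale = _sigma2_conditionals(state, hyper)
    return float(_invgamma_draw(shape[k], scale[k], rng))


def sample_mu_i(
    state: GibbsState, hyper: Hyperparameters, subject_id: str, rng: np.random.Generator
) -> float:
    """Draw one subject's mean from its normal full conditional."""
    k = state.position(subject_id)
    mean, var = _mu_i_conditionals(state)
    return float(mean[k] + np.sqrt(var[k]) * rng.standard_normal())


def _initial_state(table: ObservationTable) -> GibbsState:
    n, s1, s2 = table.suffstats()
    keep = n > 0
    if not np.all(keep):
        raise DataError("subjects with zero observations are not allowed in gibbs_fit")
    ybar = s1 / n
    mu0 = float(table.value.mean())
    tau20 = float(np.var(ybar, ddof=1)) if n.size > 1 else 1.0
    if tau20 <= 0.0:
        tau20 = 1e-6
    with np.errstate(invalid="ignore"):
        sv = (s2 - s1**2 / n) / np.maximum(n - 1, 1)
    try:
        pooled = pooled_within_subject_variance(table)
    except (DataError, NumericalError):
        pooled = max(tau20, 1e-6)
    sigma20 = np.where((n >= 2) & (sv > 0), sv, pooled)
    return GibbsState(
        mu=mu0,
        tau2=tau20,
        mu_i=ybar.astype(float).copy(),
        sigma2_i=sigma20.astype(float),
        n=n.astype(float),
        s1=s1,
        s2=s2,
        subject_ids=list(table.subject_ids),
    )


def gibbs_fit(table: ObservationTable, config: GibbsConfig | None = None) -> PosteriorDraws:
    """Fit the hierarchical model by Gibbs sampling.

    Each iteration cycles mu -> tau^2 -> {sigma_i^2} -> {mu_i}; draws after
    burn-in are retained every ``thin`` iterations.  Deterministic under a
    fixed ``config.seed``.
    """
    if config is None:
        config = GibbsConfig()
    if table.n_records == 0:
        raise DataError("no data")
    hyper = config.hyper
    rng = np.random.default_rng(config.seed)
    state = _initial_state(table)
    I = state.I

    kept = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    mu_out = np.empty(kept)
    tau2_out = np.empty(kept)
    mu_i_out = np.empty((kept, I))
    sigma2_i_out = np.empty((kept, I))

    nu = hyper.nu
    k_out = 0
    for it in range(config.n_iter):
        mean, var = _mu_conditional(state.mu_i, state.tau2, nu)
        state.mu = mean + np.sqrt(var) * rng.standard_normal()

        shape, scale = _tau2_conditional(state.mu, state.mu_i, hyper)
        state.tau2 = _invgamma_draw(shape, scale, rng)

        shape_s, scale_s = _sigma2_conditionals(state, hyper)
        state.sigma2_i = scale_s / rng.standard_gamma(shape_s)

        mean_i, var_i = _mu_i_conditionals(state)
        state.mu_i = mean_i + np.sqrt(var_i) * rng.standard_normal(I)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            mu_out[k_out] = state.mu
            tau2_out[k_out] = state.tau2
            mu_i_out[k_out] = state.mu_i
            sigma2_i_out[k_out] = state.sigma2_i
            k_out += 1

    return PosteriorDraws(
        mu=mu_out[:k_out],
        tau2=tau2_out[:k_out],
        mu_i=mu_i_out[:k_out],
        sigma2_i=sigma2_i_out[:k_out],
        subject_ids=list(table.subject_ids),
    )


def posterior_predictive(
    draws: PosteriorDraws, subject_id: str, rng: np.random.Generator
) -> np.ndarray:
    """One posterior-predictive sample of the next observation per draw."""
    k = draws.position(subject_id)
    if draws.n_draws < 1:
        raise NumericalError("no posterior draws")
    mu_i = draws.mu_i[:, k]
    sd_i = np.sqrt(draws.sigma2_i[:, k])
    return mu_i + sd_i * rng.standard_normal(draws.n_draws)


def predictive_score_bayes(predictive_samples: Sequence[float], observed: float) -> float:
    """Two-sided empirical tail probability of ``observed``.

    ``2 * min(F(y), 1 - F(y))`` with ``F`` the mid-rank empirical CDF of
    the predictive sample; small values flag atypical observations.
    """
    s = np.asarray(predictive_samples, dtype=float)
    if s.size == 0:
        raise NumericalError("empty predictive sample")
    below = np.count_nonzero(s < observed)
    ties = np.count_nonzero(s == observed)
    f = (below + 0.5 * ties) / s.size
    return float(2.0 * min(f, 1.0 - f))


def predictive_scores_all_subjects(
    draws: PosteriorDraws,
    observed: np.ndarray,
    rng: np.random.Generator | None = None,
    smooth: bool = True,
) -> np.ndarray:
    """Two-sided posterior-predictive tail probability per subject.

    With ``smooth=True`` (default) the predictive CDF is the
    Rao-Blackwellised mixture ``F(y) = mean_t Phi((y - mu_i_t) / sd_i_t)``,
    which is deterministic given the draws and has lower Monte-Carlo noise
    than ranking ``y`` within a sampled predictive draw (``smooth=False``,
    which requires ``rng``).
    """
    from scipy.special import ndtr

    mu_i = draws.mu_i
    if smooth:
        f = ndtr((observed[None, :] - mu_i) / np.sqrt(draws.sigma2_i)).mean(axis=0)
        return 2.0 * np.minimum(f, 1.0 - f)
    if rng is None:
        raise DataError("rng is required for sample-based predictive scores")
    y_star = mu_i + np.sqrt(draws.sigma2_i) * rng.standard_normal(mu_i.shape)
    below = np.count_nonzero(y_star < observed[None, :], axis=0)
    ties = np.count_nonzero(y_star == observed[None, :], axis=0)
    f = (below + 0.5 * ties) / y_star.shape[0]
    return 2.0 * np.minimum(f, 1.0 - f)


def dynamic_band_bayes(
    table: ObservationTable,
    subject_id: str,
    config: GibbsConfig | None = None,
    refit_each_step: bool = True,
) -> ReferenceBand:
    """Adaptive Bayesian reference band for one subject.

    The first two indices fall back to the static tolerance interval built
    from the other subjects (within-subject variance needs two points);
    from the third index on, the band is the central ``1 - alpha`` interval
    of the posterior predictive fitted on the subject's first ``j - 1``
    observations plus all other subjects' data.

    With ``refit_each_step=False`` a single model is fitted once on the
    subject's first ``n_i - 1`` observations plus the other subjects'
    data, and every band from index 3 onward reuses that fit (fast;
    appropriate when only the final observation is of interest).
    """
    if config is None:
        config = GibbsConfig()
    if table.n_subjects < 2:
        raise DataError("need at least 2 subjects")
    alpha = config.hyper.alpha_level
    values = table.values_for(subject_id)
    n_i = values.size
    pool = table.without_subject(subject_id).value
    ti = tolerance_interval(pool, p=1.0 - alpha, confidence=0.95)

    band = ReferenceBand(alpha_level=alpha)
    for j in range(1, min(2, n_i) + 1):
        band.append(subject_id, j, ti.lower, ti.upper, values[j - 1], "bayes")
    if n_i <= 2:
        return band

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x9E3779B9)))
    if refit_each_step:
        for j in range(3, n_i + 1):
            sub = table.with_prefix(subject_id, j - 1)
            draws = gibbs_fit(sub, config)
            pred = posterior_predictive(draws, subject_id, rng)
            lo, hi = np.quantile(pred, [alpha / 2.0, 1.0 - alpha / 2.0])
            band.append(subject_id, j, float(lo), float(hi), values[j - 1], "bayes")
    else:
        sub = table.with_prefix(subject_id, n_i - 1)
        draws = gibbs_fit(sub, config)
        pred = posterior_predictive(draws, subject_id, rng)
        lo, hi = np.quantile(pred, [alpha / 2.0, 1.0 - alpha / 2.0])
        for j in range(3, n_i + 1):
            band.append(subject_id, j, float(lo), float(hi), values[j - 1], "bayes")
    return band
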
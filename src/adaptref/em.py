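"""Heterogeneous-variance random-intercept model fitted by EM, with a
streaming per-observation approximation and plug-in dynamic ranges.

The model is the same hierarchy as the Bayesian module but the
hyperparameters are point-estimated by maximum likelihood, treating the
subject means as latent.  The whole algorithm runs on three per-subject
summaries ``(n_i, ybar_i, y2bar_i)`` and three complete-data sufficient
statistics, so the streaming variant never stores raw data: each arriving
observation replaces only the touched subject's contribution to the
sufficient statistics before re-running the M step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import ObservationTable, ReferenceBand
from .errors import DataError, NumericalError
from .static_range import tolerance_interval

__all__ = [
    "EMState",
    "e_step",
    "m_step",
    "em_fit",
    "marginal_loglik",
    "sema_update",
    "fit_stream",
    "predictive_normal",
    "dynamic_band_em",
    "predictive_score_em",
    "dynamic_band_em_table",
]

VARIANCE_FLOOR = 1e-10


@dataclass
class EMState:
    """Parameter estimates, per-subject posteriors, CDSS and summaries.

    Memory footprint is O(I): only per-subject counts, means and mean
    squares are retained, never the raw observations.
    """

    subject_ids: list[str]
    mu_hat: float
    tau2_hat: float
    sigma2_hat: np.ndarray
    mu_i_hat: np.ndarray
    nu_i_hat: np.ndarray
    rho_i_hat: np.ndarray
    T1: float
    T2: float
    T3: np.ndarray
    n_i: np.ndarray
    ybar_i: np.ndarray
    y2bar_i: np.ndarray
    iteration: int = 0
    converged: bool = True
    loglik_path: list[float] = field(default_factory=list)
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {s: k for k, s in enumerate(self.subject_ids)}

    @property
    def I(self) -> int:
        return len(self.subject_ids)

    def position(self, subject_id: str) -> int:
        try:
            return self._pos[subject_id]
        except KeyError:
            raise DataError(f"unknown subject {subject_id!r}") from None

    def sigma2_for(self, subject_id: str) -> float:
        return float(self.sigma2_hat[self.position(subject_id)])

    def copy(self) -> "EMState":
        return EMState(
            subject_ids=list(self.subject_ids),
            mu_hat=self.mu_hat,
            tau2_hat=self.tau2_hat,
            sigma2_hat=self.sigma2_hat.copy(),
            mu_i_hat=self.mu_i_hat.copy(),
            nu_i_hat=self.nu_i_hat.copy(),
            rho_i_hat=self.rho_i_hat.copy(),
            T1=self.T1,
            T2=self.T2,
            T3=self.T3.copy(),
            n_i=self.n_i.copy(),
            ybar_i=self.ybar_i.copy(),
            y2bar_i=self.y2bar_i.copy(),
            iteration=self.iteration,
            converged=self.converged,
            loglik_path=list(self.loglik_path),
        )


def _init_from_summaries(
    subject_ids: list[str], n: np.ndarray, ybar: np.ndarray, y2bar: np.ndarray
) -> EMState:
    """Method-of-moments starting point."""
    mu0 = float(np.sum(n * ybar) / np.sum(n))
    tau20 = float(np.var(ybar, ddof=1)) if len(subject_ids) > 1 else 1.0
    tau20 = max(tau20, 1e-6)
    with np.errstate(invalid="ignore"):
        sv = np.where(n >= 2, n * (y2bar - ybar**2) / np.maximum(n - 1, 1), np.nan)
    usable = np.isfinite(sv) & (sv > 0)
    pooled = float(np.sum(((n - 1) * sv)[usable]) / np.sum((n - 1)[usable])) if np.any(usable) else tau20
    sigma20 = np.where(usable, sv, pooled).astype(float)
    I = len(subject_ids)
    state = EMState(
        subject_ids=list(subject_ids),
        mu_hat=mu0,
        tau2_hat=tau20,
        sigma2_hat=sigma20,
        mu_i_hat=ybar.astype(float).copy(),
        nu_i_hat=np.zeros(I),
        rho_i_hat=np.full(I, 0.5),
        T1=0.0,
        T2=0.0,
        T3=np.zeros(I),
        n_i=n.astype(float).copy(),
        ybar_i=ybar.astype(float).copy(),
        y2bar_i=y2bar.astype(float).copy(),
    )
    return state


def init_state(table: ObservationTable) -> EMState:
    n, s1, s2 = table.suffstats()
    if np.any(n == 0):
        raise DataError("subjects with zero observations are not allowed")
    return _init_from_summaries(list(table.subject_ids), n, s1 / n, s2 / n)


def e_step(state: EMState, table: ObservationTable | None = None) -> EMState:
    """Shrinkage update of every subject's posterior and the CDSS.

    ``rho_i = tau2 / (tau2 + sigma_i2 / n_i)``; the subject posterior mean
    is the rho-weighted blend of the subject mean and the grand mean and
    its variance is ``tau2 * (1 - rho_i)``.  The ``table`` argument is
    accepted for interface symmetry but unused: the per-subject summaries
    stored on the state are sufficient.
    """
    n = state.n_i
    rho = state.tau2_hat / (state.tau2_hat + state.sigma2_hat / np.maximum(n, 1))
    rho = np.where(n > 0, rho, 0.0)
    mu_i = rho * state.ybar_i + (1.0 - rho) * state.mu_hat
    nu_i = state.tau2_hat * (1.0 - rho)
    state.rho_i_hat = rho
    state.mu_i_hat = mu_i
    state.nu_i_hat = nu_i
    state.T1 = float(np.sum(mu_i))
    state.T2 = float(np.sum(nu_i + mu_i**2))
    state.T3 = n * (state.y2bar_i - 2.0 * mu_i * state.ybar_i + mu_i**2 + nu_i)
    return state


def m_step(state: EMState) -> EMState:
    """Re-estimate (mu, tau2, {sigma_i2}) from the CDSS.

    Subjects with fewer than two observations take the pooled
    within-subject variance instead of their own (undersized) estimate.
    """
    I = state.I
    state.mu_hat = state.T1 / I
    tau2 = state.T2 / I - state.mu_hat**2
    if tau2 <= 0.0:
        warnings.warn("tau2 estimate fell to or below zero; flooring", RuntimeWarning)
        tau2 = VARIANCE_FLOOR
    state.tau2_hat = float(tau2)

    n = state.n_i
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = state.T3 / n
    small = n < 2
    if np.any(small):
        big = ~small
        if np.any(big):
            pooled = float(np.sum(state.T3[big]) / np.sum(n[big]))
        else:
            pooled = float(np.nanmean(np.where(small, state.sigma2_hat, np.nan)))
        sigma2 = np.where(small, pooled, sigma2)
    if np.any(sigma2 <= 0.0):
        warnings.warn("sigma2 estimate fell to or below zero; flooring", RuntimeWarning)
        sigma2 = np.maximum(sigma2, VARIANCE_FLOOR)
    state.sigma2_hat = sigma2.astype(float)
    return state


def marginal_loglik(
    mu: float,
    tau2: float,
    sigma2: np.ndarray,
    n: np.ndarray,
    ybar: np.ndarray,
    y2bar: np.ndarray,
) -> float:
    """Observed-data log-likelihood of the random-intercept model.

    Per subject the marginal covariance is ``sigma_i2 * Id + tau2 * J``;
    determinant and quadratic form reduce to closed forms in the summary
    statistics.
    """
    n = np.asarray(n, dtype=float)
    S = n * (y2bar - 2.0 * mu * ybar + mu**2)
    denom = sigma2 + n * tau2
    logdet = (n - 1.0) * np.log(sigma2) + np.log(denom)
    quad = (S - tau2 * (n * (ybar - mu)) ** 2 / denom) / sigma2
    return float(-0.5 * np.sum(logdet + quad + n * math.log(2.0 * math.pi)))


def _state_loglik(state: EMState) -> float:
    return marginal_loglik(
        state.mu_hat, state.tau2_hat, state.sigma2_hat, state.n_i, state.ybar_i, state.y2bar_i
    )


def em_fit(
    table: ObservationTable,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: EMState | None = None,
) -> EMState:
    """Batch EM until the relative log-likelihood change drops below ``tol``.

    The observed-data log-likelihood is non-decreasing across iterations;
    its trace is kept on ``state.loglik_path``.  A state that exhausts
    ``max_iter`` is returned with ``converged=False``.
    """
    if table.n_subjects < 2:
        raise DataError("need at least 2 subjects for em_fit")
    if not tol > 0:
        raise DataError("tol must be positive")
    state = init.copy() if init is not None else init_state(table)
    ll_prev = -np.inf
    state.converged = False
    for it in range(1, max_iter + 1):
        e_step(state)
        m_step(state)
        state.iteration = it
        ll = _state_loglik(state)
        state.loglik_path.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
            state.converged = True
            break
        ll_prev = ll
    else:
        warnings.warn(f"EM did not converge within {max_iter} iterations", RuntimeWarning)
    # posteriors consistent with the final parameter estimates
    e_step(state)
    return state


def _subject_contribution(state: EMState, k: int) -> tuple[float, float, float]:
    """This subject's (T1, T2, T3) contribution at current estimates."""
    n = state.n_i[k]
    rho = state.tau2_hat / (state.tau2_hat + state.sigma2_hat[k] / max(n, 1.0)) if n > 0 else 0.0
    mu_i = rho * state.ybar_i[k] + (1.0 - rho) * state.mu_hat
    nu_i = state.tau2_hat * (1.0 - rho)
    t3 = n * (state.y2bar_i[k] - 2.0 * mu_i * state.ybar_i[k] + mu_i**2 + nu_i)
    state.rho_i_hat[k] = rho
    state.mu_i_hat[k] = mu_i
    state.nu_i_hat[k] = nu_i
    return mu_i, nu_i + mu_i**2, t3


def _append_subject(state: EMState, subject_id: str) -> int:
    k = state.I
    # mu_i/nu_i double as the subject's *current contribution* to T1/T2;
    # a never-seen subject has contributed nothing yet, so they start at 0
    fills = {"sigma2_hat": _pooled_sigma2(state)}
    state.subject_ids.append(subject_id)
    state._pos[subject_id] = k
    for name in ("sigma2_hat", "mu_i_hat", "nu_i_hat", "rho_i_hat", "T3", "n_i", "ybar_i", "y2bar_i"):
        arr = getattr(state, name)
        setattr(state, name, np.append(arr, fills.get(name, 0.0)))
    return k


def _pooled_sigma2(state: EMState) -> float:
    big = state.n_i >= 2
    if np.any(big):
        return float(np.sum(state.T3[big]) / np.sum(state.n_i[big]))
    return float(np.mean(state.sigma2_hat)) if state.sigma2_hat.size else state.tau2_hat


def sema_update(state: EMState, subject_id: str, new_value: float) -> EMState:
    """Streaming EM step for one arriving observation.

    Updates the touched subject's running summaries, replaces its
    contribution in the sufficient statistics (every other subject's
    contribution is untouched), and re-runs the M step.  O(1) per
    observation apart from the rare pooled-variance recomputation.
    """
    if not math.isfinite(new_value):
        raise DataError("invalid value: non-finite observation")
    k = state._pos.get(subject_id)
    if k is None:
        k = _append_subject(state, subject_id)
    # ensure T contributions exist (state fresh from init has empty CDSS)
    if state.T1 == 0.0 and state.T2 == 0.0 and not np.any(state.T3):
        e_step(state)

    old_t1 = state.mu_i_hat[k]
    old_t2 = state.nu_i_hat[k] + state.mu_i_hat[k] ** 2
    old_t3 = state.T3[k]

    n_new = state.n_i[k] + 1.0
    state.ybar_i[k] += (new_value - state.ybar_i[k]) / n_new
    state.y2bar_i[k] += (new_value**2 - state.y2bar_i[k]) / n_new
    state.n_i[k] = n_new

    new_t1, new_t2, new_t3 = _subject_contribution(state, k)
    state.T1 += new_t1 - old_t1
    state.T2 += new_t2 - old_t2
    state.T3[k] = new_t3

    I = state.I
    state.mu_hat = state.T1 / I
    tau2 = state.T2 / I - state.mu_hat**2
    state.tau2_hat = max(tau2, VARIANCE_FLOOR)
    if n_new >= 2:
        state.sigma2_hat[k] = max(new_t3 / n_new, VARIANCE_FLOOR)
    else:
        state.sigma2_hat[k] = _pooled_sigma2(state)
    state.iteration += 1
    return state


def fit_stream(
    table: ObservationTable,
    batch_size: int | None = None,
    order: str = "rows",
) -> EMState:
    """Fit by batch EM on an initial block, then stream the remainder.

    ``batch_size`` defaults to ``20 * I`` (or the whole table if smaller) —
    batch EM stabilises the hyperparameters before per-observation updates
    take over.  ``order`` is "rows" (table order) or "index" (all first
    observations, then all second, ...).
    """
    if order not in ("rows", "index"):
        raise DataError(f"unknown stream order {order!r}")
    total = table.n_records
    if batch_size is None:
        batch_size = min(total, 20 * table.n_subjects)
    batch_size = min(batch_size, total)

    if order == "rows":
        perm = np.arange(total)
    else:
        perm = np.lexsort((table.subject_pos, table.index))

    head = perm[:batch_size]
    records = [
        (table.subject_ids[table.subject_pos[r]], int(table.index[r]), float(table.value[r]))
        for r in head
    ]
    from .data_model import validate_table

    head_table = validate_table(records)
    if head_table.n_subjects >= 2:
        state = em_fit(head_table, tol=1e-10, max_iter=1000)
    else:
        state = init_state(head_table)
        e_step(state)
        m_step(state)

    for r in perm[batch_size:]:
        sema_update(state, table.subject_ids[table.subject_pos[r]], float(table.value[r]))
    return state


# -- plug-in predictive ------------------------------------------------------


def predictive_normal(
    state_or_params,
    subject_id: str,
    j: int,
    history_mean: float | None = None,
) -> tuple[float, float]:
    """Mean and SD of the plug-in predictive for index ``j`` of a subject.

    Centre ``(mu/tau2 + (j-1) ybar / sigma_i2) / (1/tau2 + (j-1)/sigma_i2)``
    and variance ``1 / (1/tau2 + (j-1)/sigma_i2) + sigma_i2``; at ``j = 1``
    this is ``N(mu, tau2 + sigma_i2)``.
    """
    state = state_or_params
    if j < 1:
        raise DataError("observation index j must be >= 1")
    k = state.position(subject_id)
    if j - 1 > state.n_i[k]:
        raise DataError(
            f"history mismatch: j-1 = {j - 1} exceeds recorded n_i = {int(state.n_i[k])}"
        )
    ybar = state.ybar_i[k] if history_mean is None else float(history_mean)
    mu, tau2, sigma2 = state.mu_hat, state.tau2_hat, float(state.sigma2_hat[k])
    m = j - 1.0
    prec = 1.0 / tau2 + m / sigma2
    centre = (mu / tau2 + m * ybar / sigma2) / prec
    var = 1.0 / prec + sigma2
    return float(centre), float(math.sqrt(var))


def dynamic_band_em(
    state: EMState, subject_id: str, j: int, alpha: float = 0.05, history_mean: float | None = None
) -> tuple[float, float]:
    """Plug-in dynamic range: centre +/- z_{1-alpha/2} * predictive SD."""
    centre, sd = predictive_normal(state, subject_id, j, history_mean)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return centre - z * sd, centre + z * sd


def predictive_score_em(
    state: EMState, subject_id: str, j: int, observed: float, history_mean: float | None = None
) -> float:
    """Two-sided tail probability of ``observed`` under the plug-in normal."""
    centre, sd = predictive_normal(state, subject_id, j, history_mean)
    return float(2.0 * stats.norm.sf(abs(observed - centre) / sd))


def dynamic_band_em_table(
    table: ObservationTable,
    subject_id: str,
    alpha: float = 0.05,
    refit_each_step: bool = True,
) -> ReferenceBand:
    """Adaptive EM reference band over a subject's full trajectory.

    Mirrors the Bayesian band: indices 1-2 use the static tolerance
    interval from the other subjects; later indices use the plug-in
    predictive fitted on the subject's first ``j - 1`` observations plus
    all other subjects' data.
    """
    if table.n_subjects < 2:
        raise DataError("need at least 2 subjects")
    values = table.values_for(subject_id)
    n_i = values.size
    pool = table.without_subject(subject_id).value
    ti = tolerance_interval(pool, p=1.0 - alpha, confidence=0.95)

    band = ReferenceBand(alpha_level=alpha)
    for j in range(1, min(2, n_i) + 1):
        band.append(subject_id, j, ti.lower, ti.upper, values[j - 1], "em")
    if n_i <= 2:
        return band

    state = None if refit_each_step else em_fit(table.with_prefix(subject_id, n_i - 1))
    for j in range(3, n_i + 1):
        if refit_each_step:
            state = em_fit(table.with_prefix(subject_id, j - 1))
        hist_mean = float(values[: j - 1].mean())
        lo, hi = dynamic_band_em(state, subject_id, j, alpha, history_mean=hist_mean)
        band.append(subject_id, j, lo, hi, values[j - 1], "em")
    return band
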
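"""Joint maximum-likelihood fit of age-specific incidence and a
prevalent-as-incident misclassification fraction.

The observation model, per stratum (sex x age band) of one network/disease:

* model prevalence p_mod comes from the illness-death projection of the
  candidate incidence curve against fixed mortality/institutionalization
  schedules;
* ``prev_count ~ Binomial(n_registered, (1 - kappa) * p_mod)`` — a fraction
  kappa of truly prevalent cases is recorded as incident instead;
* ``inc_count ~ Poisson(PY_free * i + kappa * n_registered * p_mod)`` with
  ``PY_free = person_years * (1 - p_mod)``.

Incidence is log-linear in a polynomial of age (centred at 50, scaled by
50); kappa is constant over age within each sex.  Counts are treated as
independent across strata and between measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, xlogy

from .ipm import CohortState, DiseaseSchedules, project_cohort
from .rates import RateSchedule, StandardizedRate
from .registry_io import AGE_CAP, AgeBand, RegistryTable, StandardPopulation

logger = logging.getLogger(__name__)

I_MIN = 1e-10
I_MAX = 0.5
_AGES = np.arange(AGE_CAP, dtype=float)
_X_GRID = (_AGES - 50.0) / 50.0


@dataclass(frozen=True)
class IncidenceParam:
    """Polynomial coefficients for log i(a) in powers of (a - 50)/50."""

    coefficients: np.ndarray
    sex: str = "f"

    def __post_init__(self):
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class MisclassParam:
    kappa: float

    def __post_init__(self):
        if not (0.0 <= self.kappa < 1.0):
            raise ValueError(f"kappa must lie in [0, 1), got {self.kappa}")


def incidence_curve(coefficients, ages=None) -> np.ndarray:
    """Evaluate i(a) = exp(polynomial((a-50)/50)), clipped to [1e-10, 0.5]."""
    c = np.asarray(coefficients, dtype=float)
    a = _AGES if ages is None else np.asarray(ages, dtype=float)
    x = (a - 50.0) / 50.0
    log_i = sum(c[j] * x**j for j in range(len(c)))
    return np.clip(np.exp(log_i), I_MIN, I_MAX)


def incidence_from_params(p: IncidenceParam, ages=None) -> np.ndarray:
    return incidence_curve(p.coefficients, ages)


@dataclass(frozen=True)
class SexFit:
    """Per-sex block of a fit: parameters, covariance and diagnostics.

    ``theta`` is the internal parameter vector (coefficients, then logit
    kappa unless the estimate is pinned to the boundary kappa = 0, in which
    case theta holds the coefficients only)."""

    incidence: IncidenceParam
    misclass: MisclassParam
    theta: np.ndarray
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    kappa_on_boundary: bool


@dataclass(frozen=True)
class FitResult:
    by_sex: Mapping[str, SexFit]
    loglik: float
    converged: bool

    def kappa(self, sex: str) -> float:
        return self.by_sex[sex].misclass.kappa


@dataclass(frozen=True)
class ParamDraws:
    """Multivariate-normal parameter draws around a fit, one block per sex."""

    by_sex: Mapping[str, np.ndarray]
    boundary: Mapping[str, bool]
    seed: int

    @property
    def n(self) -> int:
        return next(iter(self.by_sex.values())).shape[0]


@dataclass(frozen=True)
class FitConfig:
    degree: int = 3
    kappa_start: float = 0.05
    max_iter: int = 500
    loglik_tol: float = 1e-8
    boundary_tol: float = 1e-4
    hessian_rel_step: float = 1e-4

    def __post_init__(self):
        if not (1 <= self.degree <= 4):
            raise ValueError("degree must be between 1 and 4")


# ---------------------------------------------------------------------------
# expected counts and likelihood


@dataclass(frozen=True)
class _SexData:
    bands: tuple[AgeBand, ...]
    person_years: np.ndarray
    n_registered: np.ndarray
    prev: np.ndarray
    inc: np.ndarray


def _sex_data(table: RegistryTable, sex: str) -> _SexData:
    keys = sorted((k for k in table.rows if k.sex == sex), key=lambda k: k.age_band)
    return _SexData(
        bands=tuple(k.age_band for k in keys),
        person_years=np.array([table.rows[k].person_years for k in keys], dtype=float),
        n_registered=np.array([table.rows[k].n_registered for k in keys], dtype=float),
        prev=np.array([table.rows[k].prev_count for k in keys], dtype=float),
        inc=np.array([table.rows[k].inc_count for k in keys], dtype=float),
    )


def _band_means(i_vec: np.ndarray, state: CohortState, bands: Sequence[AgeBand]):
    """Occupancy-weighted band prevalence and susceptible-weighted band
    incidence from a projected cohort."""
    p_band = np.empty(len(bands))
    i_band = np.empty(len(bands))
    for j, band in enumerate(bands):
        sl = slice(band.lower, band.upper)
        alive = state.S[sl] + state.C[sl]
        tot = alive.sum()
        p_band[j] = state.C[sl].sum() / tot if tot > 0 else np.nan
        s_tot = state.S[sl].sum()
        i_band[j] = (state.S[sl] * i_vec[sl]).sum() / s_tot if s_tot > 0 else i_vec[sl].mean()
    return p_band, i_band


def _safe_incidence(i_vec: np.ndarray, fixed: DiseaseSchedules) -> np.ndarray:
    # keep i + m <= 1 so the projection invariants hold at extreme curves
    return np.minimum(i_vec, 1.0 - fixed.m)


def _expected_for_sex(coefficients: np.ndarray, kappa: float,
                      fixed: DiseaseSchedules, data: _SexData):
    """Per-band (E_inc, E_prev, q_prev) for one sex."""
    i_vec = _safe_incidence(incidence_curve(coefficients), fixed)
    state = project_cohort(fixed.with_incidence(i_vec))
    p_band, i_band = _band_means(i_vec, state, data.bands)
    q = (1.0 - kappa) * p_band
    e_prev = data.n_registered * q
    py_free = data.person_years * (1.0 - p_band)
    e_inc = py_free * i_band + kappa * data.n_registered * p_band
    return e_inc, e_prev, q, p_band, i_band


def expected_counts(i: RateSchedule, kappa: float,
                    fixed: Mapping[str, DiseaseSchedules],
                    exposures: RegistryTable) -> dict:
    """Expected incident and prevalent counts per stratum of ``exposures``.

    ``i`` supplies the incidence schedule (band values expanded to the
    single-year grid); the model prevalence is re-projected from it.
    """
    out = {}
    for sex in sorted({k.sex for k in exposures.rows}):
        data = _sex_data(exposures.subset(sex=sex), sex)
        i_vec = np.nan_to_num(i.to_single_year(sex), nan=I_MIN)
        i_vec = _safe_incidence(np.clip(i_vec, I_MIN, I_MAX), fixed[sex])
        state = project_cohort(fixed[sex].with_incidence(i_vec))
        p_band, i_band = _band_means(i_vec, state, data.bands)
        py_free = data.person_years * (1.0 - p_band)
        e_inc = py_free * i_band + kappa * data.n_registered * p_band
        e_prev = data.n_registered * (1.0 - kappa) * p_band
        keys = sorted((k for k in exposures.rows if k.sex == sex), key=lambda k: k.age_band)
        for key, ei, ep in zip(keys, e_inc, e_prev):
            out[key] = (float(ei), float(ep))
    return out


def _poisson_logpmf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Continuous extension of the Poisson log-pmf (gamma-function form)."""
    out = np.where(lam > 0, xlogy(k, np.maximum(lam, 1e-300)) - lam - gammaln(k + 1.0), 0.0)
    out = np.where((lam <= 0) & (k > 0), -np.inf, out)
    return out


def _binom_logpmf(k: np.ndarray, n: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Continuous extension of the Binomial log-pmf."""
    q = np.clip(q, 0.0, 1.0)
    coef = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    with np.errstate(invalid="ignore"):
        out = coef + xlogy(k, q) + xlogy(n - k, 1.0 - q)
    out = np.where((q <= 0) & (k > 0), -np.inf, out)
    out = np.where((q >= 1) & (k < n), -np.inf, out)
    return out


def _loglik_sex(coefficients: np.ndarray, kappa: float,
                fixed: DiseaseSchedules, data: _SexData) -> float:
    e_inc, _, q, p_band, _ = _expected_for_sex(coefficients, kappa, fixed, data)
    if np.any(~np.isfinite(p_band)):
        return -np.inf
    ll = _poisson_logpmf(data.inc, e_inc).sum()
    ll += _binom_logpmf(data.prev, data.n_registered, q).sum()
    return float(ll)


def log_likelihood(params: Mapping[str, tuple[IncidenceParam, MisclassParam]],
                   data: RegistryTable,
                   fixed: Mapping[str, DiseaseSchedules]) -> float:
    """Joint Poisson (incidence) + binomial (prevalence) log-likelihood."""
    total = 0.0
    for sex, (inc_param, mis_param) in params.items():
        sd = _sex_data(data.subset(sex=sex), sex)
        total += _loglik_sex(inc_param.coefficients, mis_param.kappa, fixed[sex], sd)
    return total


# ---------------------------------------------------------------------------
# fitting


def _start_coefficients(data: _SexData, degree: int) -> np.ndarray:
    """Poisson-regression start for log i(a), ignoring misclassification."""
    mids = np.array([(b.lower + b.upper) / 2.0 for b in data.bands])
    x = (mids - 50.0) / 50.0
    basis = np.vander(x, degree + 1, increasing=True)
    py_free = np.maximum(
        data.person_years - data.prev - 0.5 * data.inc, 0.0)
    ok = py_free > 0
    if ok.sum() <= degree:
        c = np.full(degree + 1, 0.0)
        c[0] = np.log(max((data.inc.sum() + 0.5) / max(data.person_years.sum(), 1.0), I_MIN))
        return c
    try:
        import statsmodels.api as sm

        model = sm.GLM(data.inc[ok], basis[ok], family=sm.families.Poisson(),
                       offset=np.log(py_free[ok]))
        res = model.fit(maxiter=100)
        if np.all(np.isfinite(res.params)):
            return np.asarray(res.params, dtype=float)
    except Exception:  # singular design, separation, ...
        pass
    y = np.log((data.inc[ok] + 0.5) / py_free[ok])
    c, *_ = np.linalg.lstsq(basis[ok], y, rcond=None)
    return c


def _numeric_hessian(fun, theta: np.ndarray, rel_step: float) -> np.ndarray:
    p = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    hess = np.empty((p, p))
    f0 = fun(theta)
    for a in range(p):
        ea = np.zeros(p)
        ea[a] = h[a]
        fpp = fun(theta + ea)
        fmm = fun(theta - ea)
        hess[a, a] = (fpp - 2.0 * f0 + fmm) / h[a] ** 2
        for b in range(a + 1, p):
            eb = np.zeros(p)
            eb[b] = h[b]
            fab = fun(theta + ea + eb)
            fa_b = fun(theta + ea - eb)
            f_ab = fun(theta - ea + eb)
            f_a_b = fun(theta - ea - eb)
            hess[a, b] = hess[b, a] = (fab - fa_b - f_ab + f_a_b) / (4.0 * h[a] * h[b])
    return hess


def _covariance_from_hessian(neg_hess: np.ndarray) -> np.ndarray | None:
    try:
        cov = np.linalg.inv(neg_hess)
    except np.linalg.LinAlgError:
        return None
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals < -1e-8 * max(1.0, float(np.max(np.abs(eigvals))))):
        return None
    return cov


def _fit_sex(data: _SexData, fixed: DiseaseSchedules, config: FitConfig) -> SexFit:
    if np.count_nonzero(data.person_years > 0) < 2:
        raise ValueError("need at least 2 age bands with positive exposure")
    c0 = _start_coefficients(data, config.degree)
    theta0 = np.concatenate([c0, [logit(config.kappa_start)]])

    def negll_full(theta):
        return -_loglik_sex(theta[:-1], float(expit(theta[-1])), fixed, data)

    bounds = [(-30.0, 30.0)] * (config.degree + 1) + [(-30.0, 8.0)]
    res = minimize(negll_full, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": config.max_iter, "ftol": 1e-11, "gtol": 1e-6})
    kappa_hat = float(expit(res.x[-1]))
    converged = bool(res.success)

    def negll_pinned(coeffs):
        return -_loglik_sex(coeffs, 0.0, fixed, data)

    # Boundary handling.  On the logit scale the gradient vanishes as
    # kappa -> 0, so the optimizer can stall at a small interior value even
    # when the ML solution sits on the boundary; whenever kappa-hat is
    # small, compare against the pinned kappa = 0 fit and keep whichever
    # attains the higher likelihood.
    if kappa_hat < max(config.boundary_tol, 0.02):
        res2 = minimize(negll_pinned, res.x[:-1], method="L-BFGS-B",
                        bounds=bounds[:-1],
                        options={"maxiter": config.max_iter, "ftol": 1e-11, "gtol": 1e-6})
        tol = 1e-7 * max(1.0, abs(float(res.fun)))
        if kappa_hat < config.boundary_tol or float(res2.fun) <= float(res.fun) + tol:
            theta = np.asarray(res2.x, dtype=float)
            converged = converged and bool(res2.success)
            cov = _covariance_from_hessian(
                _numeric_hessian(negll_pinned, theta, config.hessian_rel_step))
            return SexFit(
                incidence=IncidenceParam(theta, sex=""),
                misclass=MisclassParam(0.0),
                theta=theta,
                covariance=cov,
                loglik=-float(res2.fun),
                converged=converged and cov is not None,
                kappa_on_boundary=True,
            )

    theta = np.asarray(res.x, dtype=float)
    cov = _covariance_from_hessian(
        _numeric_hessian(negll_full, theta, config.hessian_rel_step))
    return SexFit(
        incidence=IncidenceParam(theta[:-1], sex=""),
        misclass=MisclassParam(kappa_hat),
        theta=theta,
        covariance=cov,
        loglik=-float(res.fun),
        converged=converged and cov is not None,
        kappa_on_boundary=False,
    )


def fit_dismod(data: RegistryTable, fixed: Mapping[str, DiseaseSchedules],
               config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood fit, one (incidence curve, kappa) block per sex.

    ``data`` must contain a single network x disease; outflow schedules in
    ``fixed`` are held constant (not estimated).
    """
    config = config or FitConfig()
    if len(data.networks()) > 1 or len(data.diseases()) > 1:
        raise ValueError("fit_dismod expects a single network x disease subtable")
    by_sex: dict[str, SexFit] = {}
    for sex in sorted({k.sex for k in data.rows}):
        sd = _sex_data(data.subset(sex=sex), sex)
        sexfit = _fit_sex(sd, fixed[sex], config)
        by_sex[sex] = SexFit(
            incidence=IncidenceParam(sexfit.incidence.coefficients, sex=sex),
            misclass=sexfit.misclass,
            theta=sexfit.theta,
            covariance=sexfit.covariance,
            loglik=sexfit.loglik,
            converged=sexfit.converged,
            kappa_on_boundary=sexfit.kappa_on_boundary,
        )
    total_ll = sum(f.loglik for f in by_sex.values())
    return FitResult(by_sex=by_sex, loglik=total_ll,
                     converged=all(f.converged for f in by_sex.values()))


# ---------------------------------------------------------------------------
# parametric bootstrap


def sample_params(fit: FitResult, n: int = 1000, seed: int = 0) -> ParamDraws:
    """Multivariate-normal draws of the internal parameter vector per sex."""
    rng = np.random.default_rng(seed)
    by_sex = {}
    boundary = {}
    for sex in sorted(fit.by_sex):
        block = fit.by_sex[sex]
        if not block.converged or block.covariance is None:
            raise ValueError(f"cannot sample from a non-converged fit (sex {sex}); "
                             "if kappa sat near zero, a boundary refit is required")
        cov = block.covariance
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals < -1e-8 * max(1.0, float(np.max(np.abs(eigvals))))):
            raise ValueError("covariance is not positive semi-definite; "
                             "consider a boundary refit")
        draws = rng.multivariate_normal(block.theta, cov, size=n, method="eigh",
                                        check_valid="ignore")
        by_sex[sex] = draws
        boundary[sex] = block.kappa_on_boundary
    return ParamDraws(by_sex=by_sex, boundary=boundary, seed=seed)


def _draw_curves(theta: np.ndarray, boundary: bool,
                 fixed: DiseaseSchedules):
    """(i(a), p(a) state) implied by one internal parameter vector."""
    if boundary:
        coeffs = theta
    else:
        coeffs = theta[:-1]
    i_vec = _safe_incidence(incidence_curve(coeffs), fixed)
    state = project_cohort(fixed.with_incidence(i_vec))
    return i_vec, state


def _standardized_pair(thetas: Mapping[str, np.ndarray],
                       boundary: Mapping[str, bool],
                       fixed: Mapping[str, DiseaseSchedules],
                       w: StandardPopulation) -> tuple[float, float]:
    """Standardized (incidence, prevalence) per 1,000 for one parameter set."""
    inc_total = 0.0
    prev_total = 0.0
    cache = {}
    for (sex, band), wt in w.weights.items():
        if sex not in cache:
            cache[sex] = _draw_curves(thetas[sex], boundary[sex], fixed[sex])
        i_vec, state = cache[sex]
        sl = slice(band.lower, band.upper)
        alive = state.S[sl] + state.C[sl]
        tot = alive.sum()
        if tot <= 0:
            return np.nan, np.nan
        p_b = state.C[sl].sum() / tot
        s_tot = state.S[sl].sum()
        i_b = (state.S[sl] * i_vec[sl]).sum() / s_tot if s_tot > 0 else i_vec[sl].mean()
        inc_total += wt * i_b
        prev_total += wt * p_b
    return 1000.0 * inc_total, 1000.0 * prev_total


def model_standardized_rates(fit: FitResult,
                             fixed: Mapping[str, DiseaseSchedules],
                             w: StandardPopulation) -> tuple[float, float]:
    """Point-estimate standardized (incidence, prevalence) per 1,000 from
    the ML parameters, without bootstrap draws."""
    return _standardized_pair({s: fit.by_sex[s].theta for s in fit.by_sex},
                              {s: fit.by_sex[s].kappa_on_boundary for s in fit.by_sex},
                              fixed, w)


def standardized_rate_ci(fit: FitResult, draws: ParamDraws,
                         fixed: Mapping[str, DiseaseSchedules],
                         w: StandardPopulation,
                         max_dropped_frac: float = 0.10
                         ) -> tuple[StandardizedRate, StandardizedRate]:
    """Standardized incidence and prevalence with percentile bootstrap CIs.

    The point estimates come from the ML parameters; the 2.5th/97.5th
    percentiles over the draws give the CI; ``se_log`` is the SD of the log
    rates over the draws.  Draws producing non-finite rates are dropped
    (error if more than 10% are).
    """
    point = _standardized_pair({s: fit.by_sex[s].theta for s in fit.by_sex},
                               {s: fit.by_sex[s].kappa_on_boundary for s in fit.by_sex},
                               fixed, w)
    n = draws.n
    inc_vals = np.empty(n)
    prev_vals = np.empty(n)
    for k in range(n):
        thetas = {s: draws.by_sex[s][k] for s in draws.by_sex}
        inc_vals[k], prev_vals[k] = _standardized_pair(thetas, draws.boundary, fixed, w)
    ok = np.isfinite(inc_vals) & np.isfinite(prev_vals)
    dropped = n - int(ok.sum())
    if dropped:
        logger.warning("dropped %d/%d non-finite bootstrap draws", dropped, n)
    if dropped > max_dropped_frac * n:
        raise ValueError(f"{dropped}/{n} bootstrap draws were non-finite")
    inc_vals, prev_vals = inc_vals[ok], prev_vals[ok]

    def summarize(point_value: float, vals: np.ndarray) -> StandardizedRate:
        lo, hi = np.percentile(vals, [2.5, 97.5])
        lo = min(float(lo), point_value)
        hi = max(float(hi), point_value)
        with np.errstate(divide="ignore"):
            logs = np.log(np.maximum(vals, 1e-300))
        return StandardizedRate(value=point_value, ci_lo=lo, ci_hi=hi,
                                se_log=float(np.std(logs, ddof=1)) if vals.size > 1 else 0.0)

    return summarize(point[0], inc_vals), summarize(point[1], prev_vals)
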
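import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from dismodkit import dismod_fit
from dismodkit.dismod_fit import (
    FitConfig,
    FitResult,
    IncidenceParam,
    MisclassParam,
    ParamDraws,
    SexFit,
    expected_counts,
    fit_dismod,
    incidence_curve,
    log_likelihood,
    model_standardized_rates,
    sample_params,
    standardized_rate_ci,
)
from dismodkit.ipm import DiseaseSchedules, project_cohort
from dismodkit.rates import RateSchedule
from dismodkit.registry_io import (
    AgeBand,
    RegistryCounts,
    RegistryTable,
    StratumKey,
    uniform_standard_population,
)

SEXES = ("f", "m")
WIDE_BANDS = [AgeBand(lo, lo + 20) for lo in range(0, 100, 20)]


def fixed_schedules() -> dict[str, DiseaseSchedules]:
    ages = np.arange(100, dtype=float)
    m = np.clip(5e-5 * np.exp(0.08 * ages), 0, 0.5)
    f = 0.5 * m
    r = np.where(ages >= 65, 0.001, 0.0)
    return {s: DiseaseSchedules(i=0.0, m=m, f=f, r=r) for s in SEXES}


def exposures_table(n_per_band: float, bands=None) -> RegistryTable:
    bands = bands or WIDE_BANDS
    rows = {}
    for sex in SEXES:
        for band in bands:
            rows[StratumKey("net", "d", sex, band)] = RegistryCounts(
                person_years=n_per_band, n_registered=int(n_per_band),
                prev_count=0, inc_count=0, deaths_with_disease=0, inst_with_disease=0)
    return RegistryTable("episode_of_disease", 0, rows)


def model_table(i_const: float, kappa: float, fixed, n_per_band: float,
                seed=None, exact=False, bands=None) -> RegistryTable:
    """Counts drawn from (or set to the expectation of) the observation model."""
    bands = bands or WIDE_BANDS
    exposures = exposures_table(n_per_band, bands)
    i_sched = RateSchedule(
        values={(s, b): i_const for s in SEXES for b in bands}, kind="incidence")
    expectation = expected_counts(i_sched, kappa, fixed, exposures)
    rng = np.random.default_rng(seed)
    rows = {}
    for key, counts in exposures.rows.items():
        e_inc, e_prev = expectation[key]
        if exact:
            inc, prev = e_inc, e_prev
        else:
            inc = int(rng.poisson(e_inc))
            prev = int(rng.binomial(counts.n_registered, e_prev / counts.n_registered))
        rows[key] = RegistryCounts(
            person_years=counts.person_years, n_registered=counts.n_registered,
            prev_count=prev, inc_count=inc, deaths_with_disease=0, inst_with_disease=0)
    return RegistryTable("episode_of_disease", 0, rows)


class TestIncidenceCurve:
    def test_constant(self):
        i = incidence_curve([np.log(0.01), 0, 0, 0])
        assert np.allclose(i, 0.01)

    def test_linear_term_at_100(self):
        i = incidence_curve([np.log(0.01), 1, 0, 0], ages=[100])
        assert i[0] == pytest.approx(0.01 * np.e)

    def test_clipping(self):
        assert incidence_curve([5.0], ages=[50])[0] == 0.5
        assert incidence_curve([-99.0], ages=[50])[0] == 1e-10


class TestExpectedCounts:
    def closed_form_p_band(self, i_const, band):
        # no mortality: p(a) = 1 - (1-i)^a with unit occupancy
        ages = np.arange(band.lower, band.upper)
        return np.mean(1 - (1 - i_const) ** ages)

    def test_no_misclassification(self):
        fixed = {s: DiseaseSchedules(i=0.0, m=0.0, f=0.0, r=0.0) for s in SEXES}
        exposures = exposures_table(10_000)
        i_sched = RateSchedule(values={(s, b): 0.005 for s in SEXES for b in WIDE_BANDS},
                               kind="incidence")
        out = expected_counts(i_sched, 0.0, fixed, exposures)
        for key, (e_inc, e_prev) in out.items():
            p = self.closed_form_p_band(0.005, key.age_band)
            assert e_prev == pytest.approx(10_000 * p, rel=1e-9)
            assert e_inc == pytest.approx(10_000 * (1 - p) * 0.005, rel=1e-9)

    def test_misclassification_shifts_counts(self):
        fixed = {s: DiseaseSchedules(i=0.0, m=0.0, f=0.0, r=0.0) for s in SEXES}
        exposures = exposures_table(10_000)
        i_sched = RateSchedule(values={(s, b): 0.005 for s in SEXES for b in WIDE_BANDS},
                               kind="incidence")
        base = expected_counts(i_sched, 0.0, fixed, exposures)
        shifted = expected_counts(i_sched, 0.1, fixed, exposures)
        for key in base:
            n_p = base[key][1]  # n * p_mod at kappa = 0
            assert shifted[key][1] == pytest.approx(0.9 * n_p, rel=1e-9)
            assert shifted[key][0] == pytest.approx(base[key][0] + 0.1 * n_p, rel=1e-9)

    def test_arithmetic_example(self):
        # E[inc] = PY_free*i + kappa*n*p = 50 + 50 = 100 when kappa*n*p = 50
        py_free, i, kappa, n_p = 10_000.0, 0.005, 0.1, 500.0
        assert py_free * i + kappa * n_p == pytest.approx(100.0)
        assert (1 - kappa) * n_p == pytest.approx(450.0)


class TestLogLikelihood:
    def params(self, i_const, kappa):
        c = [np.log(i_const), 0, 0, 0]
        return {s: (IncidenceParam(c, s), MisclassParam(kappa)) for s in SEXES}

    def test_matches_scipy_pmf_oracle(self):
        fixed = fixed_schedules()
        table = model_table(0.01, 0.1, fixed, 5_000, seed=5)
        params = self.params(0.01, 0.1)
        ll = log_likelihood(params, table, fixed)

        i_sched = RateSchedule(values={(s, b): 0.01 for s in SEXES for b in WIDE_BANDS},
                               kind="incidence")
        expectation = expected_counts(i_sched, 0.1, fixed, table)
        oracle = 0.0
        for key, counts in table.rows.items():
            e_inc, e_prev = expectation[key]
            q = e_prev / counts.n_registered
            oracle += stats.poisson.logpmf(counts.inc_count, e_inc)
            oracle += stats.binom.logpmf(counts.prev_count, counts.n_registered, q)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_zero_count_poisson_term(self):
        # inc_count = 0 contributes exactly -lambda
        fixed = {s: DiseaseSchedules(i=0.0, m=0.0, f=0.0, r=0.0) for s in SEXES}
        bands = [AgeBand(0, 100)]
        rows = {StratumKey("net", "d", s, bands[0]): RegistryCounts(
            person_years=1000.0, n_registered=1000, prev_count=0, inc_count=0,
            deaths_with_disease=0, inst_with_disease=0) for s in SEXES}
        table = RegistryTable("episode_of_disease", 0, rows)
        params = self.params(0.01, 0.0)
        i_sched = RateSchedule(values={(s, bands[0]): 0.01 for s in SEXES},
                               kind="incidence")
        expectation = expected_counts(i_sched, 0.0, fixed, table)
        oracle = 0.0
        for key, counts in table.rows.items():
            e_inc, e_prev = expectation[key]
            oracle += -e_inc + counts.n_registered * np.log1p(-e_prev / counts.n_registered)
        assert log_likelihood(params, table, fixed) == pytest.approx(oracle, abs=1e-8)

    def test_full_prevalence_finite(self):
        fixed = {s: DiseaseSchedules(i=0.0, m=0.0, f=0.0, r=0.0) for s in SEXES}
        bands = [AgeBand(0, 100)]
        rows = {StratumKey("net", "d", s, bands[0]): RegistryCounts(
            person_years=100.0, n_registered=100, prev_count=100, inc_count=0,
            deaths_with_disease=0, inst_with_disease=0) for s in SEXES}
        table = RegistryTable("episode_of_disease", 0, rows)
        ll = log_likelihood(self.params(0.01, 0.0), table, fixed)
        # oracle: binomial log-pmf at k = n with q < 1, plus Poisson at 0
        i_sched = RateSchedule(values={(s, bands[0]): 0.01 for s in SEXES},
                               kind="incidence")
        expectation = expected_counts(i_sched, 0.0, fixed, table)
        oracle = sum(
            stats.binom.logpmf(100, 100, e_prev / 100) + stats.poisson.logpmf(0, e_inc)
            for e_inc, e_prev in expectation.values())
        assert np.isfinite(ll)
        assert ll == pytest.approx(oracle, abs=1e-10)


class TestFitDismod:
    def test_boundary_case_by_construction(self):
        # exact-expectation data generated at kappa = 0: the ML solution is
        # on the boundary, deterministically
        fixed = fixed_schedules()
        table = model_table(0.01, 0.0, fixed, 20_000, exact=True)
        fit = fit_dismod(table, fixed)
        for sex in SEXES:
            assert fit.by_sex[sex].kappa_on_boundary
            assert fit.by_sex[sex].misclass.kappa == 0.0

    def test_kappa_recovery_from_simulated_counts(self):
        fixed = fixed_schedules()
        table = model_table(0.01, 0.15, fixed, 100_000, seed=12345)
        fit = fit_dismod(table, fixed)
        for sex in SEXES:
            assert 0.10 < fit.by_sex[sex].misclass.kappa < 0.20

    def test_exact_expectation_identity(self):
        # noise-free counts: fitted kappa reproduces the generator to 1e-3
        fixed = fixed_schedules()
        table = model_table(0.01, 0.15, fixed, 50_000, exact=True)
        fit = fit_dismod(table, fixed)
        for sex in SEXES:
            assert fit.by_sex[sex].misclass.kappa == pytest.approx(0.15, abs=1e-3)

    def test_duplicated_strata_double_loglik(self):
        from dismodkit.dismod_fit import _fit_sex, _sex_data

        fixed = fixed_schedules()
        table = model_table(0.01, 0.1, fixed, 20_000, seed=77)
        sd = _sex_data(table.subset(sex="f"), "f")
        doubled = type(sd)(bands=sd.bands + sd.bands,
                           person_years=np.tile(sd.person_years, 2),
                           n_registered=np.tile(sd.n_registered, 2),
                           prev=np.tile(sd.prev, 2), inc=np.tile(sd.inc, 2))
        config = FitConfig()
        fit1 = _fit_sex(sd, fixed["f"], config)
        fit2 = _fit_sex(doubled, fixed["f"], config)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-6)
        assert fit2.misclass.kappa == pytest.approx(fit1.misclass.kappa, abs=2e-3)
        assert np.allclose(fit2.theta[:-1], fit1.theta[:-1], atol=2e-3)

    def test_requires_single_network(self):
        fixed = fixed_schedules()
        t1 = model_table(0.01, 0.0, fixed, 1_000, seed=1)
        rows = dict(t1.rows)
        for key, counts in t1.rows.items():
            rows[StratumKey("other", key.disease, key.sex, key.age_band)] = counts
        merged = RegistryTable("episode_of_disease", 0, rows)
        with pytest.raises(ValueError, match="single network"):
            fit_dismod(merged, fixed)

    def test_ml_beats_truth_loglik(self):
        fixed = fixed_schedules()
        truth_params = {s: (IncidenceParam([np.log(0.01), 0, 0, 0], s),
                            MisclassParam(0.15)) for s in SEXES}
        for seed in range(3):
            table = model_table(0.01, 0.15, fixed, 30_000, seed=900 + seed)
            fit = fit_dismod(table, fixed)
            assert fit.loglik >= log_likelihood(truth_params, table, fixed) - 1e-6


def make_fit(theta_by_sex, cov_by_sex, boundary=False):
    by_sex = {}
    for sex, theta in theta_by_sex.items():
        theta = np.asarray(theta, dtype=float)
        coeffs = theta if boundary else theta[:-1]
        kappa = 0.0 if boundary else float(expit(theta[-1]))
        by_sex[sex] = SexFit(
            incidence=IncidenceParam(coeffs, sex), misclass=MisclassParam(kappa),
            theta=theta, covariance=cov_by_sex[sex], loglik=0.0, converged=True,
            kappa_on_boundary=boundary)
    return FitResult(by_sex=by_sex, loglik=0.0, converged=True)


class TestSampleParams:
    def test_zero_covariance_draws_equal_estimate(self):
        theta = np.array([np.log(0.01), 0.5, 0.0, 0.0, logit(0.1)])
        fit = make_fit({s: theta for s in SEXES},
                       {s: np.zeros((5, 5)) for s in SEXES})
        draws = sample_params(fit, n=20, seed=1)
        for sex in SEXES:
            assert np.allclose(draws.by_sex[sex], theta)

    def test_determinism(self):
        theta = np.array([np.log(0.01), 0.5, 0.0, 0.0, logit(0.1)])
        cov = 0.01 * np.eye(5)
        fit = make_fit({s: theta for s in SEXES}, {s: cov for s in SEXES})
        d1 = sample_params(fit, n=50, seed=42)
        d2 = sample_params(fit, n=50, seed=42)
        for sex in SEXES:
            assert np.array_equal(d1.by_sex[sex], d2.by_sex[sex])

    def test_monte_carlo_sd_matches_diagonal(self):
        theta = np.zeros(3)
        sds = np.array([0.1, 0.2, 0.3])
        fit = make_fit({"f": theta}, {"f": np.diag(sds**2)}, boundary=True)
        draws = sample_params(fit, n=10_000, seed=7)
        empirical = draws.by_sex["f"].std(axis=0, ddof=1)
        assert np.all(np.abs(empirical / sds - 1) < 0.05)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 0.0], [0.0, -1.0]])
        fit = make_fit({"f": np.zeros(2)}, {"f": bad}, boundary=True)
        with pytest.raises(ValueError, match="positive semi-definite"):
            sample_params(fit, n=10, seed=0)

    def test_non_converged_fit_rejected(self):
        block = SexFit(incidence=IncidenceParam([0.0], "f"), misclass=MisclassParam(0.0),
                       theta=np.zeros(1), covariance=None, loglik=0.0,
                       converged=False, kappa_on_boundary=True)
        fit = FitResult(by_sex={"f": block}, loglik=0.0, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            sample_params(fit, n=10, seed=0)


class TestStandardizedRateCI:
    def test_identical_draws_collapse_ci(self):
        fixed = fixed_schedules()
        theta = np.array([np.log(0.01), 0.0, 0.0, 0.0, logit(0.1)])
        fit = make_fit({s: theta for s in SEXES}, {s: np.zeros((5, 5)) for s in SEXES})
        draws = sample_params(fit, n=30, seed=3)
        inc, prev = standardized_rate_ci(fit, draws, fixed, uniform_standard_population())
        assert inc.ci_lo == pytest.approx(inc.value, abs=1e-12)
        assert inc.ci_hi == pytest.approx(inc.value, abs=1e-12)
        assert prev.ci_lo == pytest.approx(prev.value, abs=1e-12)

    def test_percentiles_match_sort_oracle(self):
        fixed = fixed_schedules()
        theta = np.array([np.log(0.01), 0.2, 0.0, 0.0, logit(0.1)])
        cov = np.diag([0.01, 0.004, 0.0, 0.0, 0.04])
        fit = make_fit({s: theta for s in SEXES}, {s: cov for s in SEXES})
        draws = sample_params(fit, n=400, seed=9)
        inc, _ = standardized_rate_ci(fit, draws, fixed, uniform_standard_population())

        # independent route: rebuild every draw's standardized incidence with
        # public pieces, then take sorted-linear-interpolation percentiles
        stdpop = uniform_standard_population()
        values = []
        for k in range(400):
            total = 0.0
            for sex in SEXES:
                coeffs = draws.by_sex[sex][k][:-1]
                i_vec = np.minimum(incidence_curve(coeffs), 1.0 - fixed[sex].m)
                state = project_cohort(fixed[sex].with_incidence(i_vec))
                for (s, band), wt in stdpop.weights.items():
                    if s != sex:
                        continue
                    sl = slice(band.lower, band.upper)
                    s_occ = state.S[sl]
                    total += wt * float((s_occ * i_vec[sl]).sum() / s_occ.sum())
            values.append(1000.0 * total)
        values = np.sort(np.array(values))

        def percentile(sorted_vals, pct):
            # linear interpolation between closest ranks
            idx = (len(sorted_vals) - 1) * pct / 100.0
            lo, hi = int(np.floor(idx)), int(np.ceil(idx))
            frac = idx - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        assert inc.ci_lo == pytest.approx(percentile(values, 2.5), abs=1e-9)
        assert inc.ci_hi == pytest.approx(percentile(values, 97.5), abs=1e-9)
        assert inc.se_log == pytest.approx(np.std(np.log(values), ddof=1), abs=1e-9)

    def test_modeled_vs_observed_direction_on_care_data(self):
        # kappa > 0 data: the model moves incidence down and prevalence up
        # relative to the naive observed rates
        from dismodkit.rates import direct_standardize, incidence_schedule, prevalence_schedule
        from dismodkit.synthetic_data import get_preset, simulate_registry

        sc = get_preset("knee_oa_like", 150_000)
        table = simulate_registry(sc.truth, sc.obs, seed=21)
        fixed = sc.truth.schedules
        fit = fit_dismod(table, fixed)
        stdpop = uniform_standard_population()
        obs_inc = direct_standardize(incidence_schedule(table, "net", "knee_oa"), stdpop)
        obs_prev = direct_standardize(prevalence_schedule(table, "net", "knee_oa"), stdpop)
        mod_inc, mod_prev = model_standardized_rates(fit, fixed, stdpop)
        assert any(fit.by_sex[s].misclass.kappa > 0 for s in SEXES)
        assert mod_inc < obs_inc.value
        assert mod_prev >= obs_prev.value


@pytest.fixture(scope="module")
def calibration_replicates():
    """20 parametric replicates at 1e6 person-years each: kappa estimates
    and bootstrap-CI coverage of the true standardized incidence."""
    fixed = fixed_schedules()
    stdpop = uniform_standard_population()
    truth_theta = np.array([np.log(0.01), 0.0, 0.0, 0.0, logit(0.15)])
    truth_fit = make_fit({s: truth_theta for s in SEXES},
                         {s: np.zeros((5, 5)) for s in SEXES})
    true_inc, _ = model_standardized_rates(truth_fit, fixed, stdpop)
    out = []
    for seed in range(20):
        # 5 bands x 2 sexes x 100k person-years per band = 1e6 PY
        table = model_table(0.01, 0.15, fixed, 100_000, seed=3000 + seed)
        fit = fit_dismod(table, fixed)
        draws = sample_params(fit, n=300, seed=seed)
        inc, _ = standardized_rate_ci(fit, draws, fixed, stdpop)
        out.append({
            "kappa": np.mean([fit.by_sex[s].misclass.kappa for s in SEXES]),
            "covers": inc.ci_lo <= true_inc <= inc.ci_hi,
        })
    return out


class TestBootstrapCalibration:
    def test_mean_kappa_within_002(self, calibration_replicates):
        mean_kappa = np.mean([r["kappa"] for r in calibration_replicates])
        assert abs(mean_kappa - 0.15) <= 0.02

    def test_ci_coverage_in_band(self, calibration_replicates):
        coverage = np.mean([r["covers"] for r in calibration_replicates])
        assert 0.88 <= coverage <= 1.0
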
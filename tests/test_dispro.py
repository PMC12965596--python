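import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special, stats

from faersignal.dispro import (GPS_INIT, ContingencyTable, GpsPrior,
                               SignalMetrics, SignalThresholds, bcpnn_ic,
                               build_tables, compute_metrics, ebgm_stat,
                               evaluate_signal, gps_fit, gps_loglik,
                               posterior_cdf, prr_stat, ror_stat)
from faersignal.errors import DataError


class TestContingencyTable:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_expected(self):
        t = ContingencyTable(10, 20, 30, 240)
        assert t.n == 300
        assert t.expected == pytest.approx(4.0)


class TestBuildTables:
    def test_small_enumeration(self):
        cohort = [(1, "E1"), (1, "E2"), (2, "E1")]
        background = [(3, "E1"), (4, "E2")]
        tables = build_tables(cohort, cohort + background)
        t = tables["E1"]
        assert (t.a, t.b, t.c, t.d) == (2, 0, 1, 1)
        t2 = tables["E2"]
        assert (t2.a, t2.b, t2.c, t2.d) == (1, 1, 1, 1)

    def test_term_absent_from_cohort(self):
        cohort = [(1, "E1"), (2, "E1")]
        everything = cohort + [(3, "E9")]
        t = build_tables(cohort, everything)["E9"]
        assert (t.a, t.b) == (0, 2)

    def test_repeated_mention_counts_once(self):
        cohort = [(1, "E1"), (1, "E1")]
        t = build_tables(cohort, cohort + [(2, "E1")])["E1"]
        assert t.a == 1

    def test_margins_consistent(self, small_dataset):
        from faersignal.cohort import deduplicate, select_primary_suspect
        survivors = deduplicate(small_dataset.reports)
        cohort = select_primary_suspect(
            survivors.survivors, small_dataset.drug_rows, ["MIRTAZAPINE"])
        pairs = sorted({(r.primaryid, r.pt) for r in small_dataset.reac_rows
                        if r.primaryid in survivors.survivor_ids})
        cohort_pairs = [(p, t) for p, t in pairs if p in cohort]
        tables = build_tables(cohort_pairs, pairs)
        n_cohort = len({p for p, _ in cohort_pairs})
        ns = {t.n for t in tables.values()}
        assert len(ns) == 1  # identical N across terms
        for t in tables.values():
            assert t.a + t.b == n_cohort
        # sum of a over terms = distinct (report, term) pairs in cohort
        assert sum(t.a for t in tables.values()) == len(cohort_pairs)

    def test_empty_database_raises(self):
        with pytest.raises(DataError):
            build_tables([], [])


class TestRor:
    def test_point_estimate(self):
        est = ror_stat(ContingencyTable(10, 20, 30, 240))
        assert est.ror == pytest.approx(4.0)

    def test_ci_against_independent_recomputation(self):
        est = ror_stat(ContingencyTable(10, 20, 30, 240))
        assert est.lo == pytest.approx(1.7118753498660897, rel=1e-12)
        assert est.hi == pytest.approx(9.34647490616159, rel=1e-12)

    def test_symmetric_table(self):
        est = ror_stat(ContingencyTable(5, 5, 5, 5))
        assert est.ror == pytest.approx(1.0)
        assert est.lo < 1 < est.hi

    def test_zero_cell_undefined(self):
        est = ror_stat(ContingencyTable(0, 20, 30, 240))
        assert not est.defined
        assert math.isnan(est.ror)
        assert "zero cell" in est.reason


class TestPrr:
    def test_point_estimate(self):
        est = prr_stat(ContingencyTable(10, 20, 30, 240))
        assert est.prr == pytest.approx(3.0)

    def test_exact_independence(self):
        est = prr_stat(ContingencyTable(10, 90, 20, 180))
        assert est.prr == pytest.approx(1.0)
        assert est.chi2 == pytest.approx(0.0)

    def test_yates_chi2_textbook_value(self):
        # sum over cells of (|obs - exp| - 0.5)^2 / exp
        est = prr_stat(ContingencyTable(10, 20, 30, 240))
        assert est.chi2 == pytest.approx(9.695512820512821, rel=1e-12)

    def test_uncorrected_option(self):
        t = ContingencyTable(10, 20, 30, 240)
        obs = np.array([[10, 20], [30, 240]])
        expected = stats.chi2_contingency(obs, correction=False)[0]
        assert prr_stat(t, yates=False).chi2 == pytest.approx(expected)

    def test_no_background_term_reports_undefined(self):
        est = prr_stat(ContingencyTable(10, 20, 0, 240))
        assert not est.defined


class TestBcpnn:
    def test_ic_example(self):
        ic, _ = bcpnn_ic(ContingencyTable(10, 20, 30, 240))
        assert ic == pytest.approx(math.log2(10.5 / 4.5), rel=1e-12)
        assert ic == pytest.approx(1.222392421336448, rel=1e-12)

    def test_ic025_example(self):
        _, ic025 = bcpnn_ic(ContingencyTable(10, 20, 30, 240))
        assert ic025 == pytest.approx(-0.02458111698478707, rel=1e-9)

    def test_independence_limit(self):
        # a == E and a large -> IC -> 0
        t = ContingencyTable(10_000, 90_000, 90_000, 810_000)
        assert t.expected == pytest.approx(t.a)
        ic, _ = bcpnn_ic(t)
        assert abs(ic) < 1e-4


def _simulate_tables(rng, n_pairs, alpha, beta, e_values):
    """Tables whose a-counts follow a gamma-Poisson mixture around E."""
    e = np.asarray(e_values)[rng.integers(0, len(e_values), n_pairs)]
    lam = rng.gamma(alpha, 1 / beta, n_pairs)
    a = rng.poisson(lam * e)
    n_total = 1_000_000
    tables = []
    for ai, ei in zip(a, e):
        margin = max(int(round(math.sqrt(ei * n_total))), ai + 1)
        b = margin - ai
        c = margin - ai
        tables.append(ContingencyTable(ai, b, c, n_total - ai - b - c))
    return tables


class TestGpsFit:
    def test_single_gamma_parameter_recovery(self):
        rng = np.random.default_rng(17)
        tables = _simulate_tables(rng, 100_000, 2.0, 4.0,
                                  [0.5, 1, 2, 5, 10, 20])
        prior = gps_fit(tables, single_component=True)
        assert prior.alpha2 == pytest.approx(2.0, rel=0.1)
        assert prior.beta2 == pytest.approx(4.0, rel=0.1)

    def test_fit_on_real_database_tables(self, small_dataset):
        from faersignal.pipeline import fit_database_prior
        from faersignal.cohort import deduplicate
        survivors = deduplicate(small_dataset.reports).survivors
        prior = fit_database_prior(survivors, small_dataset.drug_rows,
                                   small_dataset.reac_rows)
        assert isinstance(prior, GpsPrior)
        assert 0.5 <= prior.mean <= 2.0  # mostly-null database

    def test_loglik_at_fit_beats_init(self):
        rng = np.random.default_rng(23)
        tables = _simulate_tables(rng, 5_000, 1.5, 2.0, [1, 5, 10])
        prior = gps_fit(tables)
        a = np.array([t.a for t in tables], float)
        e = np.array([t.expected for t in tables], float)
        ll_init = gps_loglik(GPS_INIT, a, e)
        ll_fit = gps_loglik((prior.alpha1, prior.beta1, prior.alpha2,
                             prior.beta2, prior.p_mix), a, e)
        assert ll_fit >= ll_init

    def test_null_data_prior_mean_near_one(self):
        rng = np.random.default_rng(31)
        e_values = [0.5, 1, 2, 5, 10, 20]
        e = np.asarray(e_values)[rng.integers(0, len(e_values), 20_000)]
        a = rng.poisson(e)  # rate ratio exactly 1 everywhere
        n_total = 1_000_000
        tables = []
        for ai, ei in zip(a, e):
            margin = max(int(round(math.sqrt(ei * n_total))), int(ai) + 1)
            tables.append(ContingencyTable(
                int(ai), margin - ai, margin - ai,
                n_total - 2 * margin + int(ai)))
        prior = gps_fit(tables)
        assert 0.8 <= prior.mean <= 1.25


DEGENERATE_PRIOR = GpsPrior(2.0, 4.0, 2.0, 4.0, 0.5)


class TestEbgm:
    def test_degenerate_prior_digamma_closed_form(self):
        t = ContingencyTable(10, 190, 3990, 195810)
        assert t.expected == pytest.approx(4.0, rel=1e-3)
        ebgm, _ = ebgm_stat(t, DEGENERATE_PRIOR)
        # exp(psi(2+10) - ln(4+E)) with E ~= 4
        expected = math.exp(special.digamma(12)
                            - math.log(4 + t.expected))
        assert ebgm == pytest.approx(expected, rel=1e-9)
        assert ebgm == pytest.approx(1.438, abs=2e-3)

    def test_large_count_limit(self):
        # a = 10000, E = 1000 with a weak prior -> EBGM ~= a/E = 10
        weak = GpsPrior(0.01, 0.01, 0.01, 0.01, 0.5)
        n = 100_000_000
        margin = int(math.sqrt(1000 / 0.9998 * n))  # E ~ 1000 after overlap
        a = 10_000
        t = ContingencyTable(a, margin - a, margin - a, n - 2 * margin + a)
        ebgm, _ = ebgm_stat(t, weak)
        assert ebgm == pytest.approx(a / t.expected, rel=0.01)

    def test_ebgm05_below_ebgm_and_cdf_calibrated(self):
        rng = np.random.default_rng(5)
        prior = GpsPrior(0.7, 0.6, 2.5, 2.2, 0.3)
        for _ in range(200):
            a = int(rng.integers(1, 200))
            margin = int(rng.integers(a + 1, a + 5000))
            n = int(rng.integers(4 * margin, 40 * margin))
            t = ContingencyTable(a, margin - a, margin - a,
                                 n - 2 * margin + a)
            ebgm, ebgm05 = ebgm_stat(t, prior)
            assert ebgm05 < ebgm
            assert posterior_cdf(ebgm05, t, prior) == pytest.approx(
                0.05, abs=1e-5)

    def test_quadrature_oracle_single_table(self):
        prior = GpsPrior(0.9, 0.8, 3.0, 2.0, 0.4)
        t = ContingencyTable(25, 975, 4975, 994025)
        ebgm, ebgm05 = ebgm_stat(t, prior)
        from faersignal.dispro import posterior_mixture
        q, (s1, r1), (s2, r2) = posterior_mixture(t, prior)

        def mean_log():
            f1 = integrate.quad(
                lambda x: math.log(x) * stats.gamma.pdf(x, s1, scale=1/r1),
                0, np.inf)[0]
            f2 = integrate.quad(
                lambda x: math.log(x) * stats.gamma.pdf(x, s2, scale=1/r2),
                0, np.inf)[0]
            return q * f1 + (1 - q) * f2

        assert ebgm == pytest.approx(math.exp(mean_log()), rel=1e-6)


class TestShrinkageProperty:
    def test_ebgm_between_prior_and_raw_ratio_on_log_scale(self):
        rng = np.random.default_rng(11)
        prior = GpsPrior(1.2, 1.1, 2.4, 2.3, 0.35)
        prior_geo_mean = math.exp(
            prior.p_mix * (special.digamma(prior.alpha1)
                           - math.log(prior.beta1))
            + (1 - prior.p_mix) * (special.digamma(prior.alpha2)
                                   - math.log(prior.beta2)))
        for _ in range(200):
            a = int(rng.integers(1, 100))
            margin = int(rng.integers(a + 1, a + 2000))
            n = int(rng.integers(4 * margin, 20 * margin))
            t = ContingencyTable(a, margin - a, margin - a,
                                 n - 2 * margin + a)
            ebgm, _ = ebgm_stat(t, prior)
            lhs = abs(math.log(ebgm) - math.log(prior_geo_mean))
            rhs = abs(math.log(a / t.expected) - math.log(prior_geo_mean))
            assert lhs <= rhs + 1e-9


class TestMonotonicity:
    @given(st.integers(1, 60))
    @settings(max_examples=30, deadline=None)
    def test_stats_nondecreasing_in_a(self, a):
        b, c, d = 500, 800, 100_000
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert ror_stat(t2).ror > ror_stat(t1).ror
        assert prr_stat(t2).prr > prr_stat(t1).prr
        assert bcpnn_ic(t2)[0] > bcpnn_ic(t1)[0]
        e1, _ = ebgm_stat(t1, DEGENERATE_PRIOR)
        e2, _ = ebgm_stat(t2, DEGENERATE_PRIOR)
        assert e2 > e1


class TestEvaluateSignal:
    def _metrics(self, **kw):
        base = dict(a=10, ror=3.0, ror_lo=1.5, ror_hi=6.0, prr=3.0,
                    chi2=25.0, ic=1.1, ic025=0.4, ebgm=3.0, ebgm05=2.2)
        base.update(kw)
        return SignalMetrics(**base)

    def test_all_criteria_met(self):
        t = ContingencyTable(10, 100, 100, 10_000)
        assert evaluate_signal(self._metrics(), t, SignalThresholds())

    def test_single_failing_component_blocks(self):
        t = ContingencyTable(10, 100, 100, 10_000)
        m = self._metrics(ic025=-0.02)
        assert not evaluate_signal(m, t, SignalThresholds())
        assert m.flags["bcpnn"] is False

    def test_min_count_gate(self):
        t = ContingencyTable(2, 10, 10, 10_000)
        m = self._metrics(a=2, ror=50.0, ror_lo=10.0, ror_hi=250.0)
        assert not evaluate_signal(m, t, SignalThresholds())
        assert any("min_a" in r for r in m.reasons)

    def test_undefined_component_is_negative_with_reason(self):
        t = ContingencyTable(10, 0, 100, 10_000)
        m = self._metrics(ror=math.nan, ror_lo=math.nan, ror_hi=math.nan)
        assert not evaluate_signal(m, t, SignalThresholds())
        assert any("undefined" in r.lower() for r in m.reasons)

    def test_compute_metrics_end_to_end(self):
        t = ContingencyTable(50, 950, 1000, 199_000)
        m = compute_metrics(t, DEGENERATE_PRIOR)
        assert m.ror_lo <= m.ror <= m.ror_hi
        assert m.ic025 <= m.ic
        assert m.ebgm05 <= m.ebgm
        assert m.positive == all(m.flags.values())
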
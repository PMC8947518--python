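"""Tumour onset, Gompertz growth, nodal spread, and metastasis."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from bcmicrosim import Scenario, rng_stream
from bcmicrosim.natural_history import (
    NaturalHistory,
    Tumour,
    diameter,
    metastasis_hazard,
    node_intensity,
    onset_rate,
    sample_first_event,
    sample_metastasis_age,
    sample_nodes,
    sample_onsets,
    sample_tumour,
    volume,
    volume_derivative,
)
from bcmicrosim.population import Individual

from conftest import flat_onset_params


def make_tumour(**kw):
    defaults = dict(
        tumour_type="invasive",
        onset_age=50.0,
        alpha=0.5,
        dmax=5.0,
        d0=0.2,
        mu_N=0.0,
        mu_M=0.0,
    )
    defaults.update(kw)
    return Tumour(**defaults)


def make_individual(**kw):
    defaults = dict(
        id=0,
        birth_year=1950,
        region="default",
        brca="none",
        family_history=False,
        hrt=None,
        other_cause_death_age=85.0,
    )
    defaults.update(kw)
    return Individual(**defaults)


class TestGrowth:
    def test_diameter_at_onset_is_occult_size(self):
        t = make_tumour()
        assert diameter(t, t.onset_age) == pytest.approx(0.2)

    def test_diameter_saturates_at_dmax(self):
        t = make_tumour()
        assert diameter(t, t.onset_age + 1e6) == pytest.approx(5.0, rel=1e-9)

    def test_closed_form_spot_check(self):
        # d0 (dmax/d0)^(1-e^{-alpha tau}) at tau = 2
        t = make_tumour(alpha=0.5, dmax=5.0)
        assert diameter(t, 52.0) == pytest.approx(1.530, abs=1e-3)

    def test_diameter_before_onset_rejected(self):
        with pytest.raises(ValueError):
            diameter(make_tumour(), 49.0)

    @settings(max_examples=200, deadline=None)
    @given(
        alpha=st.floats(0.01, 5.0),
        dmax=st.floats(0.5, 20.0),
        tau1=st.floats(0.0, 50.0),
        dtau=st.floats(1e-6, 50.0),
    )
    def test_growth_is_monotone_and_bounded(self, alpha, dmax, tau1, dtau):
        from hypothesis import assume

        # keep the exponent in a range where the curve is not yet
        # saturated to dmax at float precision
        assume(alpha * (tau1 + dtau) < 15.0)
        t = make_tumour(alpha=alpha, dmax=dmax)
        d1 = diameter(t, t.onset_age + tau1)
        d2 = diameter(t, t.onset_age + tau1 + dtau)
        assert d1 < d2 < dmax

    @pytest.mark.parametrize(
        "d,expected,tol",
        [(0.0, 0.0, 0), (1.0, 0.5236, 1e-4), (0.2, 4.189e-3, 1e-6)],
    )
    def test_spherical_volume(self, d, expected, tol):
        assert volume(d) == pytest.approx(expected, abs=tol)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            volume(-1.0)

    def test_volume_derivative_matches_finite_difference(self):
        t = make_tumour()
        a, h = 53.0, 1e-6
        fd = (volume(diameter(t, a + h)) - volume(diameter(t, a - h))) / (2 * h)
        assert volume_derivative(t, a) == pytest.approx(fd, rel=1e-5)


class TestOnset:
    def test_rate_is_base_rate_when_all_rrs_are_one(self, params):
        p = flat_onset_params(params, 0.002, 0.001)
        ind = make_individual()
        rates = onset_rate(p, ind, 50.0, 2000.0, {})
        assert rates["invasive"] == pytest.approx(0.002)
        assert rates["dcis"] == pytest.approx(0.001)

    def test_relative_risks_multiply(self, params):
        """BRCA x family history combine multiplicatively on the base rate."""
        ind = make_individual(brca="carrier", family_history=True)
        base = onset_rate(params, make_individual(), 55.0, 2005.0, {})["invasive"]
        rr = params.relative_risk("brca") * params.relative_risk("family_history")
        got = onset_rate(params, ind, 55.0, 2005.0, {})["invasive"]
        assert got == pytest.approx(base * rr)

    def test_prior_dcis_raises_invasive_rate_only(self, params):
        ind = make_individual()
        plain = onset_rate(params, ind, 60.0, 2010.0, {"had_dcis": False})
        primed = onset_rate(params, ind, 60.0, 2010.0, {"had_dcis": True})
        rr = params.relative_risk("prior_dcis_invasive")
        assert primed["invasive"] == pytest.approx(plain["invasive"] * rr)
        assert primed["dcis"] == pytest.approx(plain["dcis"])

    def test_age_outside_table_support_errors(self, params):
        with pytest.raises(ValueError, match="no row"):
            onset_rate(params, make_individual(), 500.0, 2000.0, {})

    def test_zero_rate_gives_no_onsets(self, params):
        p = flat_onset_params(params, 0.0, 0.0)
        ind = make_individual()
        assert sample_onsets(p, ind, rng_stream(0, 0, "natural_history")) == []

    def test_constant_rate_count_matches_poisson_mean(self, params):
        """NHPP with constant intensity r over L years: mean count = rL."""
        r, L, n = 0.02, 60.0, 20_000
        p = flat_onset_params(params, r, 0.0)
        rng = np.random.default_rng(42)
        counts = []
        for i in range(n):
            ind = make_individual(other_cause_death_age=L)
            counts.append(len(sample_onsets(p, ind, rng)))
        counts = np.asarray(counts)
        se = np.sqrt(r * L / n)
        assert abs(counts.mean() - r * L) < 3 * se

    def test_doubling_rates_doubles_expected_count(self, params):
        n = 20_000
        means = []
        for r in (0.01, 0.02):
            p = flat_onset_params(params, r, r)
            rng = np.random.default_rng(1)
            ind = make_individual(other_cause_death_age=60.0)
            means.append(
                np.mean([len(sample_onsets(p, ind, rng)) for _ in range(n)])
            )
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.05)


class TestNodalSpread:
    def test_zero_propensity_means_zero_intensity(self, params):
        t = make_tumour(mu_N=0.0)
        assert node_intensity(params, t, 55.0) == 0.0

    def test_dcis_has_no_nodal_spread(self, params):
        with pytest.raises(ValueError, match="invasive"):
            node_intensity(params, make_tumour(tumour_type="dcis"), 55.0)

    def test_volume_terms_off_gives_constant_intensity(self, params):
        ns = params.node_spread.copy()
        ns.loc[0, ["b2", "b3"]] = 0.0
        p = dataclasses.replace(params, node_spread=ns)
        t = make_tumour(mu_N=2.0)
        expected = 2.0 * float(ns.loc[0, "b1"])
        for age in (50.0, 55.0, 70.0):
            assert node_intensity(p, t, age) == pytest.approx(expected)

    def test_homogeneous_expected_count(self, params):
        """mu_N=2, b1=0.1, b2=b3=0 over 5 years -> Poisson mean 1.0."""
        ns = params.node_spread.copy()
        ns.loc[0, ["b1", "b2", "b3"]] = [0.1, 0.0, 0.0]
        p = dataclasses.replace(params, node_spread=ns)
        t = make_tumour(mu_N=2.0)
        rng = np.random.default_rng(3)
        n = 20_000
        counts = np.array([len(sample_nodes(p, t, 55.0, rng)) for _ in range(n)])
        assert abs(counts.mean() - 1.0) < 3 * np.sqrt(1.0 / n)

    def test_empty_window_gives_no_nodes(self, params):
        t = make_tumour(mu_N=1.0)
        assert len(sample_nodes(params, t, t.onset_age, np.random.default_rng(0))) == 0

    def test_mean_count_matches_quadrature(self, params):
        """MC mean node count vs numerically integrated intensity."""
        t = make_tumour(mu_N=0.7, alpha=0.4, dmax=4.0)
        until = t.onset_age + 10.0
        lam, _ = integrate.quad(
            lambda a: node_intensity(params, t, a), t.onset_age, until, limit=200
        )
        rng = np.random.default_rng(8)
        n = 20_000
        counts = np.array([len(sample_nodes(params, t, until, rng)) for _ in range(n)])
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / n)

    def test_degenerate_gamma_behaves_as_fixed_mean(self, params):
        """mu_N gamma variance -> 0 gives the same count law as fixed mu_N."""
        ns0 = params.node_spread.copy()
        ns0.loc[0, "mu_n_var"] = 0.0
        p0 = dataclasses.replace(params, node_spread=ns0)
        mean = float(ns0.loc[0, "mu_n_mean"])
        ind = make_individual()
        rng = rng_stream(5, 0, "natural_history")
        draws = [
            sample_tumour(p0, ind, 50.0, "invasive", rng).mu_N for _ in range(200)
        ]
        assert all(d == pytest.approx(mean) for d in draws)

    def test_gamma_heterogeneity_moments(self, params):
        """Gamma draws reproduce the requested mean and variance."""
        ind = make_individual()
        rng = rng_stream(6, 0, "natural_history")
        mus = np.array(
            [sample_tumour(params, ind, 50.0, "invasive", rng).mu_N for _ in range(50_000)]
        )
        row = params.node_spread.iloc[0]
        assert mus.mean() == pytest.approx(row["mu_n_mean"], rel=0.03)
        assert mus.var() == pytest.approx(row["mu_n_var"], rel=0.10)


class TestMetastasis:
    def test_hazards_add_across_tumours(self, params):
        """Three invasive tumours: woman-level hazard is the sum of the
        per-tumour hazards mu_M * k."""
        tumours = []
        per_tumour = []
        for mu in (0.01, 0.02, 0.03):
            t = make_tumour(mu_M=1.0)
            k = metastasis_hazard(params, [t], 55.0)
            t2 = make_tumour(mu_M=mu / k)
            per_tumour.append(mu)
            tumours.append(t2)
        total = metastasis_hazard(params, tumours, 55.0)
        assert total == pytest.approx(sum(per_tumour))

    def test_no_invasive_tumours_means_zero_hazard(self, params):
        dcis = make_tumour(tumour_type="dcis", dmax=2.0)
        assert metastasis_hazard(params, [dcis], 60.0) == 0.0
        assert metastasis_hazard(params, [], 60.0) == 0.0

    def test_zero_propensity_never_metastasises(self, params):
        nh = NaturalHistory(tumours=[make_tumour(mu_M=0.0)])
        assert sample_metastasis_age(params, nh, 90.0, np.random.default_rng(0)) is None

    def test_constant_hazard_median_is_ln2_over_h(self, params):
        """A flat k-table with mu_M*k = 0.1/yr: median time ln2/0.1 = 6.93."""
        k = params.k_table.copy()
        k["k"] = 0.1
        p = dataclasses.replace(params, k_table=k)
        t = make_tumour(mu_M=1.0, onset_age=40.0)
        nh = NaturalHistory(tumours=[t])
        rng = np.random.default_rng(11)
        n = 50_000
        times = np.array(
            [sample_metastasis_age(p, nh, 1e6, rng) - 40.0 for _ in range(n)]
        )
        assert np.median(times) == pytest.approx(math.log(2) / 0.1, abs=0.1)

    def test_survival_matches_integrated_hazard(self, params):
        """KS test of simulated metastasis times against exp(-int hazard)."""
        t = make_tumour(mu_M=1.0, alpha=0.6, dmax=4.0, mu_N=0.0, onset_age=40.0)
        nh = NaturalHistory(tumours=[t])
        until = 60.0
        rng = np.random.default_rng(12)
        draws = []
        n = 20_000
        for _ in range(n):
            a = sample_metastasis_age(params, nh, until, rng)
            if a is not None:
                draws.append(a)
        draws = np.asarray(draws)

        grid = np.linspace(40.0, until, 2001)
        h = np.array([metastasis_hazard(params, [t], a) for a in grid])
        cum = integrate.cumulative_trapezoid(h, grid, initial=0.0)
        total = cum[-1]

        def cdf(x):  # conditional on event before `until`
            return np.interp(x, grid, 1.0 - np.exp(-cum)) / (1.0 - np.exp(-total))

        assert stats.kstest(draws, cdf).pvalue > 0.01

    def test_joint_simulation_equals_superposition(self, params):
        """k tumours simulated jointly vs the superposition of k
        single-tumour first-event draws: same first-event law (KS)."""
        tum = [
            make_tumour(mu_M=0.8, alpha=0.5, dmax=4.0, onset_age=40.0),
            make_tumour(mu_M=0.4, alpha=0.3, dmax=3.0, onset_age=45.0),
        ]
        until = 65.0
        rng = np.random.default_rng(13)
        n = 20_000
        joint = []
        for _ in range(n):
            a = sample_metastasis_age(params, NaturalHistory(tumours=tum), until, rng)
            joint.append(a if a is not None else np.inf)
        superposed = []
        for _ in range(n):
            firsts = []
            for t in tum:
                a = sample_metastasis_age(params, NaturalHistory(tumours=[t]), until, rng)
                firsts.append(a if a is not None else np.inf)
            superposed.append(min(firsts))
        joint = np.asarray(joint)
        superposed = np.asarray(superposed)
        # compare finite-event distributions and event probabilities
        p_joint = np.isfinite(joint).mean()
        p_sup = np.isfinite(superposed).mean()
        assert abs(p_joint - p_sup) < 3 * np.sqrt(2 * p_joint * (1 - p_joint) / n)
        res = stats.ks_2samp(joint[np.isfinite(joint)], superposed[np.isfinite(superposed)])
        assert res.pvalue > 0.01


class TestFirstEventSampler:
    def test_zero_hazard_never_fires(self):
        rng = np.random.default_rng(0)
        assert sample_first_event(lambda t: np.zeros_like(t), 0, 50, rng) is None

    def test_constant_hazard_is_exponential(self):
        rng = np.random.default_rng(1)
        n = 20_000
        draws = [sample_first_event(lambda t: np.full_like(t, 0.3), 0, 1e4, rng) for _ in range(n)]
        assert stats.kstest(np.array(draws), stats.expon(scale=1 / 0.3).cdf).pvalue > 0.01

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sample_first_event(lambda t: -np.ones_like(t), 0, 10, np.random.default_rng(0))
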
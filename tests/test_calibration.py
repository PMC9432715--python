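"""Replacement-rate fitting, chi-squared weighting, ensemble scan."""

import numpy as np
import pytest

from cryptcomp.calibration import (
    PRESETS,
    ParameterRanges,
    chi_squared,
    ensemble_scan,
    exemplary_tissue,
    fit_lambda,
    model_rates_at,
)
from cryptcomp.hazard import TissueParams
from cryptcomp.incidence import AgeGroupRecord, IncidenceTable, poisson_intervals
from cryptcomp.niche import Arrangement, NicheParams
from cryptcomp.synthetic import generate_incidence


def _flat_table(rates, sigma=1.0):
    records = tuple(
        AgeGroupRecord(
            age_lo=5.0 * k,
            age_hi=5.0 * k + 5,
            rate=float(r),
            ci_lo=float(r) - 1.96 * sigma,
            ci_hi=float(r) + 1.96 * sigma,
            sigma=sigma,
        )
        for k, r in enumerate(rates)
    )
    return IncidenceTable(records=records)


class TestModelRates:
    def test_closed_pathways_give_zero_rates(self):
        tissue = TissueParams(
            K=10**7, gamma=0.0, niche=NicheParams(8, 0.0, 1e-6, 0.016)
        )
        rates = model_rates_at(tissue, np.array([2.5, 42.5, 82.5]))
        np.testing.assert_array_equal(rates, 0.0)

    def test_rates_span_orders_of_magnitude(self, colon_tissue):
        rates = model_rates_at(colon_tissue, np.array([2.5, 42.5, 82.5]))
        assert rates[2] / rates[0] > 100  # youngest to oldest midpoint
        assert rates[2] / rates[1] > 10  # still steeply rising past midlife

    def test_negative_age_rejected(self, colon_tissue):
        with pytest.raises(ValueError):
            model_rates_at(colon_tissue, np.array([-1.0]))


class TestChiSquared:
    def test_zero_when_model_equals_data(self):
        table = _flat_table(np.linspace(1, 17, 17))
        assert chi_squared(table.rates, table) == 0.0

    def test_unit_when_one_group_off_by_one_sigma(self):
        table = _flat_table(np.full(17, 10.0), sigma=2.5)
        model = table.rates.copy()
        model[7] += 2.5
        assert chi_squared(model, table) == pytest.approx(1.0)

    def test_expectation_matches_chi2_distribution(self):
        # unit-sigma Gaussian perturbations on 17 groups: E[chi2] = 17
        rng = np.random.default_rng(7)
        table = _flat_table(np.full(17, 100.0), sigma=3.0)
        values = [
            chi_squared(table.rates + 3.0 * rng.standard_normal(17), table)
            for _ in range(1000)
        ]
        # SE of the mean of 1000 chi2_17 draws: sqrt(2*17/1000) ~ 0.18
        assert np.mean(values) == pytest.approx(17.0, abs=0.7)

    def test_mismatched_lengths_rejected(self):
        table = _flat_table(np.full(17, 1.0))
        with pytest.raises(ValueError):
            chi_squared(np.ones(5), table)

    def test_alternative_weightings_available(self, noise_free_table):
        model = noise_free_table.rates * 1.1
        base = chi_squared(model, noise_free_table, weighting="poisson_ci")
        logw = chi_squared(model, noise_free_table, weighting="log_rates")
        sq = chi_squared(model, noise_free_table, weighting="sqrt_mu")
        assert base > 0 and logw > 0 and sq > 0
        assert not np.isclose(base, logw)


class TestFitLambda:
    def test_noise_free_recovery(self, colon_tissue, noise_free_table):
        fit = fit_lambda(colon_tissue, noise_free_table)
        assert fit.converged
        assert fit.n_points == 17
        assert fit.lambda_hat == pytest.approx(0.016, rel=1e-3)
        assert fit.chi2 < 1e-2

    def test_optimality_against_rate_halving_and_doubling(self, colon_tissue, noise_free_table):
        fit = fit_lambda(colon_tissue, noise_free_table)

        def chi2_at(lam):
            t = TissueParams(colon_tissue.K, colon_tissue.gamma, colon_tissue.niche.with_lam(lam))
            return chi_squared(model_rates_at(t, noise_free_table.midpoints), noise_free_table)

        assert fit.chi2 <= chi2_at(2 * fit.lambda_hat)
        assert fit.chi2 <= chi2_at(fit.lambda_hat / 2)

    def test_matches_brute_force_grid(self, colon_tissue, noise_free_table):
        fit = fit_lambda(colon_tissue, noise_free_table)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 400))
        chis = [
            chi_squared(
                model_rates_at(
                    TissueParams(colon_tissue.K, colon_tissue.gamma, colon_tissue.niche.with_lam(lam)),
                    noise_free_table.midpoints,
                ),
                noise_free_table,
            )
            for lam in grid
        ]
        best = grid[int(np.argmin(chis))]
        step = np.log(grid[1]) - np.log(grid[0])
        assert abs(np.log(fit.lambda_hat) - np.log(best)) <= step

    def test_fitted_rate_increases_with_true_rate(self, colon_tissue):
        hats = []
        for lam_true in (0.008, 0.016, 0.032):
            tissue = TissueParams(colon_tissue.K, colon_tissue.gamma, colon_tissue.niche.with_lam(lam_true))
            table = generate_incidence(tissue, noise="none")
            hats.append(fit_lambda(colon_tissue, table).lambda_hat)
        assert hats[0] < hats[1] < hats[2]

    def test_unprepared_table_rejected(self, colon_tissue):
        records = tuple(
            AgeGroupRecord(age_lo=5.0 * k, age_hi=None if k == 5 else 5.0 * k + 5, rate=1.0, sigma=1.0)
            for k in range(6)
        )
        table = IncidenceTable(records=records)
        with pytest.raises(ValueError):
            fit_lambda(colon_tissue, table)


class TestEnsembleScan:
    def test_combinatorial_count_and_determinism(self, noise_free_table):
        ranges = ParameterRanges(
            n_min=7,
            n_max=8,
            n_exemplar=8,
            k=(1e7, 1.5e7, 2e7),
            u=(1.75e-6, 4.4e-6, 7.13e-6),
            v=(1.75e-6, 4.4e-6, 7.13e-6),
            gamma=(0.015, 0.05, 0.094),
        )
        a = ensemble_scan(ranges, noise_free_table)
        b = ensemble_scan(ranges, noise_free_table)
        assert len(a.results) == 3**4 * 2
        assert not a.failures
        assert a.stats == b.stats
        assert [r.lambda_hat for r in a.kept] == [r.lambda_hat for r in b.kept]

    def test_identical_chi2_keeps_everything(self):
        # all fits hitting an identical objective cannot be filtered out
        table = _flat_table(np.full(17, 0.0), sigma=1.0)
        ranges = ParameterRanges(
            n_min=5, n_max=5, n_exemplar=5,
            k=(1e7,) * 3, u=(4.4e-6,) * 3, v=(4.4e-6,) * 3, gamma=(0.05,) * 3,
        )
        summary = ensemble_scan(ranges, table)
        assert len(summary.kept) == len(summary.results)

    def test_generating_combination_attains_minimum(self):
        # scan against noise-free data generated at the expected-value set
        expected = TissueParams(
            K=1.5e7, gamma=0.05, niche=NicheParams(7, 4.4e-6, 4.4e-6, 0.016)
        )
        table = generate_incidence(expected, noise="none")
        ranges = ParameterRanges(
            n_min=6, n_max=8, n_exemplar=7,
            k=PRESETS["colon"].k, u=PRESETS["colon"].u,
            v=PRESETS["colon"].v, gamma=PRESETS["colon"].gamma,
        )
        summary = ensemble_scan(ranges, table)
        best = min(summary.results, key=lambda r: r.chi2)
        assert best.tissue.niche.N == 7
        assert best.tissue.K == pytest.approx(1.5e7)
        assert best.tissue.niche.u == pytest.approx(4.4e-6)
        assert best.tissue.niche.v == pytest.approx(4.4e-6)
        assert best.tissue.gamma == pytest.approx(0.05)
        assert best.lambda_hat == pytest.approx(0.016, rel=1e-3)


def test_presets_cover_the_three_organs():
    assert set(PRESETS) == {"colon", "gastric", "rectum"}
    assert PRESETS["gastric"].k == (4e6, 8e6, 16e6)
    assert PRESETS["rectum"].k[0] == pytest.approx(1e6)
    gastric = exemplary_tissue("gastric")
    assert gastric.niche.N == 7 and gastric.K == 8_000_000


def test_arrangements_agree_after_separate_calibration(colon_tissue, noise_free_table):
    """The two topologies bracket real arrangements; once each is given its
    own fitted rate, their predicted incidence curves nearly coincide."""
    ring_niche = NicheParams(
        colon_tissue.niche.N,
        colon_tissue.niche.u,
        colon_tissue.niche.v,
        1.0,
        Arrangement.LINEAR_RING,
    )
    ring_tissue = TissueParams(colon_tissue.K, colon_tissue.gamma, ring_niche)
    fit = fit_lambda(ring_tissue, noise_free_table)
    rates_ring = model_rates_at(fit.tissue, noise_free_table.midpoints)
    rates_mixed = noise_free_table.rates
    mid = noise_free_table.midpoints
    rel = np.abs(rates_ring / rates_mixed - 1.0)
    # bulk of the incidence (ages > 40) agrees to ~10%; the sparse young-age
    # tail differs by at most a factor ~2 on rates spanning 3+ decades
    assert np.max(rel[mid > 40]) < 0.10
    assert np.max(rates_ring / rates_mixed) < 2.5
    assert 0.5 < fit.lambda_hat / 0.016 < 2.0
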
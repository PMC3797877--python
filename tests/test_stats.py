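import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hierqst.design import LABEL_COLUMNS, PhenotypeTable, PopulationInfo, StudyDesign, ValidationError
from hierqst.stats import (
    correlate_elevation,
    g_test,
    holm_adjust,
    population_means,
    power_transform,
)


def small_table(rows):
    pops = tuple(
        PopulationInfo(p, "R1", 1000.0 + 100 * i)
        for i, p in enumerate(sorted({r["population"] for r in rows}))
    )
    design = StudyDesign(pops, 6, 8)
    df = pd.DataFrame(rows)
    for c in LABEL_COLUMNS:
        if c not in df:
            df[c] = {"plant_id": "x", "region": "R1", "treatment": "control", "family": "F1",
                     "initial_diameter": 5.0}[c]
    return PhenotypeTable(df[LABEL_COLUMNS + ["y"]], design, ["y"])


class TestPopulationMeans:
    def test_single_family_population_mean_is_family_mean(self):
        table = small_table(
            [{"population": "P1", "family": "F1", "y": v} for v in (1.0, 3.0)]
        )
        assert population_means(table, "y")["P1"] == pytest.approx(2.0)

    def test_families_weighted_equally_regardless_of_size(self):
        """Families of sizes (1, 99) with means (0, 10) average to 5, not 9.9."""
        rows = [{"population": "P1", "family": "F1", "y": 0.0}]
        rows += [{"population": "P1", "family": "F2", "y": 10.0} for _ in range(99)]
        table = small_table(rows)
        assert population_means(table, "y")["P1"] == pytest.approx(5.0)

    def test_clipped_plants_excluded_by_default(self):
        rows = [
            {"population": "P1", "family": "F1", "treatment": "control", "y": 1.0},
            {"population": "P1", "family": "F1", "treatment": "clipped", "y": 100.0},
        ]
        table = small_table(rows)
        assert population_means(table, "y")["P1"] == pytest.approx(1.0)

    def test_recovers_generating_population_effects(self, design):
        from hierqst.simulate import PhenoSimParams, simulate_phenotypes

        table = simulate_phenotypes(
            PhenoSimParams(design=design, sigma2_residual=1e-30, seed=77)
        )
        means = population_means(table, "trait")
        # family means are exact, so population means have zero within-pop spread
        per_plant = table.subset_treatment("control").data
        for pop, block in per_plant.groupby("population"):
            assert means[pop] == pytest.approx(block["trait"].mean(), abs=1e-9)


class TestCorrelateElevation:
    def test_proportional_values_give_r_one(self, design):
        elev = design.elevations()
        means = pd.Series(2.0 * elev.to_numpy(), index=elev.index, name="y")
        res = correlate_elevation(means, design)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_values_raise(self, design):
        means = pd.Series(1.0, index=design.elevations().index, name="y")
        with pytest.raises(ValidationError, match="zero variance"):
            correlate_elevation(means, design)

    def test_p_value_matches_t_transformation(self, design):
        rng = np.random.default_rng(6)
        elev = design.elevations()
        y = 0.9 * (elev - elev.mean()) / elev.std() + rng.normal(0, 0.4, len(elev))
        means = pd.Series(y.to_numpy(), index=elev.index, name="y")
        res = correlate_elevation(means, design)
        n = len(elev)
        t = res.r * np.sqrt((n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-12)

    def test_affine_rescaling_of_elevation_leaves_r(self, design):
        elev = design.elevations()
        rng = np.random.default_rng(8)
        means = pd.Series(rng.normal(0, 1, len(elev)), index=elev.index, name="y")
        r1 = correlate_elevation(means, design).r
        scaled = StudyDesign(
            tuple(
                PopulationInfo(p.population, p.region, 3.0 * p.elevation + 7.0, p.longitude, p.latitude)
                for p in design.populations
            ),
            design.families_per_population,
            design.plants_per_family,
        )
        assert correlate_elevation(means, scaled).r == pytest.approx(r1, abs=1e-12)

    def test_subset_restriction(self, design):
        elev = design.elevations()
        means = pd.Series(np.arange(len(elev), dtype=float), index=elev.index, name="y")
        subset = design.populations_in("SEA")
        res = correlate_elevation(means, design, subset=subset, label="SEA")
        assert res.n_populations == len(subset)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.037]) == [pytest.approx(0.037)]

    def test_equal_pvalues_all_scaled_by_m(self):
        assert holm_adjust([0.01] * 8) == [pytest.approx(0.08)] * 8

    def test_step_down_hand_computation(self):
        """(0.001, 0.02, 0.04) -> (0.003, 0.04, 0.04)."""
        adjusted = holm_adjust([0.001, 0.02, 0.04])
        assert adjusted == [pytest.approx(v) for v in (0.003, 0.04, 0.04)]

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 20)
        adj = np.array(holm_adjust(p))
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, pvals):
        base = holm_adjust(pvals)
        rev = holm_adjust(pvals[::-1])
        assert rev == base[::-1]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.0, 0.5])


class TestGTest:
    def test_observed_equals_expected_gives_zero(self):
        obs = np.array([10.0, 20.0, 30.0])
        res = g_test(obs, expected=obs)
        assert res.g == 0.0
        assert res.p == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        """(10,0;0,10) gives G = 40 ln 2 with 1 df."""
        res = g_test(np.array([[10, 0], [0, 10]]))
        assert res.g == pytest.approx(40 * np.log(2), abs=1e-10)
        assert res.df == 1

    def test_independence_symmetric_under_transpose(self):
        rng = np.random.default_rng(4)
        obs = rng.integers(1, 30, (3, 4)).astype(float)
        a, b = g_test(obs), g_test(obs.T)
        assert a.g == pytest.approx(b.g, abs=1e-12)
        assert a.df == b.df

    def test_expected_zero_with_observed_raises(self):
        with pytest.raises(ValidationError, match="expected"):
            g_test(np.array([5.0, 1.0]), expected=np.array([5.0, 0.0]))
        # expected 0 with observed 0 is silently dropped
        res = g_test(np.array([5.0, 0.0, 5.0]), expected=np.array([5.0, 0.0, 5.0]))
        assert res.g == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            g_test(np.array([[1.0, -2.0], [3.0, 4.0]]))

    def test_matches_scipy_log_likelihood_statistic(self):
        rng = np.random.default_rng(9)
        obs = rng.integers(5, 40, (4, 4)).astype(float)
        res = g_test(obs)
        g_scipy, p_scipy, df_scipy, _ = sps.chi2_contingency(obs, correction=False,
                                                             lambda_="log-likelihood")
        assert res.g == pytest.approx(float(g_scipy), abs=1e-10)
        assert res.df == int(df_scipy)
        assert res.p == pytest.approx(float(p_scipy), abs=1e-12)


class TestPowerTransform:
    def test_identity_and_zero(self):
        vals = np.array([0.0, 1.0, 7.5])
        assert np.allclose(power_transform(vals, 1.0), vals)
        assert power_transform(np.array([0.0]), 0.331)[0] == 0.0

    def test_log_exp_oracle(self):
        got = power_transform(np.array([8.0]), 0.331)[0]
        assert got == pytest.approx(np.exp(0.331 * np.log(8.0)), abs=1e-12)

    def test_negative_rejected_missing_passes(self):
        with pytest.raises(ValidationError):
            power_transform(np.array([-1.0]), 0.5)
        out = power_transform(np.array([np.nan, 4.0]), 0.5)
        assert np.isnan(out[0]) and out[1] == 2.0
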
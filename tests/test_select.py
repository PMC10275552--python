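import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islandbd import (
    CladeRecord,
    IslandDataset,
    ModelParams,
    ModelSpec,
    bootstrap_lrt,
    decide_model,
    gof_compare,
    gof_statistics,
    make_table1_fixture,
)
from islandbd.fit import FitResult


class TestDecideModel:
    def test_empirical_delta_beyond_iw_tail_selects_cs(self):
        cs = np.linspace(-0.29, 8.0, 200)
        iw = np.linspace(-3.0, 1.11, 200)
        assert decide_model(6.43, cs, iw) == "CS"

    def test_delta_between_percentiles_is_indecisive(self):
        cs = np.linspace(-0.29, 8.0, 200)
        iw = np.linspace(-3.0, 1.11, 200)
        assert decide_model(0.5, cs, iw) == "indecisive"

    def test_delta_below_both_selects_iw(self):
        cs = np.linspace(1.0, 8.0, 200)
        iw = np.linspace(-3.0, 2.0, 200)
        assert decide_model(-2.0, cs, iw) == "IW"

    def test_identical_distributions_zero_delta_indecisive(self):
        # stub scenario: both models explain every dataset equally well
        zeros = np.zeros(100)
        assert decide_model(0.0, zeros, zeros) == "indecisive"

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=20, max_size=60), st.data())
    def test_monotone_in_empirical_delta(self, deltas, data):
        cs = np.array(deltas)
        iw = cs - 1.0
        order = {"IW": 0, "indecisive": 1, "CS": 2}
        ds = sorted(data.draw(st.lists(st.floats(-10, 10), min_size=3, max_size=8)))
        decisions = [order[decide_model(d, cs, iw)] for d in ds]
        assert decisions == sorted(decisions)


class TestGofStatistics:
    def test_table1_summary(self, table1):
        assert gof_statistics(table1) == {
            "total_species": 65,
            "n_colonizations": 5,
            "largest_clade_size": 28,
            "largest_clade_rank": 1,
        }

    def test_empty_dataset(self):
        assert gof_statistics(IslandDataset(10.0, 5, ())) == {
            "total_species": 0,
            "n_colonizations": 0,
            "largest_clade_size": 0,
            "largest_clade_rank": 0,
        }

    def test_size_tie_goes_to_older_colonization(self):
        ds = IslandDataset(
            20.0,
            9,
            (
                CladeRecord("young", 1, "endemic_clade", 5.0, (4.0, 2.0)),
                CladeRecord("old", 2, "endemic_clade", 10.0, (7.0, 3.0)),
            ),
        )
        s = gof_statistics(ds)
        assert s["largest_clade_size"] == 3 and s["largest_clade_rank"] == 1


class TestGofCompare:
    @pytest.fixture()
    def cheap_fit(self):
        return FitResult(
            spec=ModelSpec("CS", True),
            params=ModelParams(0.3, 0.1, 4.0, 0.02, 0.0),
            loglik=-10.0,
            df=4,
            n_events=5,
        )

    def test_percentiles_and_medians_reported(self, cheap_fit):
        ds = IslandDataset(
            8.0, 12, (CladeRecord("a", 1, "endemic_clade", 5.0, (2.0,)),)
        )
        res = gof_compare(ds, cheap_fit, n_sims=300, seed=5)
        assert set(res.medians) == set(res.percentiles) == set(res.empirical)
        for v in res.percentiles.values():
            assert 0.0 <= v <= 1.0

    def test_zero_colonization_edge(self, cheap_fit):
        fit = FitResult(
            spec=ModelSpec("CS", True),
            params=cheap_fit.params.with_(gamma0=1e-12),
            loglik=-1.0,
            df=4,
            n_events=2,
        )
        ds = IslandDataset(8.0, 12, (CladeRecord("a", 1, "endemic_singleton", 5.0),))
        res = gof_compare(ds, fit, n_sims=100, seed=6)
        assert res.medians["total_species"] == 0
        assert res.percentiles["total_species"] >= 0.99

    def test_percentile_calibration_under_true_model(self, cheap_fit):
        """Percentile of a statistic from data simulated under the model is ~uniform."""
        from islandbd import simulate_cs

        rng = np.random.default_rng(17)
        pcts = []
        while len(pcts) < 60:
            ds = simulate_cs(cheap_fit.params, 8.0, 12, rng=rng).dataset
            res = gof_compare(ds, cheap_fit, n_sims=150, seed=int(rng.integers(2**31)))
            pcts.append(res.percentiles["total_species"])
        # randomized tie-breaking makes these continuous uniforms
        from scipy.stats import kstest

        assert kstest(pcts, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def toy_world():
    ds = IslandDataset(
        6.0,
        8,
        (
            CladeRecord("a", 1, "endemic_clade", 4.0, (2.0,)),
            CladeRecord("b", 2, "non_endemic_singleton", 1.5),
        ),
    )
    fit_cs = FitResult(ModelSpec("CS", True), ModelParams(0.3, 0.1, 3.0, 0.04, 0.0), -9.0, 4, 3)
    fit_iw = FitResult(ModelSpec("IW", True), ModelParams(0.3, 0.1, 6.0, 0.04, 0.0), -9.5, 4, 3)
    return ds, fit_cs, fit_iw


class TestBootstrapPlumbing:
    def test_bootstrap_runs_and_is_seed_deterministic(self, toy_world):
        ds, fit_cs, fit_iw = toy_world
        r1 = bootstrap_lrt(ds, fit_cs, fit_iw, n_reps=3, seed=11, max_evals=120)
        r2 = bootstrap_lrt(ds, fit_cs, fit_iw, n_reps=3, seed=11, max_evals=120)
        assert np.array_equal(r1.deltas_under_cs, r2.deltas_under_cs)
        assert np.array_equal(r1.deltas_under_iw, r2.deltas_under_iw)
        assert r1.decision == r2.decision
        assert r1.empirical_delta == pytest.approx(0.5)
        assert len(r1.deltas_under_cs) + r1.n_failures_cs == 3
        assert len(r1.deltas_under_iw) + r1.n_failures_iw == 3
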
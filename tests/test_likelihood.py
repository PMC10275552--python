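import math
from dataclasses import replace

import numpy as np
import pytest

from islandbd import (
    CladeRecord,
    IslandDataset,
    LikelihoodOptions,
    ModelParams,
    loglik_iw,
    loglik_oracle_mc,
)
from islandbd.likelihood import QState, apply_branching, apply_colonization, propagate_q

EXACT = LikelihoodOptions()
APPROX = LikelihoodOptions(reset="approx")


def _state(n_dim=5, k=0, w=0, age=5.0, p_dim=1):
    q = np.zeros((n_dim, p_dim, 1))
    q[0, 0, 0] = 1.0
    return QState(q=q, log_scale=0.0, k=k, age=age, w=w)


class TestOperators:
    def test_zero_length_interval_is_identity(self):
        p = ModelParams(0.3, 0.2, 10.0, 0.01, 0.0)
        s = _state()
        out = propagate_q(s, s.age, p, 10)
        assert np.allclose(out.q, s.q) and out.log_scale == 0.0

    def test_all_rates_zero_is_identity(self):
        p = ModelParams(0.0, 0.0, math.inf, 0.0, 0.0)
        out = propagate_q(_state(), 1.0, p, 10)
        assert np.allclose(out.q[0, 0, 0] * math.exp(out.log_scale), 1.0)

    def test_pure_colonization_decay(self):
        # k=0, only colonization active: Q_0 shrinks by exp(-M gamma0 dt)
        p = ModelParams(0.0, 0.0, math.inf, 0.01, 0.0)
        out = propagate_q(_state(), 0.0, p, 10, APPROX)
        val = out.q[0, 0, 0] * math.exp(out.log_scale)
        assert val == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_colonization_event_scales_by_rate_and_increments_k(self):
        p = ModelParams(0.0, 0.0, math.inf, 0.01, 0.0)
        out = apply_colonization(_state(), "non_endemic_singleton", p, 10, APPROX)
        assert out.k == 1 and out.F == 1
        assert out.q[0, 0, 0] * math.exp(out.log_scale) == pytest.approx(0.01)

    def test_colonization_zeroed_beyond_cap(self):
        p = ModelParams(0.4, 0.1, 36.45, 0.01, 0.0)
        s = _state(n_dim=40, k=0)
        s.q[:, 0, 0] = 1.0
        out = apply_colonization(s, "endemic_clade", p, 10, APPROX)
        scaled = out.q[:, 0, 0] * math.exp(out.log_scale)
        assert np.all(scaled[37:] == 0.0)
        assert scaled[36] > 0.0

    def test_branching_event_scales_by_lineage_count(self):
        p = ModelParams(0.44, 0.0, math.inf, 0.0, 0.0)
        s = _state(k=2)
        out = apply_branching(s, lineage_count=2, is_crown=False, p=p, opts=APPROX)
        assert out.k == 3
        assert out.q[0, 0, 0] * math.exp(out.log_scale) == pytest.approx(2 * 0.44)

    def test_branching_impossible_without_cladogenesis(self):
        p = ModelParams(0.0, 0.1, math.inf, 0.01, 0.0)
        ds = IslandDataset(5.0, 10, (CladeRecord("c", 1, "endemic_clade", 3.0, (1.0,)),))
        assert loglik_iw(ds, p) == -math.inf


class TestLoglik:
    def test_exceeding_cap_is_impossible(self, table1):
        p = ModelParams(0.4, 0.1, 60.0, 0.001, 0.0)
        assert loglik_iw(table1, p) == -math.inf  # 65 species > cap 60

    def test_analytic_toys_exact_mode(self, toys):
        for case in toys.values():
            if case.analytic is None:
                continue
            ll = loglik_iw(case.dataset, case.params, EXACT)
            assert ll == pytest.approx(case.analytic, abs=1e-8), case.name

    def test_empty_island_closed_form_both_modes(self, toys):
        case = toys["empty_pure_birth"]
        for opts in (EXACT, APPROX):
            assert loglik_iw(case.dataset, case.params, opts) == pytest.approx(-0.5, abs=1e-9)

    def test_single_colonist_first_colonization_convention(self):
        # with the approximate reset bookkeeping (observed colonization treated
        # as the founder's first), the singleton loglik is ln g0 - M g0 T,
        # independent of the colonization age
        M, g0, T = 10, 0.01, 5.0
        p = ModelParams(0.0, 0.0, math.inf, g0, 0.0)
        vals = []
        for a in (0.5, 2.0, 4.5):
            ds = IslandDataset(T, M, (CladeRecord("c", 1, "non_endemic_singleton", a),))
            vals.append(loglik_iw(ds, p, APPROX))
        expected = math.log(g0) - M * g0 * T
        for v in vals:
            assert v == pytest.approx(expected, abs=1e-6)

    def test_single_colonist_reset_erasure_depends_on_age(self):
        # exact bookkeeping: earlier foundings by the focal species are erased
        # by the reset rule, so only (0, a) is recolonization-free
        M, g0, T = 10, 0.01, 5.0
        p = ModelParams(0.0, 0.0, math.inf, g0, 0.0)
        for a in (1.0, 4.0):
            ds = IslandDataset(T, M, (CladeRecord("c", 1, "non_endemic_singleton", a),))
            expected = math.log(g0) - g0 * a - (M - 1) * g0 * T
            assert loglik_iw(ds, p, EXACT) == pytest.approx(expected, abs=1e-9)

    def test_tolerance_stability(self, toys):
        case = toys["endemic_pair_bd"]
        base = LikelihoodOptions(method="ivp", rtol=1e-8, atol=1e-40)
        tight = LikelihoodOptions(method="ivp", rtol=1e-9, atol=1e-41)
        a = loglik_iw(case.dataset, case.params, base)
        b = loglik_iw(case.dataset, case.params, tight)
        c = loglik_iw(case.dataset, case.params, EXACT)
        assert abs(a - b) < 1e-4
        assert abs(a - c) < 1e-4

    def test_truncation_insensitivity(self, toys):
        case = toys["endemic_pair_bd"]
        a = loglik_iw(case.dataset, case.params, replace(EXACT, n_max=24))
        b = loglik_iw(case.dataset, case.params, replace(EXACT, n_max=48))
        assert a == pytest.approx(b, abs=1e-8)

    def test_conditioning_on_colonization(self, toys):
        case = toys["single_colonist_pure_birth"]
        plain = loglik_iw(case.dataset, case.params, EXACT)
        cond = loglik_iw(case.dataset, case.params, replace(EXACT, conditioning="colonization"))
        ll_empty = -10 * 0.01 * 5.0
        assert cond == pytest.approx(plain - math.log1p(-math.exp(ll_empty)), abs=1e-8)


class TestOracle:
    def test_oracle_matches_closed_form_empty_island(self):
        # oracle degenerates to a frequency estimate when there are no ages
        M, g0, T = 10, 0.01, 5.0
        p = ModelParams(0.0, 0.0, math.inf, g0, 0.0)
        ds = IslandDataset(T, M, ())
        est, se = loglik_oracle_mc(ds, p, n_sims=50_000, bin_width=1.0, seed=4)
        assert abs(est - (-0.5)) <= 3 * se

    @pytest.mark.parametrize(
        "name",
        [
            "single_colonist_bd",
            "endemic_pair_bd",
            "endemic_triple_capped",
            "endemic_singleton_bd",
        ],
    )
    def test_oracle_agreement_spot_check(self, toys, name):
        """|loglik_iw - Monte-Carlo oracle| <= 3 SE on extinction-bearing toys.

        A quick spot check; the full toy suite at higher replication runs in
        the acceptance tests.
        """
        case = toys[name]
        est, se = loglik_oracle_mc(
            case.dataset, case.params, n_sims=40_000, bin_width=case.bin_width, seed=1000
        )
        ll = loglik_iw(case.dataset, case.params, EXACT)
        assert math.isfinite(est)
        assert abs(ll - est) <= 3 * se
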
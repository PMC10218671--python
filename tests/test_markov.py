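"""Markov cohort model: conservation, closed forms, tunnel dynamics."""

import numpy as np
import pytest

from tdabc_cea import config as cfgmod
from tdabc_cea.markov import (
    ModelConfig,
    StrategyParams,
    UtilitySet,
    build_schedule,
    mean_outcomes,
    monthly_discount_rate,
    run_cohort,
    run_strategy,
)


def _params(**over):
    base = dict(
        name="soc",
        p_healed=0.61,
        t_heal=3.0,
        p_recur=0.10,
        first_visit_cost=243.86,
        monthly_active_cost=406.11,
        healing_event_cost=127.95,
        p_reheal=0.61,
        t_reheal=3.0,
    )
    base.update(over)
    return StrategyParams(**base)


class TestSchedule:
    def test_no_recurrence_makes_healed_absorbing(self):
        sched = build_schedule(_params(p_recur=0.0), ModelConfig())
        assert sched.q_recur == 0.0
        trace = run_cohort(sched, UtilitySet(), _params(p_recur=0.0), ModelConfig())
        assert trace.occupancy[:, 2].max() == 0.0

    def test_full_immediate_healing(self):
        p = _params(p_healed=1.0, t_heal=1.0, p_recur=0.0)
        trace = run_strategy(p, UtilitySet(), ModelConfig())
        # whole cohort healed from cycle 2 onward
        assert np.allclose(trace.occupancy[2:, 1], 1.0)
        assert trace.occupancy[1, 0] == 1.0

    def test_soc_tunnel_leaves_039_active_at_cycle_4(self):
        trace = run_strategy(_params(p_recur=0.0), UtilitySet(), ModelConfig())
        assert trace.occupancy[4, 0] == pytest.approx(1 - 0.61, abs=1e-12)
        # still fully active through the tunnel
        assert np.allclose(trace.occupancy[1:4, 0], 1.0)

    def test_fractional_healing_time_splits_flow_with_exact_mean(self):
        p = _params(t_heal=2.4, p_recur=0.0, p_healed=0.5)
        sched = build_schedule(p, ModelConfig())
        flows = sched.heal_flow
        assert flows[2] == pytest.approx(0.5 * 0.6)
        assert flows[3] == pytest.approx(0.5 * 0.4)
        mean_t = (2 * flows[2] + 3 * flows[3]) / 0.5
        assert mean_t == pytest.approx(2.4)

    def test_calibrated_recurrence_hits_target(self):
        p = _params()
        sched = build_schedule(p, ModelConfig())
        from tdabc_cea.markov import _simulate

        assert _simulate(sched, sched.q_recur)[2] == pytest.approx(0.10, abs=1e-9)

    def test_unreachable_recurrence_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            build_schedule(_params(p_healed=0.01, p_recur=0.9), ModelConfig())


class TestCohortAccounting:
    def test_occupancy_conserved_and_bounded(self):
        for arm in ("stenting", "soc"):
            cfg = cfgmod.base_case()
            trace = run_strategy(
                cfgmod.make_strategy(cfg, arm),
                cfgmod.make_utilities(cfg),
                cfgmod.make_model_config(cfg),
            )
            occ = trace.occupancy[1:]
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert occ.min() >= -1e-15 and occ.max() <= 1 + 1e-15
            assert np.all(np.diff(trace.disc_qaly) >= 0)
            assert np.all(np.diff(trace.disc_cost) >= 0)

    def test_no_transition_closed_form_undiscounted(self):
        p = _params(p_healed=0.0, p_recur=0.0, first_visit_cost=0.0, healing_event_cost=0.0)
        cfg = ModelConfig(discount_annual=0.0)
        trace = run_strategy(p, UtilitySet(u_active=0.73), cfg)
        qalys, cost = mean_outcomes(trace)
        assert qalys == pytest.approx(36 * 0.73 / 12, abs=1e-12)  # 2.19
        assert cost == pytest.approx(36 * p.monthly_active_cost, abs=1e-9)

    def test_discounting_strictly_reduces_qalys(self):
        p = _params(p_healed=0.0, p_recur=0.0)
        q0 = run_strategy(p, UtilitySet(), ModelConfig(discount_annual=0.0)).qalys
        q3 = run_strategy(p, UtilitySet(), ModelConfig(discount_annual=0.03)).qalys
        assert q3 < q0

    def test_qalys_bounded_by_extreme_utilities(self):
        p = _params()
        trace = run_strategy(p, UtilitySet(), ModelConfig(discount_annual=0.0))
        assert 36 / 12 * 0.64 <= trace.qalys <= 36 / 12 * 1.0

    def test_all_costs_zero_yields_zero_cost(self):
        p = _params(first_visit_cost=0, monthly_active_cost=0, healing_event_cost=0)
        assert run_strategy(p, UtilitySet(), ModelConfig()).cost == 0.0

    def test_discount_conversion_consistency(self):
        """Compound monthly conversion makes a constant annual stream's
        discounted value independent of whether it accrues against annual or
        monthly compounding to high accuracy."""
        cfg = ModelConfig(discount_annual=0.03, discount_conversion="compound")
        d_m = monthly_discount_rate(cfg)
        assert (1 + d_m) ** 12 == pytest.approx(1.03, abs=1e-12)
        simple = monthly_discount_rate(ModelConfig(discount_conversion="simple"))
        assert abs(simple - d_m) / d_m < 2e-2

    def test_stenting_dominates_soc_on_qalys(self):
        cfg = cfgmod.base_case()
        mc = cfgmod.make_model_config(cfg)
        u = cfgmod.make_utilities(cfg)
        q_st = run_strategy(cfgmod.make_strategy(cfg, "stenting"), u, mc).qalys
        q_soc = run_strategy(cfgmod.make_strategy(cfg, "soc"), u, mc).qalys
        assert q_st > q_soc


class TestBaseCaseDiagnostics:
    """The reference transition structure is not published in full; the
    printed outcome means are tracked as diagnostic calibration targets."""

    def test_base_case_qalys_within_005(self, base_config):
        mc = cfgmod.make_model_config(base_config)
        u = cfgmod.make_utilities(base_config)
        q_st = run_strategy(cfgmod.make_strategy(base_config, "stenting"), u, mc).qalys
        q_soc = run_strategy(cfgmod.make_strategy(base_config, "soc"), u, mc).qalys
        assert q_st == pytest.approx(2.679, abs=0.05)
        assert q_soc == pytest.approx(2.498, abs=0.05)

    @pytest.mark.parametrize(
        "perspective,targets",
        [("hospital", (8731, 6871)), ("societal", (9204, 7581))],
    )
    def test_base_case_costs_within_5pct(self, base_config, perspective, targets):
        mc = cfgmod.make_model_config(base_config, perspective)
        u = cfgmod.make_utilities(base_config)
        c_st = run_strategy(cfgmod.make_strategy(base_config, "stenting", perspective), u, mc).cost
        c_soc = run_strategy(cfgmod.make_strategy(base_config, "soc", perspective), u, mc).cost
        assert c_st == pytest.approx(targets[0], rel=0.05)
        assert c_soc == pytest.approx(targets[1], rel=0.05)
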
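"""TDABC engine: step costing, roll-up conservation, episode arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdabc_cea.tdabc import (
    ActivityStep,
    EpisodeSpec,
    PhaseCost,
    episode_cost,
    expected_cost_with_reintervention,
    outpatient_reimbursement,
    personnel_cost,
    reimbursement_gap,
    roll_up,
    round_eur,
)


class TestPersonnelCost:
    def test_minutes_times_rate(self):
        step = ActivityStep("p", "visit", minutes=30, role="nurse")
        assert personnel_cost(step, {"nurse": 1.20}) == pytest.approx(36.00)

    def test_zero_duration_costs_nothing(self):
        step = ActivityStep("p", "noop", minutes=0, role="nurse")
        assert personnel_cost(step, {"nurse": 1.20}) == 0.0

    def test_empty_role_costs_nothing(self):
        step = ActivityStep("p", "consumable", minutes=65, role="")
        assert personnel_cost(step, {"nurse": 1.20}) == 0.0

    def test_unknown_role_raises_naming_it(self):
        step = ActivityStep("p", "visit", minutes=65, role="surgeon")
        with pytest.raises(KeyError, match="surgeon"):
            personnel_cost(step, {"nurse": 1.20})

    def test_frequency_scales_cost(self):
        step = ActivityStep("p", "debride", minutes=20, role="nurse", frequency=0.5)
        assert personnel_cost(step, {"nurse": 1.0}) == pytest.approx(10.0)


class TestRollUp:
    def test_empty_log_is_all_zero(self):
        bd = roll_up([], {}, ["a", "b"])
        assert bd.totals["total"] == 0.0
        assert (bd.per_phase.to_numpy() == 0).all()

    def test_phase_outside_declared_order_raises(self):
        with pytest.raises(ValueError, match="outside the declared order"):
            roll_up([ActivityStep("zz", "s")], {}, ["a"])

    def test_conservation_per_phase_and_total(self, stenting_breakdown):
        bd = stenting_breakdown
        recomputed = bd.per_phase["personnel"] + bd.per_phase["goods"] + bd.per_phase["patient"]
        assert (bd.per_phase["total"] - recomputed).abs().max() < 1e-9
        assert bd.totals["total"] == pytest.approx(bd.per_phase["total"].sum())

    def test_row_order_invariance(self):
        rates = {"r": 1.5}
        steps = [
            ActivityStep("a", "s1", minutes=10, role="r", goods_cost=5),
            ActivityStep("b", "s2", minutes=20, role="r", patient_cost=3),
            ActivityStep("a", "s3", minutes=7, role="r"),
        ]
        fwd = roll_up(steps, rates, ["a", "b"])
        rev = roll_up(steps[::-1], rates, ["a", "b"])
        assert fwd.per_phase.equals(rev.per_phase)

    @settings(max_examples=50, derandomize=True)
    @given(
        minutes=st.floats(0, 500),
        goods=st.floats(0, 1000),
        split=st.floats(0.01, 0.99),
    )
    def test_splitting_a_step_preserves_totals(self, minutes, goods, split):
        """A step split into two with the same role and summed minutes/costs
        rolls up identically."""
        rates = {"r": 0.8}
        whole = [ActivityStep("a", "s", minutes=minutes, role="r", goods_cost=goods)]
        parts = [
            ActivityStep("a", "s1", minutes=minutes * split, role="r", goods_cost=goods * split),
            ActivityStep("a", "s2", minutes=minutes * (1 - split), role="r", goods_cost=goods * (1 - split)),
        ]
        a = roll_up(whole, rates, ["a"]).totals
        b = roll_up(parts, rates, ["a"]).totals
        assert a["total"] == pytest.approx(b["total"], abs=1e-9)
        assert a["minutes"] == pytest.approx(b["minutes"], abs=1e-9)


class TestReintervention:
    def test_published_adjustment(self):
        assert expected_cost_with_reintervention(5081.99, 0.03) == pytest.approx(5234.45)

    def test_identity_at_zero_and_doubling_at_one(self):
        assert expected_cost_with_reintervention(5081.99, 0.0) == 5081.99
        assert expected_cost_with_reintervention(1000.0, 1.0) == 2000.0

    @settings(max_examples=50, derandomize=True)
    @given(base=st.floats(0, 1e6), p1=st.floats(0, 1), p2=st.floats(0, 1))
    def test_linear_in_base_and_monotone_in_p(self, base, p1, p2):
        assert expected_cost_with_reintervention(2 * base, p1) == pytest.approx(
            2 * expected_cost_with_reintervention(base, p1)
        )
        lo, hi = sorted([p1, p2])
        assert expected_cost_with_reintervention(base, lo) <= expected_cost_with_reintervention(base, hi)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_probability_domain(self, p):
        with pytest.raises(ValueError):
            expected_cost_with_reintervention(100.0, p)


class TestEpisodeCost:
    def test_three_month_episode_payer_split(self, soc_episode):
        total, hospital, patient = episode_cost(soc_episode)
        # printed whole-EUR figures: 1892 total, 302 patient (16%), 1590 hospital
        assert round_eur(total, 0) == 1892
        assert round_eur(patient, 0) == 302
        assert round_eur(hospital, 0) == 1590
        assert total == pytest.approx(1891.80, abs=0.02)
        assert patient == pytest.approx(301.66, abs=0.001)
        assert patient / total == pytest.approx(0.16, abs=0.005)

    def test_zero_months_drops_monthly_block(self, soc_episode):
        spec = EpisodeSpec(soc_episode.first_visit, soc_episode.monthly, soc_episode.final_phase, 0)
        total, _, _ = episode_cost(spec)
        assert total == pytest.approx(soc_episode.first_visit.total + soc_episode.final_phase.total)

    def test_affine_in_months_with_monthly_slope(self, soc_episode):
        totals = []
        for m in range(5):
            spec = EpisodeSpec(soc_episode.first_visit, soc_episode.monthly, soc_episode.final_phase, m)
            totals.append(episode_cost(spec).total)
        diffs = [b - a for a, b in zip(totals, totals[1:])]
        assert all(d == pytest.approx(soc_episode.monthly.total) for d in diffs)

    def test_no_patient_costs_means_hospital_pays_all(self):
        row = PhaseCost(minutes=10, personnel=50, goods=20, patient=0)
        total, hospital, patient = episode_cost(EpisodeSpec(row, row, row, 2))
        assert patient == 0
        assert hospital == pytest.approx(total)

    def test_negative_months_rejected(self, soc_episode):
        with pytest.raises(ValueError):
            EpisodeSpec(soc_episode.first_visit, soc_episode.monthly, soc_episode.final_phase, -1)


class TestReimbursement:
    @pytest.mark.parametrize(
        "real,tariff,gap",
        [(5082, 4742, 340), (1590, 1132, 458), (100, 100, 0)],
    )
    def test_gap(self, real, tariff, gap):
        assert reimbursement_gap(real, tariff) == pytest.approx(gap)

    @pytest.mark.parametrize(
        "n,visit,med,expected",
        [(12, 22, 72.33, 1131.96), (0, 22, 72.33, 0.0), (12, 22, 0, 264.0)],
    )
    def test_outpatient_tariff(self, n, visit, med, expected):
        assert outpatient_reimbursement(n, visit, med) == pytest.approx(expected)


class TestRounding:
    def test_half_up_at_the_cent(self):
        assert round_eur(0.005) == 0.01
        assert round_eur(1.004999) == 1.0
        assert round_eur(2.675) == 2.68  # would be 2.67 under float banker's rounding
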
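"""Model core: payoff table, expected payoffs, rates, switching functions,
thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pppgame import (
    GameParameters,
    ParameterError,
    PureOutcome,
    StrategyState,
    build_payoff_table,
    critical_thresholds,
    expected_government_payoffs,
    expected_private_payoffs,
    expected_public_payoffs,
    replicator_rates,
    replicator_rates_oracle,
    switching_functions,
    switching_values,
)
from conftest import random_params, random_state

CORNERS = [StrategyState(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)]


class TestParameterValidation:
    def test_rejects_cheaper_high_quality(self, baseline):
        with pytest.raises(ParameterError, match="CH > CL"):
            baseline.replace(CH=20.0)

    @pytest.mark.parametrize("field,bad,msg", [
        ("alpha1", 5.0, "alpha1 > alpha2"),
        ("beta1", 1.0, "beta1 > beta2"),
        ("Ws", -1.0, ">= 0"),
    ])
    def test_error_names_the_violated_inequality(self, baseline, field, bad, msg):
        with pytest.raises(ParameterError, match=msg):
            baseline.replace(**{field: bad})

    def test_state_components_bounded(self):
        with pytest.raises(ValueError):
            StrategyState(1.2, 0.5, 0.5)

    def test_round_trip_through_yaml_and_json(self, baseline, tmp_path):
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            baseline.to_file(path)
            assert GameParameters.from_file(path) == baseline


class TestPayoffTable:
    def test_cells_match_reference_combinations(self, baseline):
        p = baseline
        table = build_payoff_table(p)
        # violation, no supervision, no participation
        assert tuple(table[PureOutcome(False, False, False)]) == (
            p.Mi - p.CL, p.Fi, -p.R1)
        # no violation, supervision, participation
        assert tuple(table[PureOutcome(True, True, True)]) == (
            p.Mi + p.We + p.alpha1 - p.CH,
            p.Fi + p.Rg + p.beta1 - p.Cg - p.Rp,
            p.Rp - p.Cp)
        # baseline: no violation, supervision, no participation
        assert tuple(table[PureOutcome(True, True, False)]) == (
            p.Mi - 40.0, p.Fi - 10.0, 0.0)

    def test_reputation_only_under_participation(self, baseline):
        """alpha*/beta* shifts must not touch non-participation cells."""
        bumped = baseline.replace(alpha1=baseline.alpha1 + 7.0,
                                  beta1=baseline.beta1 + 7.0)
        t0, t1 = build_payoff_table(baseline), build_payoff_table(bumped)
        for outcome in PureOutcome.all():
            if not outcome.public_participates:
                assert t0[outcome] == t1[outcome]

    def test_fine_moves_only_in_supervised_violation_cells(self, baseline):
        bumped = baseline.replace(Ws=baseline.Ws + 11.0)
        t0, t1 = build_payoff_table(baseline), build_payoff_table(bumped)
        for outcome in PureOutcome.all():
            changed = (not outcome.private_no_violation
                       and outcome.government_supervises)
            if changed:
                assert t1[outcome].private == t0[outcome].private - 11.0
                assert t1[outcome].government == t0[outcome].government + 11.0
            else:
                assert t0[outcome] == t1[outcome]

    def test_exposure_penalty_only_in_unsupervised_reported_violation(self, baseline):
        bumped = baseline.replace(Fg=baseline.Fg + 13.0)
        t0, t1 = build_payoff_table(baseline), build_payoff_table(bumped)
        hit = PureOutcome(False, False, True)
        for outcome in PureOutcome.all():
            if outcome == hit:
                assert t1[outcome].government == t0[outcome].government - 13.0
            else:
                assert t0[outcome] == t1[outcome]

    def test_invalid_params_rejected(self, baseline):
        p = baseline.replace()
        object.__setattr__(p, "CL", 90.0)  # sidestep constructor validation
        with pytest.raises(ParameterError):
            build_payoff_table(p)


class TestExpectedPayoffs:
    def test_private_collapses_at_full_monitoring(self, baseline):
        p = baseline
        for y in (0.0, 0.3, 1.0):
            y11, _, _ = expected_private_payoffs(p, StrategyState(0.4, y, 1.0))
            assert y11 == pytest.approx(p.Mi + p.We + p.alpha1 - p.CH)
        _, y12, _ = expected_private_payoffs(p, StrategyState(0.4, 0.0, 0.0))
        assert y12 == pytest.approx(p.Mi - p.CL)

    def test_government_corners(self, baseline):
        p = baseline
        y21, _, _ = expected_government_payoffs(p, StrategyState(1.0, 0.5, 0.0))
        assert y21 == pytest.approx(p.Fi + p.Rg - p.Cg)
        _, y22, _ = expected_government_payoffs(p, StrategyState(1.0, 0.5, 1.0))
        assert y22 == pytest.approx(p.Fi + p.beta2 - p.Rp)

    def test_public_corners(self, baseline):
        p = baseline
        y31, _, _ = expected_public_payoffs(p, StrategyState(1.0, 0.5, 0.5))
        assert y31 == pytest.approx(p.Rp - p.Cp)
        _, y32, _ = expected_public_payoffs(p, StrategyState(0.0, 0.5, 0.5))
        assert y32 == pytest.approx(-p.R1)

    def test_baseline_payoff_advantages(self, baseline):
        mid = StrategyState(0.5, 0.5, 0.5)
        y11, y12, _ = expected_private_payoffs(baseline, mid)
        assert y11 - y12 == pytest.approx(35.0)
        y21, y22, _ = expected_government_payoffs(baseline, mid)
        assert y21 - y22 == pytest.approx(67.5)
        y31, y32, _ = expected_public_payoffs(baseline, mid)
        assert y31 - y32 == pytest.approx(155.0)

    def test_mean_is_share_weighted(self, baseline, rng):
        s = random_state(rng)
        y11, y12, ybar = expected_private_payoffs(baseline, s)
        assert ybar == pytest.approx(s.x * y11 + (1 - s.x) * y12)


class TestReplicatorRates:
    def test_corners_are_fixed_points(self, baseline):
        for corner in CORNERS:
            assert tuple(replicator_rates(baseline, corner)) == (0.0, 0.0, 0.0)
            assert tuple(replicator_rates_oracle(baseline, corner)) == (
                0.0, 0.0, 0.0)

    def test_baseline_midpoint_rates(self, baseline):
        mid = StrategyState(0.5, 0.5, 0.5)
        assert tuple(replicator_rates(baseline, mid)) == pytest.approx(
            (8.75, 16.875, 38.75))
        assert tuple(replicator_rates_oracle(baseline, mid)) == pytest.approx(
            (8.75, 16.875, 38.75))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_closed_form_agrees_with_table_oracle(self, seed):
        """The closed-form algebra is consistent with the payoff table."""
        params = random_params(seed)
        rng = np.random.default_rng(seed + 1)
        state = random_state(rng)
        closed = np.array(list(replicator_rates(params, state)))
        oracle = np.array(list(replicator_rates_oracle(params, state)))
        assert np.max(np.abs(closed - oracle)) < 1e-9

    def test_nuisance_parameters_cancel_bitwise(self, baseline, rng):
        """Mi, Fi, R1 shift whole payoff rows equally and must not move any
        rate."""
        perturbed = baseline.replace(Mi=baseline.Mi * 1.5,
                                     Fi=baseline.Fi * 0.5,
                                     R1=baseline.R1 * 1.5)
        for _ in range(20):
            s = random_state(rng)
            assert tuple(replicator_rates(baseline, s)) == tuple(
                replicator_rates(perturbed, s))


class TestSwitchingFunctions:
    def test_reference_values(self, baseline):
        g, _, _ = switching_functions(baseline, StrategyState(0.3, 0.5, 0.5))
        assert g == pytest.approx(-35.0)
        _, _, d = switching_functions(baseline, StrategyState(1.0, 0.2, 0.7))
        assert d == pytest.approx(-5.0)
        _, j, _ = switching_functions(baseline, StrategyState(0.0, 0.5, 0.0))
        assert j == pytest.approx(-70.0)

    def test_sign_contract_with_rates(self, baseline, rng):
        """Negative switching function => the share drifts upward inside
        (0,1)."""
        for _ in range(50):
            s = StrategyState(*rng.uniform(0.05, 0.95, size=3))
            g, j, d = switching_functions(baseline, s)
            r = replicator_rates(baseline, s)
            for bracket, rate in zip((g, j, d), r):
                if bracket < 0:
                    assert rate > 0
                elif bracket > 0:
                    assert rate < 0

    def test_monotone_in_opponent_share(self, baseline):
        """G non-increasing in y, J non-increasing in z, D non-decreasing
        in x."""
        grid = np.linspace(0.0, 1.0, 11)
        g = [switching_functions(baseline, StrategyState(0.5, v, 0.5))[0]
             for v in grid]
        j = [switching_functions(baseline, StrategyState(0.5, 0.5, v))[1]
             for v in grid]
        d = [switching_functions(baseline, StrategyState(v, 0.5, 0.5))[2]
             for v in grid]
        assert all(a >= b for a, b in zip(g, g[1:]))
        assert all(a >= b for a, b in zip(j, j[1:]))
        assert all(a <= b for a, b in zip(d, d[1:]))


class TestCriticalThresholds:
    def test_baseline_values(self, baseline):
        th = critical_thresholds(baseline, StrategyState(1.0, 0.5, 0.0))
        assert th.y_star.value == pytest.approx(0.125)
        assert th.y_star.in_range
        assert th.z_star.value == pytest.approx(0.4)
        assert th.x_star.value == pytest.approx(305.0 / 300.0)
        assert not th.x_star.in_range  # D < 0 over the whole feasible range

    def test_thresholds_are_roots_of_switching_functions(self, rng):
        """Finite thresholds (in range or not) are exact roots of G, J, D."""
        for seed in range(200):
            params = random_params(seed)
            s = random_state(rng)
            th = critical_thresholds(params, s)
            if th.y_star.finite:
                g, _, _ = switching_values(params, s.x, th.y_star.value, s.z)
                assert abs(g) < 1e-12
            if th.z_star.finite:
                _, j, _ = switching_values(params, s.x, s.y, th.z_star.value)
                assert abs(j) < 1e-12
            if th.x_star.finite:
                _, _, d = switching_values(params, th.x_star.value, s.y, s.z)
                assert abs(d) < 1e-12

    def test_zero_denominator_flagged_not_raised(self, baseline):
        # x = 1 kills the Fg term; beta1 == beta2 would kill the rest, but
        # that is structurally forbidden, so engineer P = 0 for x* instead.
        p = baseline.replace(P=0.0)
        th = critical_thresholds(p, StrategyState(0.5, 0.5, 0.5))
        assert not th.x_star.finite
        assert math.isnan(th.x_star.value)
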
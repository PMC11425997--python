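"""Distributional analysis: group net health benefit, Atkinson welfare, EDEH.

The Atkinson index at the UK inequality-aversion value (eps = 10.95) is
checked against an arbitrary-precision evaluation of the defining formula;
the full six-step run is checked against an independent step-by-step
recomputation.
"""
import math
import warnings

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equity_synth.core_types import DceaScenario, Direction, SubgroupDistribution
from equity_synth.dcea import (
    allocate_population,
    atkinson_index,
    edeh,
    group_nhb,
    post_intervention_qale,
    run_dcea,
    total_nhb,
)
from equity_synth.synth_data import default_uk_distribution, generate_distribution

UK = default_uk_distribution()


def _scenario(dqaly=16.9, dcost=335_088.0, wtp=20_000.0, n=10_000.0, dist=UK, eps=10.95):
    return DceaScenario(
        study_id="test",
        delta_qaly_pp=dqaly,
        delta_cost_pp=dcost,
        wtp_threshold=wtp,
        n_total=n,
        distribution=dist,
        epsilon=eps,
    )


def _equal_dist(n=5, qale=70.0):
    share = 1.0 / n
    return SubgroupDistribution(
        labels=tuple(f"g{i}" for i in range(n)),
        qale=(qale,) * n,
        opp_share=(share,) * n,
        pop_share=(share,) * n,
    )


def mp_atkinson(h, eps):
    with mp.workdps(60):
        h = [mp.mpf(repr(x)) for x in h]
        hbar = mp.fsum(h) / len(h)
        e = mp.mpf(repr(eps))
        if e == 1:
            gm = mp.exp(mp.fsum(mp.log(x) for x in h) / len(h))
            return float(1 - gm / hbar)
        p = 1 - e
        return float(1 - (mp.fsum((x / hbar) ** p for x in h) / len(h)) ** (1 / p))


class TestAllocatePopulation:
    def test_population_splits_by_share(self):
        assert np.allclose(allocate_population(10_000, UK), 2_000.0)
        assert np.allclose(allocate_population(6_393, UK), 1_278.6)

    def test_degenerate_share_vector(self):
        dist = SubgroupDistribution(
            labels=("a", "b"), qale=(70.0, 70.0), opp_share=(0.5, 0.5), pop_share=(1.0, 0.0)
        )
        assert allocate_population(1, dist).tolist() == [1.0, 0.0]

    def test_rejects_nonpositive_population(self):
        with pytest.raises(ValueError):
            allocate_population(0, UK)


class TestGroupNhb:
    def test_most_deprived_group_bears_net_loss(self):
        # largest opportunity-cost share can push a group negative
        nhb = group_nhb(_scenario())
        assert nhb[0] == pytest.approx(16.9 * 2000 - 10_000 * 335_088 * 0.26 / 20_000, rel=1e-12)
        assert nhb[0] == pytest.approx(-9_761.44, abs=0.01)

    def test_zero_cost_leaves_pure_gain(self):
        nhb = group_nhb(_scenario(dcost=0.0))
        assert np.allclose(nhb, 16.9 * allocate_population(10_000, UK))

    def test_zero_opportunity_share_group_keeps_full_gain(self):
        dist = SubgroupDistribution(
            labels=("a", "b"), qale=(70.0, 70.0), opp_share=(1.0, 0.0), pop_share=(0.5, 0.5)
        )
        nhb = group_nhb(_scenario(dist=dist, n=100.0, dqaly=1.0, dcost=10.0))
        assert nhb[1] == pytest.approx(1.0 * 50.0)


class TestTotalNhb:
    @pytest.mark.parametrize(
        "dqaly,dcost,wtp,n,expected",
        [
            (16.9, 335_088.0, 20_000.0, 10_000.0, 1_456.0),  # UK universal+reverse-cascade
            (0.49, 5_989.0, 150_000.0, 1_000.0, 450.07),  # US cascade
        ],
    )
    def test_published_scenarios(self, dqaly, dcost, wtp, n, expected):
        assert total_nhb(_scenario(dqaly, dcost, wtp, n)) == pytest.approx(expected, abs=0.01)

    def test_break_even_is_zero(self):
        assert total_nhb(_scenario(dqaly=2.0, dcost=40_000.0, wtp=20_000.0)) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        dqaly=st.floats(min_value=0.0, max_value=50, allow_nan=False),
        dcost=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        wtp=st.floats(min_value=1e3, max_value=2e5, allow_nan=False),
        n=st.floats(min_value=1, max_value=1e6, allow_nan=False),
    )
    def test_conservation_sum_of_groups_equals_closed_form(self, dqaly, dcost, wtp, n):
        s = _scenario(dqaly, dcost, wtp, n)
        assert sum(group_nhb(s)) == pytest.approx(total_nhb(s), rel=1e-9, abs=1e-9)


class TestAtkinson:
    def test_equality_gives_zero_for_any_aversion(self):
        for eps in (0.0, 1.0, 10.95):
            assert atkinson_index([70.0] * 5, eps) == pytest.approx(0.0, abs=1e-12)

    def test_zero_aversion_gives_zero_for_any_distribution(self):
        assert atkinson_index(UK.qale, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_uk_quintile_gradient_matches_high_precision_formula(self):
        # frozen regression constant from the arbitrary-precision oracle
        a = atkinson_index(UK.qale, 10.95)
        assert a == pytest.approx(0.019366776161, abs=1e-11)
        assert a == pytest.approx(mp_atkinson(UK.qale, 10.95), abs=1e-13)

    def test_rejects_nonpositive_health(self):
        with pytest.raises(ValueError):
            atkinson_index([70.0, 0.0], 2.0)

    def test_nondecreasing_in_aversion(self):
        vals = [atkinson_index(UK.qale, e) for e in (0.0, 0.5, 1.0, 2.0, 5.0, 10.95, 20.0)]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))

    @settings(max_examples=50, deadline=None)
    @given(
        h=st.lists(st.floats(min_value=1.0, max_value=100.0), min_size=3, max_size=8),
        eps=st.floats(min_value=0.1, max_value=15.0),
        frac=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_pigou_dalton_transfer_does_not_increase_inequality(self, h, eps, frac):
        """A mean-preserving transfer from a richer to a poorer group
        cannot raise the index."""
        h = sorted(h)
        if h[-1] - h[0] < 1e-6:
            return
        t = frac * (h[-1] - h[0]) / 2
        before = atkinson_index(h, eps)
        h2 = list(h)
        h2[0] += t
        h2[-1] -= t
        assert atkinson_index(h2, eps) <= before + 1e-10

    def test_unit_aversion_continuity(self):
        limit = atkinson_index(UK.qale, 1.0)
        assert abs(atkinson_index(UK.qale, 1.0 + 1e-6) - limit) < 1e-6
        assert abs(atkinson_index(UK.qale, 1.0 - 1e-6) - limit) < 1e-6
        assert limit == pytest.approx(mp_atkinson(UK.qale, 1.0), abs=1e-13)

    def test_population_weighted_variant(self):
        h = [60.0, 80.0]
        a_unw = atkinson_index(h, 2.0)
        a_w = atkinson_index(h, 2.0, weights=[0.9, 0.1])
        assert a_w != pytest.approx(a_unw)


class TestEdeh:
    def test_equal_distribution_equals_total_health(self):
        assert edeh([70.0] * 5, 10.95, 100.0) == pytest.approx(7_000.0)

    def test_never_exceeds_total_health(self):
        h = list(UK.qale)
        assert edeh(h, 10.95, 1.0) < np.mean(h)
        assert edeh(h, 10.95, 500.0) <= 500.0 * np.mean(h)

    def test_matches_high_precision_formula(self):
        expected = 6393 * (1 - mp_atkinson(UK.qale, 10.95)) * np.mean(UK.qale)
        assert edeh(UK.qale, 10.95, 6393) == pytest.approx(expected, rel=1e-12)


class TestPostInterventionQale:
    def test_zero_benefit_is_identity(self):
        out = post_intervention_qale(UK.qale, [0.0] * 5, [100.0] * 5)
        assert np.allclose(out, UK.qale)

    def test_uniform_per_person_gain_shifts_everyone(self):
        out = post_intervention_qale([60.0, 70.0], [5.0, 5.0], [10.0, 10.0])
        assert np.allclose(out, [60.5, 70.5])

    def test_group_level_loss_divides_by_population(self):
        out = post_intervention_qale([63.21], [-9_761.44], [2_000.0])
        assert out[0] == pytest.approx(63.21 - 4.88072, abs=1e-4)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            post_intervention_qale([70.0], [1.0], [0.0])


class TestRunDcea:
    def test_symmetric_scenario_is_equity_neutral(self):
        s = _scenario(dqaly=1.0, dcost=5_000.0, wtp=20_000.0, n=1_000.0, dist=_equal_dist())
        res = run_dcea(s)
        assert res.atkinson_pre == pytest.approx(0.0, abs=1e-12)
        assert res.atkinson_post == pytest.approx(0.0, abs=1e-12)
        assert res.equity_impact == pytest.approx(0.0, abs=1e-6)
        assert res.direction is Direction.neutral

    def test_australian_cascade_reduces_inequality(self, table4_scenarios):
        s = next(x for x in table4_scenarios if x.study_id == "Ademi-AUS")
        res = run_dcea(s)
        assert res.total_nhb == pytest.approx(1_110.5, abs=0.01)
        assert res.direction is Direction.reduces_inequality

    def test_matches_step_by_step_recomputation(self):
        """Independent spreadsheet-style recomputation of all six steps."""
        dist = generate_distribution((60.0, 80.0), (0.05, 0.55), 5)  # cost on the affluent
        s = _scenario(dqaly=0.8, dcost=9_000.0, wtp=25_000.0, n=5_000.0, dist=dist)
        res = run_dcea(s)

        n_j = [0.2 * 5_000.0] * 5
        nhb = [0.8 * nj - 5_000.0 * 9_000.0 * dj / 25_000.0 for nj, dj in zip(n_j, dist.opp_share)]
        post = [h + b / nj for h, b, nj in zip(dist.qale, nhb, n_j)]
        a_pre, a_post = mp_atkinson(dist.qale, 10.95), mp_atkinson(post, 10.95)
        e_pre = 5_000.0 * (1 - a_pre) * sum(dist.qale) / 5
        e_post = 5_000.0 * (1 - a_post) * sum(post) / 5
        expected_equity = (e_post - e_pre) - sum(nhb)

        assert np.allclose(res.group_nhb, nhb, rtol=1e-12)
        assert res.equity_impact == pytest.approx(expected_equity, abs=1e-6)
        assert res.direction is Direction.reduces_inequality

    def test_relabeling_groups_leaves_equity_invariant(self):
        dist = default_uk_distribution()
        perm = [4, 2, 0, 1, 3]
        shuffled = SubgroupDistribution(
            labels=tuple(dist.labels[i] for i in perm),
            qale=tuple(dist.qale[i] for i in perm),
            opp_share=tuple(dist.opp_share[i] for i in perm),
            pop_share=tuple(dist.pop_share[i] for i in perm),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_dcea(_scenario())
            b = run_dcea(_scenario(dist=shuffled))
        assert b.equity_impact == pytest.approx(a.equity_impact, rel=1e-9)

    def test_negative_group_benefit_warns(self):
        with pytest.warns(UserWarning, match="below baseline"):
            run_dcea(_scenario())  # most-deprived group loses on net

    def test_nonpositive_post_health_aborts(self):
        s = _scenario(dqaly=0.0, dcost=1e9, wtp=1_000.0, n=10.0)
        with pytest.raises(ValueError, match="non-positive"):
            run_dcea(s)

    def test_direction_follows_sign_of_equity_impact(self, table4_scenarios):
        for s in table4_scenarios:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_dcea(s)
            if res.equity_impact > 1e-9:
                assert res.direction is Direction.reduces_inequality
            elif res.equity_impact < -1e-9:
                assert res.direction is Direction.increases_inequality
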
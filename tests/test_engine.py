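"""Monte Carlo engine: intake arithmetic, conservation, exceedance,
attribution, route shares and the sample-size stability rule."""

import math

import numpy as np
import pytest

import goitrisk as gr
from goitrisk.distributions import TruncatedLognormal
from goitrisk.engine import ADRISampleSet
from goitrisk.errors import (
    EmptyInputError,
    NonConvergenceError,
    UndefinedShareError,
)
from goitrisk.scenario import AgeGroup, Scenario, default_agents

GSD1 = 1 + 1e-9  # effectively point-mass components


def point_scenario(c_pw=1.0, c_nf=15_000.0, ef_w=0.05, ef_f=0.02,
                   c_pf=0.0, c_nw=0.0, c_tf=0.0, **kw):
    """All-degenerate-spread scenario so intakes are exact products."""
    def dist(m):
        return TruncatedLognormal(m, GSD1, 3) if m > 0 else TruncatedLognormal(0.0)

    group = AgeGroup("adults", TruncatedLognormal(ef_w, GSD1, 3),
                     TruncatedLognormal(ef_f, GSD1, 3))
    return Scenario(
        agents=default_agents(), age_groups=(group,),
        conc_water={"perchlorate": dist(c_pw), "nitrate": dist(c_nw),
                    "thiocyanate": TruncatedLognormal(0.0)},
        conc_food={"perchlorate": dist(c_pf), "nitrate": dist(c_nf),
                   "thiocyanate": dist(c_tf)}, **kw)


class TestSimulate:
    def test_degenerate_pec_arithmetic_serum(self):
        # 1 ug/L x 0.05 L/kg-day + 15,000 ug/kg x 0.02 kg/kg-day / 150
        s = gr.simulate(point_scenario(), "adults", "serum", 100, seed=0)
        assert np.allclose(s.total, 0.05 / 1 + 300 / 150, rtol=1e-6)

    def test_degenerate_pec_arithmetic_halflife(self):
        s = gr.simulate(point_scenario(), "adults", "halflife", 100, seed=0)
        assert np.allclose(s.total, 0.05 + 300 / 240, rtol=1e-6)

    def test_endogenous_nitrate_multiplier(self):
        s = gr.simulate(point_scenario(endo_nitrate_coeff=0.5), "adults",
                        "serum", 50, seed=0)
        assert np.allclose(s.total, 0.05 + 1.5 * 300 / 150, rtol=1e-6)

    def test_all_zero_concentrations(self):
        s = gr.simulate(point_scenario(c_pw=0, c_nf=0), "adults", "serum",
                        50, seed=0)
        assert np.all(s.total == 0)

    def test_conservation_total_is_componentwise_sum(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 5000, seed=3)
        np.testing.assert_array_equal(s.total, sum(s.components.values()))
        assert all(np.all(v >= 0) for v in s.components.values())

    def test_ef_draws_shared_across_agents(self, synthetic):
        """One person, one intake rate: every agent's water component uses
        the same water-EF draw (and likewise for food)."""
        s = gr.simulate(synthetic, ">21 years", "serum", 2000, seed=5)
        for agent, divisor in [("perchlorate", 1.0), ("nitrate", 150.0)]:
            implied_ef = (s.components[f"{agent}_water"] * divisor
                          / s.conc_draws[f"{agent}_water"])
            np.testing.assert_allclose(implied_ef, s.ef_draws["water"],
                                       rtol=1e-12)

    def test_basis_switch_rescales_componentwise(self, synthetic):
        """Identical draws; only the potency divisors differ."""
        serum = gr.simulate(synthetic, "2-3 years", "serum", 2000, seed=7)
        halflife = gr.simulate(synthetic, "2-3 years", "halflife", 2000, seed=7)
        scale = {"perchlorate": 1.0, "nitrate": 150 / 240, "thiocyanate": 8.8 / 0.5}
        for name in serum.components:
            agent = name.rsplit("_", 1)[0]
            np.testing.assert_allclose(
                serum.components[name] * scale[agent],
                halflife.components[name], rtol=1e-12)

    def test_reproducible_and_order_independent_streams(self, synthetic):
        a = gr.simulate(synthetic, "2-3 years", "serum", 500, seed=9)
        b = gr.simulate(synthetic, "2-3 years", "serum", 500, seed=9)
        np.testing.assert_array_equal(a.total, b.total)

    def test_unknown_group_and_basis(self, synthetic):
        with pytest.raises(KeyError):
            gr.simulate(synthetic, "toddlers", "serum", 10, seed=0)
        with pytest.raises(KeyError):
            gr.simulate(synthetic, "2-3 years", "plasma", 10, seed=0)


class TestPercentileTable:
    def test_median_pass_through(self):
        s = gr.simulate(point_scenario(c_nf=0), "adults", "serum", 10_000, seed=0)
        table = gr.percentile_table(s, [50])
        assert table[50] == pytest.approx(0.05, rel=1e-6)

    def test_inclusive_linear_interpolation(self):
        s = ADRISampleSet("g", "serum", 100, {}, {}, {},
                          np.arange(1, 101, dtype=float), 0)
        assert gr.percentile_table(s, [50])[50] == pytest.approx(50.5)

    def test_monotone_in_percentile(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 20_000, seed=1)
        table = gr.percentile_table(s)
        vals = [table[p] for p in sorted(table)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_empty_input(self):
        s = ADRISampleSet("g", "serum", 0, {}, {}, {}, np.array([]), 0)
        with pytest.raises(EmptyInputError):
            gr.percentile_table(s)


class TestExceedance:
    def test_rfd_above_support_gives_zero(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 10_000, seed=1)
        assert gr.exceedance_fraction(s, s.total.max() * 1.01) == 0.0

    def test_rfd_at_median_gives_half(self):
        dist = TruncatedLognormal(12.0, 1.5, 3)
        group = AgeGroup("g", TruncatedLognormal(1.0, GSD1, 3),
                         TruncatedLognormal(1.0, GSD1, 3))
        scen = Scenario(agents=default_agents(), age_groups=(group,),
                        conc_water={"perchlorate": dist,
                                    "nitrate": TruncatedLognormal(0.0),
                                    "thiocyanate": TruncatedLognormal(0.0)},
                        conc_food={a: TruncatedLognormal(0.0)
                                   for a in ("perchlorate", "nitrate",
                                             "thiocyanate")})
        s = gr.simulate(scen, "g", "serum", 50_000, seed=2)
        assert gr.exceedance_fraction(s, 12.0) == pytest.approx(50.0, abs=1.0)

    def test_one_component_tail_matches_closed_form(self):
        """Single-pathway exceedance equals the truncated-lognormal tail
        probability within 3 Monte Carlo standard errors."""
        dist = TruncatedLognormal(10.0, 1.5, 3)
        group = AgeGroup("g", TruncatedLognormal(1.0, GSD1, 3),
                         TruncatedLognormal(1.0, GSD1, 3))
        scen = Scenario(agents=default_agents(), age_groups=(group,),
                        conc_water={"perchlorate": dist,
                                    "nitrate": TruncatedLognormal(0.0),
                                    "thiocyanate": TruncatedLognormal(0.0)},
                        conc_food={a: TruncatedLognormal(0.0)
                                   for a in ("perchlorate", "nitrate",
                                             "thiocyanate")})
        n = 50_000
        s = gr.simulate(scen, "g", "serum", n, seed=3)
        for rfd in (12.0, 18.0, 25.0):
            p = dist.sf(rfd)
            se = math.sqrt(p * (1 - p) / n)
            assert gr.exceedance_fraction(s, rfd) / 100 == pytest.approx(
                p, abs=3 * se)

    def test_monotone_nonincreasing_in_rfd(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 20_000, seed=4)
        excs = [gr.exceedance_fraction(s, r) for r in np.linspace(1, 40, 25)]
        assert all(b <= a for a, b in zip(excs, excs[1:]))

    def test_approach_ordering(self, synthetic):
        """RfD ordering 29.5 > 14.5 > 13.5 implies exceedance ordering
        A4 <= A4b <= A3."""
        s = gr.simulate(synthetic, "2-3 years", "serum", 20_000, seed=4)
        a3, a4, a4b = (gr.exceedance_fraction(s, r) for r in (13.5, 29.5, 14.5))
        assert a4 <= a4b <= a3

    def test_invalid_rfd(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 100, seed=0)
        with pytest.raises(ValueError):
            gr.exceedance_fraction(s, 0.0)


class TestAttribution:
    def test_partition_sums_exactly_to_exceedance(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 30_000, seed=6)
        for rfd in (5.0, 10.0, 13.5, 20.0):
            attr = gr.attribute_exceedance(s, rfd)
            assert sum(attr.values()) == pytest.approx(
                gr.exceedance_fraction(s, rfd), abs=1e-9)

    def test_single_agent_scenario_gets_all_attribution(self):
        s = gr.simulate(point_scenario(c_nf=0.0, c_pw=2.0), "adults", "serum",
                        1000, seed=0)
        attr = gr.attribute_exceedance(s, 0.05)
        assert attr["perchlorate"] == pytest.approx(100.0)
        assert attr["nitrate"] == 0.0 and attr["thiocyanate"] == 0.0

    def test_largest_contribution_rule(self):
        # perchlorate 0.9 x rfd vs nitrate 0.3 x rfd: exceeders go to perchlorate
        rfd = 1.0
        s = gr.simulate(point_scenario(c_pw=0.9 / 0.05, c_nf=0.3 * 150 / 0.02),
                        "adults", "serum", 1000, seed=0)
        attr = gr.attribute_exceedance(s, rfd)
        assert attr["perchlorate"] == pytest.approx(100.0)

    def test_single_agent_rule_differs_from_partition(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 30_000, seed=6)
        single = gr.attribute_exceedance(s, 10.0, rule="single")
        # single-agent thresholding has no partition property in general
        assert sum(single.values()) <= gr.exceedance_fraction(s, 10.0) + 1e-9


class TestRouteShares:
    def test_thiocyanate_is_food_only(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 5000, seed=8)
        water, food = gr.route_shares(s, "thiocyanate")
        assert (water, food) == (0.0, 100.0)

    def test_single_route_scenario(self):
        s = gr.simulate(point_scenario(c_nf=0.0), "adults", "serum", 100, seed=0)
        assert gr.route_shares(s, "perchlorate") == (100.0, 0.0)

    def test_shares_sum_to_100(self, synthetic):
        s = gr.simulate(synthetic, "2-3 years", "serum", 5000, seed=8)
        for agent in ("perchlorate", "nitrate"):
            water, food = gr.route_shares(s, agent)
            assert water + food == pytest.approx(100.0)

    def test_zero_agent_raises(self):
        s = gr.simulate(point_scenario(c_nf=0.0), "adults", "serum", 100, seed=0)
        with pytest.raises(UndefinedShareError):
            gr.route_shares(s, "thiocyanate")


class TestStabilityN:
    def test_degenerate_scenario_stable_at_start(self):
        n = gr.stability_n(point_scenario(), "adults", "serum",
                           start_n=1000, seed=0)
        assert n == 1000

    def test_synthetic_scenario_converges_and_is_reproducible(self, synthetic):
        n1 = gr.stability_n(synthetic, "2-3 years", "serum", start_n=1000, seed=1)
        n2 = gr.stability_n(synthetic, "2-3 years", "serum", start_n=1000, seed=1)
        assert n1 == n2 <= 10**6

    def test_cap_raises_with_trace(self, synthetic):
        with pytest.raises(NonConvergenceError) as exc:
            gr.stability_n(synthetic, "2-3 years", "serum", start_n=1000,
                           seed=1, rel_tol=1e-9, cap=4000)
        assert len(exc.value.trace) >= 2
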
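"""Steady-state balance, uptake kinetics, transfers, thresholds, light mode."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from ddaflux import (
    AllometricCoefficients,
    DDAComposition,
    GrowthRateWarning,
    PhysiologyParams,
    Scenario,
    fixation_c_cost,
    light_limited_photosynthesis,
    n2_fixation_requirement,
    nh4_uptake,
    no_transfer_concentration,
    partition_photosynthesis,
    solve_steady_state,
    total_photosynthesis,
    zero_fixation_concentration,
)

NH4_GRID = [0.0, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05]
MU_GRID = [0.3, 0.4, 0.51, 0.6, 0.7, 0.8]


# ---------------------------------------------------------------- uptake

def test_uptake_monod_anchor_points(params, quotas):
    capacity = params.vmax_nh4 * quotas.qcd
    assert nh4_uptake(0.0, params, quotas) == 0.0
    assert nh4_uptake(params.km_nh4, params, quotas) == pytest.approx(capacity / 2)
    assert nh4_uptake(1e9, params, quotas) == pytest.approx(capacity, rel=1e-6)


def test_uptake_monotone_saturating(params, quotas):
    values = [nh4_uptake(c, params, quotas) for c in NH4_GRID]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert values[-1] < params.vmax_nh4 * quotas.qcd


def test_uptake_negative_concentration_rejected(params, quotas):
    with pytest.raises(ValueError, match="ammonium"):
        nh4_uptake(-0.01, params, quotas)


# ------------------------------------------------------------- fixation

def test_fixation_requirement_closes_n_balance(params, quotas):
    mu = 0.51
    demand = mu * quotas.total_nitrogen
    assert n2_fixation_requirement(mu, quotas, 0.0) == pytest.approx(demand)
    assert n2_fixation_requirement(mu, quotas, demand) == 0.0
    assert n2_fixation_requirement(mu, quotas, 2 * demand) == 0.0


def test_fixation_requirement_frozen_example(params, quotas):
    # demand 0.51*(16.83/6.6) minus Monod uptake at 0.04; hand arithmetic
    uptake = nh4_uptake(0.04, params, quotas)
    assert n2_fixation_requirement(0.51, quotas, uptake) == pytest.approx(0.160, abs=0.005)


def test_fixation_cost_linear(params):
    assert fixation_c_cost(0.0, params) == 0.0
    a, b = 0.3, 0.7
    assert fixation_c_cost(a + b, params) == pytest.approx(
        fixation_c_cost(a, params) + fixation_c_cost(b, params)
    )
    unit = replace(params, fcn_fix=2.2)
    assert fixation_c_cost(1.0, unit) == pytest.approx(2.2)


# ------------------------------------------------------- photosynthesis

def test_total_photosynthesis_direct_substitution(params, quotas):
    mu = 0.51
    fc = fixation_c_cost(mu * quotas.total_nitrogen, params)
    expected = mu * quotas.total_carbon * 1.38 + fc
    assert total_photosynthesis(mu, quotas, params, fc) == pytest.approx(expected)
    assert total_photosynthesis(0.0, quotas, params, 0.0) == 0.0


def test_equal_e_collapse(params, quotas):
    # with one shared E the per-compartment sum collapses to mu*SumQC*(1+E)+FC
    for mu in MU_GRID:
        fc = 0.123
        assert total_photosynthesis(mu, quotas, params, fc) == pytest.approx(
            mu * quotas.total_carbon * (1 + params.e_diatom) + fc, rel=1e-12
        )


def test_doubling_vegetative_e_adds_mu_qcv_e(params, quotas):
    mu = 0.51
    doubled = replace(params, e_vegetative=0.76)
    diff = total_photosynthesis(mu, quotas, doubled, 0.0) - total_photosynthesis(
        mu, quotas, params, 0.0
    )
    assert diff == pytest.approx(mu * quotas.qcv * 0.38, rel=1e-9)


def test_partition_conserves_and_matches_n_share(quotas):
    f_d, f_v = partition_photosynthesis(10.0, quotas)
    assert f_d + f_v == pytest.approx(10.0, rel=1e-12)
    assert f_d / 10.0 == pytest.approx(quotas.qnd / (quotas.qnd + quotas.qnv))
    # diatom takes ~85% of photosynthesis with default quotas
    assert f_d / 10.0 == pytest.approx(0.850, abs=0.005)


def test_partition_symmetric_for_equal_quotas():
    from ddaflux import Quotas

    q = Quotas(qcd=6.6, qcv=6.6, qch=1.0, qnd=1.0, qnv=1.0, qnh=0.15)
    f_d, f_v = partition_photosynthesis(8.0, q)
    assert f_d == pytest.approx(f_v)


# ------------------------------------------------------------ solve

@pytest.mark.parametrize("mu", MU_GRID)
@pytest.mark.parametrize("nh4", NH4_GRID)
def test_balances_close(mu, nh4):
    sol = solve_steady_state(Scenario(mu=mu, nh4=nh4))
    assert sol.feasible
    assert abs(sol.c_residual) <= 1e-9 * max(1.0, sol.s_pho_total)
    assert abs(sol.n_residual) <= 1e-9 * max(1.0, sol.fn_fix + sol.v_nh4)
    assert sol.f_pho_d + sol.f_pho_v == pytest.approx(sol.s_pho_total, rel=1e-12)
    assert sol.fn_fix >= 0
    assert sol.v_nh4 <= sol.v_nh4_potential + 1e-15


def test_monotone_in_ammonium_at_fixed_growth():
    sols = [solve_steady_state(Scenario(mu=0.51, nh4=c)) for c in NH4_GRID]
    for field in ("fn_fix", "fc_fix_cost", "s_pho_total", "tc", "tn"):
        values = [getattr(s, field) for s in sols]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:])), field
    uptakes = [s.v_nh4 for s in sols]
    assert all(b >= a for a, b in zip(uptakes, uptakes[1:]))


def test_monotone_in_growth_at_fixed_ammonium():
    sols = [solve_steady_state(Scenario(mu=m, nh4=0.01)) for m in MU_GRID]
    for field in ("fn_fix", "s_pho_total", "tc"):
        values = [getattr(s, field) for s in sols]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:])), field


def test_supersaturating_uptake_clipped_no_negative_fixation():
    sol = solve_steady_state(Scenario(mu=0.3, nh4=5.0))
    assert sol.fn_fix == 0.0
    assert sol.v_nh4 < sol.v_nh4_potential
    assert sol.tn < 0  # excess ammonium pushed diatom -> trichome
    assert abs(sol.n_residual) < 1e-12


def test_nitrogen_transfer_endpoints(params, quotas):
    sol0 = solve_steady_state(Scenario(mu=0.51, nh4=0.0))
    assert sol0.tn == pytest.approx(0.51 * quotas.qnd, rel=1e-12)
    star = no_transfer_concentration(0.51, params, quotas)
    assert solve_steady_state(Scenario(mu=0.51, nh4=star)).tn == pytest.approx(0.0, abs=1e-12)


def test_carbon_transfer_balance_point(params, quotas):
    # if vegetative photosynthesis exactly met trichome demand, tc would vanish
    from ddaflux import carbon_transfer

    mu, fc = 0.51, 0.0
    demand = mu * (quotas.qcv * 1.38 + quotas.qch * 1.38)
    assert carbon_transfer(mu, quotas, params, fc, demand) == pytest.approx(0.0, abs=1e-12)


# -------------------------------------------------------- thresholds

def test_no_transfer_concentration_agrees_with_bisection(params, quotas):
    star = no_transfer_concentration(0.51, params, quotas)
    root = brentq(
        lambda c: solve_steady_state(Scenario(mu=0.51, nh4=c)).tn,
        1e-6, 1.0, xtol=1e-12,
    )
    assert abs(star - root) < 1e-9


def test_zero_fixation_concentration_agrees_with_grid_search(params, quotas):
    star = zero_fixation_concentration(0.4, params, quotas)
    grid = np.linspace(0.0, 0.1, 20001)
    fixation = np.array(
        [solve_steady_state(Scenario(mu=0.4, nh4=c)).fn_fix for c in grid]
    )
    first_zero = grid[np.argmax(fixation == 0.0)]
    assert abs(star - first_zero) <= (grid[1] - grid[0])
    assert solve_steady_state(Scenario(mu=0.4, nh4=star * 1.000001)).fn_fix == 0.0


def test_threshold_ordering_and_degenerate_cases(params, quotas):
    for mu in MU_GRID:
        assert zero_fixation_concentration(mu, params, quotas) >= no_transfer_concentration(
            mu, params, quotas
        )
    assert no_transfer_concentration(0.0, params, quotas) == 0.0
    with pytest.raises(ValueError, match="capacity"):
        no_transfer_concentration(10.0, params, quotas)


# ---------------------------------------------------- scale invariance

def test_quota_rescaling_scales_fluxes_and_preserves_ratios(params):
    k = 3.7
    shifted = AllometricCoefficients(
        diatom=(-0.933 + math.log10(k), 0.881),
        vegetative=(-0.665 + math.log10(k), 0.939),
        heterocyst=(-0.665 + math.log10(k), 0.939),
    )
    base = solve_steady_state(Scenario(mu=0.51, nh4=0.01))
    scaled = solve_steady_state(Scenario(mu=0.51, nh4=0.01, allometry=shifted))
    for field in ("v_nh4", "fn_fix", "fc_fix_cost", "s_pho_total", "tc", "tn"):
        assert getattr(scaled, field) == pytest.approx(k * getattr(base, field), rel=1e-9)
    assert scaled.tc / scaled.s_pho_total == pytest.approx(
        base.tc / base.s_pho_total, rel=1e-9
    )
    q_base = Scenario(mu=0.51, nh4=0.01).quotas()
    q_scaled = Scenario(mu=0.51, nh4=0.01, allometry=shifted).quotas()
    assert no_transfer_concentration(0.51, params, q_scaled) == pytest.approx(
        no_transfer_concentration(0.51, params, q_base), rel=1e-12
    )
    assert zero_fixation_concentration(0.51, params, q_scaled) == pytest.approx(
        zero_fixation_concentration(0.51, params, q_base), rel=1e-12
    )


# ------------------------------------------------------ trichome count

def test_trichome_count_orderings():
    # more trichomes: more C transferred in, more fixation; the diatom's
    # share of the N budget (relative N transfer) shrinks
    from ddaflux import budget

    scenarios = [
        Scenario(mu=0.51, nh4=0.01, composition=DDAComposition(n_trichomes=n))
        for n in range(1, 6)
    ]
    sols = [solve_steady_state(s) for s in scenarios]
    budgets = [
        budget(sol, s.quotas(), s.resolved_params())
        for sol, s in zip(sols, scenarios)
    ]
    tcs = [s.tc for s in sols]
    fns = [s.fn_fix for s in sols]
    tnp = [b.n_transfer_percent for b in budgets]
    assert all(b > a for a, b in zip(tcs, tcs[1:]))
    assert all(b > a for a, b in zip(fns, fns[1:]))
    assert all(b < a for a, b in zip(tnp, tnp[1:]))


# -------------------------------------------------------------- light

def test_zero_irradiance_infeasible(params, quotas):
    cap_d, cap_v = light_limited_photosynthesis(0.0, params, quotas)
    assert cap_d == cap_v == 0.0
    sol = solve_steady_state(Scenario(mu=0.51, nh4=0.01, irradiance=0.0))
    assert not sol.feasible


def test_saturating_irradiance_recovers_replete_solution():
    replete = solve_steady_state(Scenario(mu=0.51, nh4=0.01))
    lit = solve_steady_state(Scenario(mu=0.51, nh4=0.01, irradiance=1e6))
    assert lit.feasible
    assert lit.f_pho_d == pytest.approx(replete.f_pho_d, rel=1e-9)
    assert lit.f_pho_v == pytest.approx(replete.f_pho_v, rel=1e-9)
    assert lit.tc == pytest.approx(replete.tc, rel=1e-9)


def test_subsaturating_light_contract():
    # below saturation the diatom's capacity binds: realized diatom
    # photosynthesis and C transfer rise with irradiance, N side untouched
    lo = solve_steady_state(Scenario(mu=0.51, nh4=0.01, irradiance=40.0))
    hi = solve_steady_state(Scenario(mu=0.51, nh4=0.01, irradiance=50.0))
    replete = solve_steady_state(Scenario(mu=0.51, nh4=0.01))
    assert lo.feasible and hi.feasible
    assert lo.f_pho_d < hi.f_pho_d
    assert lo.tc < hi.tc <= replete.tc + 1e-12
    assert lo.tn == hi.tn == replete.tn
    assert lo.fn_fix == hi.fn_fix == replete.fn_fix
    assert lo.v_nh4 == hi.v_nh4
    # capacity caps are honoured and the C balance still closes
    for sol in (lo, hi):
        assert sol.f_pho_d <= sol.capacity_d + 1e-12
        assert sol.f_pho_v <= sol.capacity_v + 1e-12
        assert abs(sol.c_residual) < 1e-9 * sol.s_pho_total


def test_negative_irradiance_rejected(params, quotas):
    with pytest.raises(ValueError, match="irradiance"):
        light_limited_photosynthesis(-1.0, params, quotas)


# --------------------------------------------------------- validation

def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(mu=0.5, nh4=-0.1)
    with pytest.raises(ValueError):
        Scenario(mu=-0.1)
    with pytest.warns(GrowthRateWarning):
        Scenario(mu=1.5)
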
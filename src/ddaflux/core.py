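"""Steady-state C and N mass balances of the association.

The model assumes every elemental pool is at steady state over a day, so
supply equals consumption:

* carbon:    FphoD + FphoV = µ·(QCV·(1+Ev) + QCH·(1+Eh) + QCD·(1+Ed)) + FC_fix
* nitrogen:  FN_fix + V_NH4 = µ·(QNV + QNH + QND)

where µ is the shared growth rate (d⁻¹), Q are pooled quotas, E the
respiration-to-biosynthesis ratios, FC_fix = FN_fix · fcn_fix the carbon
price of N2 fixation, and ammonium uptake follows Monod kinetics scaled by
the diatom's carbon quota (the diatom performs the uptake):

    V_NH4 = vmax_nh4 · QCD · [NH4+] / ([NH4+] + km_nh4)

Fixation takes up whatever nitrogen demand uptake leaves uncovered, and is
floored at zero: when Monod uptake would exceed whole-association demand,
effective uptake is clipped to demand (steady state admits no N waste).

Photosynthesis is split between diatom and vegetative cells in proportion
to their N quotas (heterocysts fix no carbon).  Net transfers follow from
per-compartment budgets: carbon moves diatom→trichome to cover the gap
between trichome carbon demand (growth + respiration + fixation cost) and
vegetative photosynthesis; nitrogen moves trichome→diatom whenever uptake
falls short of the diatom's own N demand, and reverses at high ammonium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .composition import (
    DEFAULT_ALLOMETRY,
    DEFAULT_COMPOSITION,
    DEFAULT_RCN,
    AllometricCoefficients,
    DDAComposition,
    Quotas,
    build_quotas,
)

__all__ = [
    "LightResponse",
    "PhysiologyParams",
    "Scenario",
    "FluxSolution",
    "GrowthRateWarning",
    "VARIANTS",
    "GROWTH_RATE_RANGE",
    "DEFAULT_FCN_FIX",
    "nh4_uptake",
    "n2_fixation_requirement",
    "fixation_c_cost",
    "total_photosynthesis",
    "partition_photosynthesis",
    "carbon_transfer",
    "nitrogen_transfer",
    "solve_steady_state",
    "no_transfer_concentration",
    "zero_fixation_concentration",
    "light_limited_photosynthesis",
    "apply_variant",
]

#: growth-rate band supported by observations; values outside it warn.
GROWTH_RATE_RANGE = (0.3, 0.8)

#: carbon cost of N2 fixation, pmol C (pmol N)^-1, calibrated by
#: least squares against the two published C-transfer percentages at
#: µ = 0.51 d^-1 (see ddaflux.calibration.fit_fixation_cost).
DEFAULT_FCN_FIX = 2.07

#: named sensitivity variants.
VARIANTS = ("none", "double_vegetative_E", "half_vegetative_pmax")

#: relative tolerance on the steady-state balance residuals.
BALANCE_RTOL = 1e-9


class GrowthRateWarning(UserWarning):
    """Growth rate outside the observationally supported band."""


@dataclass(frozen=True)
class LightResponse:
    """Saturating photosynthesis-irradiance response, per compartment.

    Capacity of compartment x: ``Pmax_x · (1 − exp(−α·I / Pmax_x))`` with
    ``Pmax_x = pmax_per_n · scale_x · QNx``, i.e. maximum photosynthesis
    proportional to the compartment's nitrogen quota with one shared
    initial slope α.  Used only when a scenario specifies an irradiance.
    """

    #: pmol C (pmol N)^-1 d^-1 at saturating light.
    pmax_per_n: float = 15.0
    #: initial slope, pmol C d^-1 per (µmol photons m^-2 s^-1).
    alpha: float = 0.3
    pmax_scale_diatom: float = 1.0
    pmax_scale_vegetative: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pmax_per_n", "alpha", "pmax_scale_diatom", "pmax_scale_vegetative"):
            if not getattr(self, name) > 0:
                raise ValueError(f"light-response parameter {name} must be > 0")


@dataclass(frozen=True)
class PhysiologyParams:
    """Physiological rate and cost parameters.

    Respiration ratios E may be zero; everything else is strictly positive.
    ``vmax_nh4`` is expressed per unit diatom carbon and multiplied by QCD
    to yield a per-association uptake capacity.
    """

    e_diatom: float = 0.38
    e_vegetative: float = 0.38
    e_heterocyst: float = 0.38
    fcn_fix: float = DEFAULT_FCN_FIX
    vmax_nh4: float = 1.16
    km_nh4: float = 0.483
    rcn: float = DEFAULT_RCN
    light: LightResponse = field(default_factory=LightResponse)

    def __post_init__(self) -> None:
        for name in ("e_diatom", "e_vegetative", "e_heterocyst"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fcn_fix", "vmax_nh4", "km_nh4", "rcn"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def apply_variant(params: PhysiologyParams, variant: str) -> PhysiologyParams:
    """Return a copy of ``params`` with one named sensitivity variant applied.

    ``double_vegetative_E`` doubles the vegetative respiration ratio;
    ``half_vegetative_pmax`` halves the vegetative light-saturated
    photosynthesis rate (effective in light mode only); ``none`` is the
    identity.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "none":
        return params
    if variant == "double_vegetative_E":
        return replace(params, e_vegetative=2.0 * params.e_vegetative)
    return replace(
        params,
        light=replace(params.light,
                      pmax_scale_vegetative=0.5 * params.light.pmax_scale_vegetative),
    )


@dataclass(frozen=True)
class Scenario:
    """One model evaluation: growth rate + environment + composition + params.

    ``irradiance=None`` selects light-replete mode, where photosynthesis is
    purely demand-driven; a numeric irradiance (µmol photons m⁻² s⁻¹)
    activates the light-limited mode.
    """

    mu: float
    nh4: float = 0.0
    irradiance: float | None = None
    composition: DDAComposition = DEFAULT_COMPOSITION
    params: PhysiologyParams = field(default_factory=PhysiologyParams)
    allometry: AllometricCoefficients = DEFAULT_ALLOMETRY
    variant: str = "none"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"growth rate must be >= 0, got {self.mu!r}")
        if self.nh4 < 0:
            raise ValueError(f"ammonium concentration must be >= 0, got {self.nh4!r}")
        if self.irradiance is not None and self.irradiance < 0:
            raise ValueError(f"irradiance must be >= 0, got {self.irradiance!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        lo, hi = GROWTH_RATE_RANGE
        if not lo <= self.mu <= hi:
            warnings.warn(
                f"growth rate {self.mu} d^-1 outside the supported band "
                f"[{lo}, {hi}] d^-1",
                GrowthRateWarning,
                stacklevel=2,
            )

    def resolved_params(self) -> PhysiologyParams:
        return apply_variant(self.params, self.variant)

    def quotas(self) -> Quotas:
        return build_quotas(self.composition, self.allometry,
                            self.resolved_params().rcn)


@dataclass(frozen=True)
class FluxSolution:
    """All resolved per-association daily fluxes for one scenario.

    Transfers are signed: ``tc`` > 0 means carbon flows diatom→trichome
    (the consistent direction); ``tn`` > 0 means nitrogen flows
    trichome→diatom, turning negative once ammonium uptake exceeds the
    diatom's own demand.  ``capacity_d``/``capacity_v`` are light-response
    caps, ``None`` in light-replete mode.
    """

    mu: float
    nh4: float
    irradiance: float | None
    v_nh4_potential: float
    v_nh4: float
    fn_fix: float
    fc_fix_cost: float
    s_pho_total: float
    f_pho_d: float
    f_pho_v: float
    tc: float
    tn: float
    c_residual: float
    n_residual: float
    feasible: bool
    capacity_d: float | None = None
    capacity_v: float | None = None

    def as_record(self) -> dict:
        """Flat dict of all fields, suitable for tabular output."""
        return {
            "mu": self.mu,
            "nh4": self.nh4,
            "irradiance": self.irradiance,
            "v_nh4_potential": self.v_nh4_potential,
            "v_nh4": self.v_nh4,
            "fn_fix": self.fn_fix,
            "fc_fix_cost": self.fc_fix_cost,
            "s_pho_total": self.s_pho_total,
            "f_pho_d": self.f_pho_d,
            "f_pho_v": self.f_pho_v,
            "tc": self.tc,
            "tn": self.tn,
            "c_residual": self.c_residual,
            "n_residual": self.n_residual,
            "feasible": self.feasible,
            "capacity_d": self.capacity_d,
            "capacity_v": self.capacity_v,
        }


def nh4_uptake(nh4: float, params: PhysiologyParams, quotas: Quotas) -> float:
    """Monod ammonium uptake by the diatom, pmol N d⁻¹ per association.

    ``vmax_nh4 · QCD · nh4 / (nh4 + km_nh4)``; zero at zero ammonium, half
    the capacity at the half-saturation concentration, saturating at
    ``vmax_nh4 · QCD``.
    """
    if nh4 < 0:
        raise ValueError(f"ammonium concentration must be >= 0, got {nh4!r}")
    return params.vmax_nh4 * quotas.qcd * nh4 / (nh4 + params.km_nh4)


def n2_fixation_requirement(mu: float, quotas: Quotas, uptake: float) -> float:
    """N2 fixation needed to close the N balance, pmol N d⁻¹.

    ``max(0, µ·(QNV+QNH+QND) − uptake)``: exactly zero once uptake covers
    whole-association demand.
    """
    if uptake < 0:
        raise ValueError("uptake must be >= 0")
    return max(0.0, mu * quotas.total_nitrogen - uptake)


def fixation_c_cost(fn_fix: float, params: PhysiologyParams) -> float:
    """Carbon price of fixation: ``fn_fix · fcn_fix``, pmol C d⁻¹."""
    if fn_fix < 0:
        raise ValueError("fn_fix must be >= 0")
    return fn_fix * params.fcn_fix


def total_photosynthesis(
    mu: float, quotas: Quotas, params: PhysiologyParams, fc_fix_cost: float
) -> float:
    """Total required carbon fixation, pmol C d⁻¹.

    Growth plus respiration per compartment plus the fixation cost:
    ``µ·(QCV·(1+Ev) + QCH·(1+Eh) + QCD·(1+Ed)) + fc_fix_cost``.  With a
    single shared E this collapses to ``µ·ΣQC·(1+E) + fc_fix_cost``.
    """
    growth_and_respiration = mu * (
        quotas.qcv * (1.0 + params.e_vegetative)
        + quotas.qch * (1.0 + params.e_heterocyst)
        + quotas.qcd * (1.0 + params.e_diatom)
    )
    return growth_and_respiration + fc_fix_cost


def partition_photosynthesis(s_total: float, quotas: Quotas) -> tuple[float, float]:
    """Split total photosynthesis across diatom and vegetative cells.

    Proportional to nitrogen quotas; heterocysts fix no carbon.  Returns
    ``(f_pho_d, f_pho_v)`` with ``f_pho_d + f_pho_v == s_total``.
    """
    if s_total < 0:
        raise ValueError("s_total must be >= 0")
    share_d = quotas.qnd / (quotas.qnd + quotas.qnv)
    f_pho_d = s_total * share_d
    return f_pho_d, s_total - f_pho_d


def _trichome_carbon_demand(mu: float, quotas: Quotas, params: PhysiologyParams) -> float:
    return mu * (
        quotas.qcv * (1.0 + params.e_vegetative)
        + quotas.qch * (1.0 + params.e_heterocyst)
    )


def carbon_transfer(
    mu: float,
    quotas: Quotas,
    params: PhysiologyParams,
    fc_fix_cost: float,
    f_pho_v: float,
) -> float:
    """Net carbon transfer, pmol C d⁻¹, positive diatom→trichome.

    Trichome carbon demand (growth + respiration + fixation cost) minus
    what vegetative photosynthesis supplies in-house.
    """
    return _trichome_carbon_demand(mu, quotas, params) + fc_fix_cost - f_pho_v


def nitrogen_transfer(mu: float, quotas: Quotas, v_nh4_effective: float) -> float:
    """Net nitrogen transfer, pmol N d⁻¹, positive trichome→diatom.

    Diatom nitrogen demand minus its (effective) ammonium uptake: positive
    when fixation subsidises the diatom, negative when excess ammonium is
    pushed diatom→trichome, zero at the no-transfer concentration.
    """
    return mu * quotas.qnd - v_nh4_effective


def light_limited_photosynthesis(
    irradiance: float, params: PhysiologyParams, quotas: Quotas
) -> tuple[float, float]:
    """Attainable photosynthesis per compartment at a given irradiance.

    Returns ``(capacity_diatom, capacity_vegetative)`` in pmol C d⁻¹ from
    the saturating response ``Pmax·(1 − exp(−α·I/Pmax))``; heterocysts have
    zero capacity by construction.
    """
    if irradiance < 0:
        raise ValueError(f"irradiance must be >= 0, got {irradiance!r}")
    lr = params.light

    def capacity(qn: float, scale: float) -> float:
        pmax = lr.pmax_per_n * scale * qn
        if pmax == 0.0 or irradiance == 0.0:
            return 0.0
        return pmax * (1.0 - math.exp(-lr.alpha * irradiance / pmax))

    return (
        capacity(quotas.qnd, lr.pmax_scale_diatom),
        capacity(quotas.qnv, lr.pmax_scale_vegetative),
    )


def solve_steady_state(scenario: Scenario) -> FluxSolution:
    """Resolve all fluxes of one scenario.

    Composes uptake → fixation → fixation cost → total photosynthesis →
    partition → transfers.  When Monod uptake exceeds whole-association
    demand, effective uptake is clipped to demand (fixation floored at 0).
    In light mode the compartment photosynthesis rates are additionally
    capped by their light-response capacities, with the shortfall
    reassigned to the unconstrained compartment; scenarios whose total
    capacity cannot meet the required supply are flagged infeasible (never
    silently truncated).
    """
    params = scenario.resolved_params()
    quotas = scenario.quotas()
    mu = scenario.mu

    v_potential = nh4_uptake(scenario.nh4, params, quotas)
    demand_n = mu * quotas.total_nitrogen
    v_effective = min(v_potential, demand_n)
    fn_fix = n2_fixation_requirement(mu, quotas, v_effective)
    fc_cost = fixation_c_cost(fn_fix, params)
    s_total = total_photosynthesis(mu, quotas, params, fc_cost)
    f_pho_d, f_pho_v = partition_photosynthesis(s_total, quotas)

    feasible = True
    capacity_d: float | None = None
    capacity_v: float | None = None
    if scenario.irradiance is not None:
        capacity_d, capacity_v = light_limited_photosynthesis(
            scenario.irradiance, params, quotas
        )
        if capacity_d + capacity_v < s_total * (1.0 - BALANCE_RTOL):
            feasible = False
            f_pho_d, f_pho_v = capacity_d, capacity_v
        elif f_pho_d > capacity_d:
            f_pho_d = capacity_d
            f_pho_v = s_total - f_pho_d
        elif f_pho_v > capacity_v:
            f_pho_v = capacity_v
            f_pho_d = s_total - f_pho_v

    tc = carbon_transfer(mu, quotas, params, fc_cost, f_pho_v)
    tn = nitrogen_transfer(mu, quotas, v_effective)
    c_residual = (f_pho_d + f_pho_v) - s_total
    n_residual = (fn_fix + v_effective) - demand_n

    return FluxSolution(
        mu=mu,
        nh4=scenario.nh4,
        irradiance=scenario.irradiance,
        v_nh4_potential=v_potential,
        v_nh4=v_effective,
        fn_fix=fn_fix,
        fc_fix_cost=fc_cost,
        s_pho_total=s_total,
        f_pho_d=f_pho_d,
        f_pho_v=f_pho_v,
        tc=tc,
        tn=tn,
        c_residual=c_residual,
        n_residual=n_residual,
        feasible=feasible,
        capacity_d=capacity_d,
        capacity_v=capacity_v,
    )


def _threshold(mu_demand_n: float, params: PhysiologyParams, quotas: Quotas) -> float:
    """Ammonium level where Monod uptake equals a given N demand."""
    capacity = params.vmax_nh4 * quotas.qcd
    a = mu_demand_n / capacity
    if a >= 1.0:
        raise ValueError(
            "demand exceeds maximum uptake capacity: no finite ammonium "
            f"concentration satisfies it (demand/capacity = {a:.4g})"
        )
    return params.km_nh4 * a / (1.0 - a)


def no_transfer_concentration(
    mu: float, params: PhysiologyParams, quotas: Quotas
) -> float:
    """Ammonium level at which net N transfer is zero, mmol m⁻³.

    Closed form of ``nitrogen_transfer == 0``: uptake equals the diatom's
    own demand µ·QND.  With QND = QCD/rCN this is independent of the
    quotas themselves: a = µ/(rCN·vmax), threshold = km·a/(1−a).
    """
    return _threshold(mu * quotas.qnd, params, quotas)


def zero_fixation_concentration(
    mu: float, params: PhysiologyParams, quotas: Quotas
) -> float:
    """Ammonium level above which N2 fixation is zero, mmol m⁻³.

    Uptake equals whole-association demand µ·(QNV+QNH+QND); always at or
    above the no-transfer concentration for the same µ.
    """
    return _threshold(mu * quotas.total_nitrogen, params, quotas)
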
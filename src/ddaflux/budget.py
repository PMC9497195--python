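"""Element-fate budgets and parameter sweeps.

A :class:`Budget` decomposes one steady-state solution into percentage
shares of total carbon and nitrogen supply.  Under steady state supply
equals consumption, so one base (total supply) serves both sides: the
supply shares and the consumption shares each sum to 100.

Sweeps evaluate the model over the Cartesian product of requested axes
(ammonium, growth rate, trichome number, irradiance) in row-major order
and return a :class:`pandas.DataFrame`; infeasible grid points are flagged
rather than aborting the sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .composition import Quotas
from .core import (
    FluxSolution,
    PhysiologyParams,
    Scenario,
    apply_variant,
    solve_steady_state,
)

__all__ = ["Budget", "budget", "sweep", "apply_variant", "SWEEP_AXES"]

#: axes a sweep may vary.
SWEEP_AXES = ("nh4", "mu", "n_trichomes", "irradiance")


@dataclass(frozen=True)
class Budget:
    """Percent decomposition of total C and N supply into fates.

    Carbon supply splits into diatom and vegetative photosynthesis;
    carbon consumption into growth and respiration of each side plus the
    fixation cost.  Nitrogen supply splits into fixation and ammonium
    uptake; nitrogen consumption into per-compartment growth.  Transfers
    are expressed against the same totals; ``n_transfer_percent`` is the
    heterocyst→diatom leg, signed (negative once excess ammonium flows
    diatom→trichome), and ``n_transfer_het_to_veg_percent`` exposes the
    within-trichome leg separately.
    """

    c_photosynthesis_diatom: float
    c_photosynthesis_vegetative: float
    c_growth_diatom: float
    c_growth_trichome: float
    c_respiration_diatom: float
    c_respiration_trichome: float
    c_fixation_cost: float
    c_transfer_percent: float
    n_fixation: float
    n_uptake: float
    n_growth_diatom: float
    n_growth_vegetative: float
    n_growth_heterocyst: float
    n_transfer_percent: float
    n_transfer_het_to_veg_percent: float

    def as_record(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @property
    def c_supply_total(self) -> float:
        return self.c_photosynthesis_diatom + self.c_photosynthesis_vegetative

    @property
    def c_consumption_total(self) -> float:
        return (
            self.c_growth_diatom
            + self.c_growth_trichome
            + self.c_respiration_diatom
            + self.c_respiration_trichome
            + self.c_fixation_cost
        )

    @property
    def n_supply_total(self) -> float:
        return self.n_fixation + self.n_uptake

    @property
    def n_consumption_total(self) -> float:
        return self.n_growth_diatom + self.n_growth_vegetative + self.n_growth_heterocyst


def budget(solution: FluxSolution, quotas: Quotas, params: PhysiologyParams) -> Budget:
    """Percentage element-fate decomposition of one feasible solution."""
    if not solution.feasible:
        raise ValueError("cannot build a budget from an infeasible solution")
    mu = solution.mu
    s_c = solution.s_pho_total
    s_n = solution.fn_fix + solution.v_nh4
    if s_c <= 0 or s_n <= 0:
        raise ValueError("budget undefined for a non-growing scenario (zero supply)")

    # heterocyst keeps its own demand from fixed N; the rest is exported
    # to the diatom (the tn leg, when positive) and to vegetative cells.
    het_export = solution.fn_fix - mu * quotas.qnh
    het_to_veg = max(0.0, min(het_export - max(solution.tn, 0.0), mu * quotas.qnv))

    return Budget(
        c_photosynthesis_diatom=100.0 * solution.f_pho_d / s_c,
        c_photosynthesis_vegetative=100.0 * solution.f_pho_v / s_c,
        c_growth_diatom=100.0 * mu * quotas.qcd / s_c,
        c_growth_trichome=100.0 * mu * quotas.trichome_carbon / s_c,
        c_respiration_diatom=100.0 * mu * quotas.qcd * params.e_diatom / s_c,
        c_respiration_trichome=100.0
        * mu
        * (quotas.qcv * params.e_vegetative + quotas.qch * params.e_heterocyst)
        / s_c,
        c_fixation_cost=100.0 * solution.fc_fix_cost / s_c,
        c_transfer_percent=100.0 * solution.tc / s_c,
        n_fixation=100.0 * solution.fn_fix / s_n,
        n_uptake=100.0 * solution.v_nh4 / s_n,
        n_growth_diatom=100.0 * mu * quotas.qnd / s_n,
        n_growth_vegetative=100.0 * mu * quotas.qnv / s_n,
        n_growth_heterocyst=100.0 * mu * quotas.qnh / s_n,
        n_transfer_percent=100.0 * solution.tn / s_n,
        n_transfer_het_to_veg_percent=100.0 * het_to_veg / s_n,
    )


def _scenario_at(base: Scenario, point: Mapping[str, float]) -> Scenario:
    changes: dict = {}
    for axis, value in point.items():
        if axis == "n_trichomes":
            changes["composition"] = replace(base.composition, n_trichomes=int(value))
        else:
            changes[axis] = value
    return replace(base, **changes)


def sweep(axes: Mapping[str, Sequence], base: Scenario) -> pd.DataFrame:
    """Evaluate the model over the Cartesian product of ``axes``.

    ``axes`` maps axis names (a subset of :data:`SWEEP_AXES`) to non-empty
    value lists; the grid is traversed row-major in the order the axes are
    listed.  Each record carries the axis values, all flux fields, all
    budget fields and a ``status`` column (``ok`` or ``infeasible``);
    infeasible points keep their flux fields but have budget fields empty.
    """
    for axis, values in axes.items():
        if axis not in SWEEP_AXES:
            raise ValueError(f"unknown sweep axis {axis!r}; expected one of {SWEEP_AXES}")
        if len(values) == 0:
            raise ValueError(f"sweep axis {axis!r} has no values")

    names = list(axes)
    budget_fields = list(Budget.__dataclass_fields__)
    records = []
    for combo in itertools.product(*(axes[n] for n in names)):
        point = dict(zip(names, combo))
        scenario = _scenario_at(base, point)
        solution = solve_steady_state(scenario)
        record = dict(point)
        record.update(solution.as_record())
        if solution.feasible:
            b = budget(solution, scenario.quotas(), scenario.resolved_params())
            record.update(b.as_record())
            record["status"] = "ok"
        else:
            record.update({k: float("nan") for k in budget_fields})
            record["status"] = "infeasible"
        records.append(record)

    columns = (
        names
        + [c for c in FluxSolution.__dataclass_fields__ if c not in names]
        + budget_fields
        + ["status"]
    )
    return pd.DataFrame.from_records(records, columns=columns)
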
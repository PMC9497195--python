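"""Calibration of the N2-fixation carbon cost.

The carbon price of fixation (``fcn_fix``, pmol C per pmol N) is not
directly observable here; it is pinned by least squares so that the model
reproduces the two published relative C-transfer values at the average
observed growth rate (0.51 d⁻¹): 22.7% of total C supply at zero ambient
ammonium and 11.1% at 0.04 mmol m⁻³.  The frozen package default
(:data:`ddaflux.core.DEFAULT_FCN_FIX`) is this fit rounded to two decimals;
it is an ordinary config parameter and can be overridden.
"""

from __future__ import annotations

from dataclasses import replace

from scipy.optimize import minimize_scalar

from .core import PhysiologyParams, Scenario, solve_steady_state

__all__ = ["fit_fixation_cost", "DEFAULT_ANCHORS"]

#: (ammonium mmol m^-3, observed C-transfer percent) anchor points.
DEFAULT_ANCHORS = ((0.0, 22.7), (0.04, 11.1))

#: growth rate the anchors were reported at, d^-1.
ANCHOR_MU = 0.51


def fit_fixation_cost(
    anchors=DEFAULT_ANCHORS,
    mu: float = ANCHOR_MU,
    params: PhysiologyParams | None = None,
    bounds: tuple[float, float] = (0.5, 5.0),
) -> float:
    """Least-squares estimate of ``fcn_fix`` from C-transfer anchors.

    Minimises the sum of squared differences between the model's
    ``tc / s_pho_total`` (in percent) and each anchor's observed percent,
    over ``fcn_fix`` within ``bounds``.
    """
    base = params if params is not None else PhysiologyParams()

    def transfer_percent(fcn_fix: float, nh4: float) -> float:
        scenario = Scenario(mu=mu, nh4=nh4, params=replace(base, fcn_fix=fcn_fix))
        sol = solve_steady_state(scenario)
        return 100.0 * sol.tc / sol.s_pho_total

    def sse(fcn_fix: float) -> float:
        return sum(
            (transfer_percent(fcn_fix, nh4) - observed) ** 2
            for nh4, observed in anchors
        )

    result = minimize_scalar(sse, bounds=bounds, method="bounded")
    return float(result.x)
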
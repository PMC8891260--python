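"""Capacity and resource projections for multi-billion-dose targets.

Per-scenario platform performance is extrapolated linearly to a dose
target (1 B/yr for the headline comparison, 2.4 B/yr for annual boosters,
11.3 B/yr for the global herd-immunity demand): the number of production
lines needed is fractional (campaign average), and scale, batches, CapEx
and OpEx scale exactly with it.  Economy of scale is deliberately
suppressed in the extrapolation — the sampled processes are already
large-scale, and supplier constraints counteract further scale economies —
so per-line costs are evaluated at the sampled scale and multiplied by the
line count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PlatformConfig
from .costs import opex
from .factors import ParameterError, ScenarioSet
from .fillfinish import FillFinishSpec, ff_annual_doses
from .process import annual_output

__all__ = ["project_resources", "booster_demand", "global_gap_projection"]

#: default annual dose targets: 1 B, booster demand, global herd-immunity gap
DEFAULT_TARGETS = (1e9, 2.4e9, 11.3e9)


def project_resources(
    scenarios,
    cfg: PlatformConfig,
    target: float,
    ff_spec: FillFinishSpec | None = None,
    integer_lines: bool = False,
) -> pd.DataFrame:
    """Resources required to supply ``target`` doses per year, per scenario.

    Returns per-scenario lines (fractional unless ``integer_lines``),
    total required bioreactor working volume, batch starts per year,
    DS-only and total (with fill-to-finish) CapEx and OpEx.  Scenarios
    with zero annual output are flagged undefined (``inf`` resources).
    """
    if target <= 0:
        raise ParameterError("target must be positive")
    out = annual_output(scenarios, cfg)
    cost = opex(scenarios, out, cfg)

    df = scenarios.values if isinstance(scenarios, ScenarioSet) else scenarios
    dpy = out["doses_per_year"].to_numpy(dtype=float)
    scale = df["scale"].to_numpy(dtype=float)

    with np.errstate(divide="ignore"):
        lines = np.where(dpy > 0, target / np.where(dpy > 0, dpy, 1.0), np.inf)
    if integer_lines:
        lines = np.ceil(lines)

    res = pd.DataFrame(
        {
            "target_doses": np.full(len(lines), float(target)),
            "lines": lines,
            "required_scale": lines * scale,
            "batches_per_year": lines * out["batches_started"].to_numpy(),
            "capex_ds": lines * cost["capex"].to_numpy(),
            "opex_ds": lines * cost["opex_total"].to_numpy(),
            "undefined": ~np.isfinite(lines),
        }
    )

    if ff_spec is not None:
        ff_capacity = ff_annual_doses(ff_spec)
        ff_lines = target / ff_capacity
        if integer_lines:
            ff_lines = np.ceil(ff_lines)
        containers = target / ff_spec.doses_per_container
        ff_opex = ff_lines * ff_spec.annual_fixed_cost + containers * ff_spec.cost_per_container
        res["ff_lines"] = ff_lines
        res["capex_total"] = res["capex_ds"] + ff_lines * ff_spec.capex_usd
        res["opex_total"] = res["opex_ds"] + ff_opex
    else:
        res["capex_total"] = res["capex_ds"]
        res["opex_total"] = res["opex_ds"]
    return res


def booster_demand(vulnerable: float, frontline: float, doses_per_person: float = 1) -> float:
    """Annual booster doses for the vulnerable plus frontline populations."""
    if min(vulnerable, frontline, doses_per_person) < 0:
        raise ParameterError("inputs must be non-negative")
    return (vulnerable + frontline) * doses_per_person


def global_gap_projection(
    scenarios,
    cfg: PlatformConfig,
    target: float = 11.3e9,
    ff_spec: FillFinishSpec | None = None,
) -> pd.DataFrame:
    """Resource distribution to meet the global demand gap (default 11.3 B doses)."""
    return project_resources(scenarios, cfg, target, ff_spec=ff_spec)
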
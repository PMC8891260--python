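"""The end-to-end KPI chain: scenario table -> eight techno-economic KPIs.

The eight canonical KPIs per scenario are CapEx, OpEx, batches per year,
amount per batch, amount per year, doses per batch, doses per year and
cost per dose.  The table also carries specific productivity and the time
to one billion doses, which the comparative assessment reports alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Config, PlatformConfig
from .costs import opex
from .factors import central_scenario
from .fillfinish import FillFinishSpec, bottleneck, ff_annual_doses, ff_cost_per_dose
from .process import annual_output, time_to_dose_target

__all__ = ["KPI_COLUMNS", "compute_kpis", "baseline_cost_per_dose"]

#: the eight canonical KPIs, in reporting order
KPI_COLUMNS = [
    "capex",
    "opex_total",
    "batches_released",
    "amount_per_batch",
    "amount_per_year",
    "doses_per_batch",
    "doses_per_year",
    "cost_per_dose",
]


def compute_kpis(scenarios, cfg: PlatformConfig, dose_target: float = 1e9) -> pd.DataFrame:
    """Run the production and cost models over a scenario table.

    Returns one row per scenario with the eight KPIs plus
    ``batches_started``, ``specific_productivity`` and
    ``time_to_target_years`` (``inf`` flagged where output is zero).
    """
    out = annual_output(scenarios, cfg)
    cost = opex(scenarios, out, cfg)
    kpis = pd.concat([out, cost], axis=1)
    kpis["time_to_target_years"] = time_to_dose_target(
        out["doses_per_year"].to_numpy(), dose_target
    )
    return kpis


def baseline_cost_per_dose(
    cfg: PlatformConfig, ff_spec: FillFinishSpec
) -> dict:
    """Total cost per dose at the baseline scenario, including fill-to-finish.

    One drug-substance line is paired with one fill-finish line; the
    combined throughput is the bottleneck of the two stages.  DS fixed
    costs and fill-finish line costs accrue in full; DS variable
    (materials) cost accrues only for the product actually filled, since a
    fill-limited line would not run its bioreactor flat out.
    """
    base = central_scenario(cfg.factor_set)
    out = annual_output(base, cfg)
    cost = opex(base, out, cfg)

    ds_rate = float(out["doses_per_year"].iloc[0])
    ff_rate = ff_annual_doses(ff_spec)
    stage, filled = bottleneck(ds_rate, ff_rate)
    utilisation = filled / ds_rate if ds_rate > 0 else 0.0

    ds_cost = (
        float(cost["opex_fixed"].iloc[0])
        + float(cost["opex_variable"].iloc[0]) * utilisation
    )
    ff_dose_cost = ff_cost_per_dose(ff_spec, doses_filled=filled)
    total = ds_cost / filled + ff_dose_cost if filled > 0 else float("inf")
    return {
        "platform": cfg.platform,
        "ds_doses_per_year": ds_rate,
        "ff_doses_per_year": ff_rate,
        "bottleneck": stage,
        "doses_per_year": filled,
        "ds_cost_per_dose": ds_cost / filled if filled > 0 else float("inf"),
        "ff_cost_per_dose": ff_dose_cost,
        "cost_per_dose": total,
    }
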
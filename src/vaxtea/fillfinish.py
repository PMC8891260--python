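"""Fill-to-finish lines: throughput, bottleneck location and per-dose cost.

Three container technologies are modelled: conventional multi-dose vials
(5- or 10-dose), blow-fill-seal single-dose units, and 200-dose bags.  A
line is characterised by its nameplate container rate, an overall equipment
effectiveness (OEE) factor absorbing all downtime, the doses per container,
a per-container consumable cost, and line CapEx/operating cost.  Lines are
assumed continuously scheduled (525,600 min/yr) with OEE discounting the
realised rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factors import ParameterError

__all__ = ["FillFinishSpec", "ff_annual_doses", "bottleneck", "ff_cost_per_dose"]


@dataclass(frozen=True)
class FillFinishSpec:
    technology: str
    doses_per_container: int
    containers_per_minute: float
    oee: float
    operating_minutes: float
    cost_per_container: float
    capex_usd: float
    operating_usd_per_year: float
    annual_fixed_frac: float = 0.14  # annualised CapEx + maintenance fraction

    def __post_init__(self) -> None:
        if not 0 < self.oee <= 1:
            raise ParameterError("OEE must be in (0, 1]")
        if self.doses_per_container < 1 or self.containers_per_minute <= 0:
            raise ParameterError("invalid fill-finish line specification")

    @property
    def annual_fixed_cost(self) -> float:
        """Annualised line CapEx plus annual operating cost, USD/yr."""
        return self.capex_usd * self.annual_fixed_frac + self.operating_usd_per_year


def ff_annual_doses(spec: FillFinishSpec) -> float:
    """Annual dose throughput of one fill-finish line."""
    return (
        spec.containers_per_minute
        * spec.oee
        * spec.operating_minutes
        * spec.doses_per_container
    )


def bottleneck(ds_rate, ff_rate):
    """Locate the limiting stage of a combined DS + fill-finish train.

    Returns ``(stage, limiting_rate)`` where stage is ``"DS"`` or
    ``"fill-finish"``; ties go to DS by convention.  Accepts scalars or
    arrays (arrays return a boolean-labelled stage array).
    """
    ds = np.asarray(ds_rate, dtype=float)
    ff = np.asarray(ff_rate, dtype=float)
    if np.any(ds < 0) or np.any(ff < 0):
        raise ParameterError("rates must be non-negative")
    limiting = np.minimum(ds, ff)
    stage = np.where(ds <= ff, "DS", "fill-finish")
    if limiting.ndim == 0:
        return str(stage), float(limiting)
    return stage, limiting


def ff_cost_per_dose(spec: FillFinishSpec, doses_filled: float | None = None) -> float:
    """Fill-to-finish cost per dose.

    ``doses_filled`` is the annual dose flow actually put through the line
    (default: the line's own capacity).  Fixed line costs are spread over
    that flow; container consumables scale with it.  Returns ``inf`` for a
    zero flow (undefined, flagged by the caller).
    """
    capacity = ff_annual_doses(spec)
    doses = capacity if doses_filled is None else float(doses_filled)
    if doses <= 0:
        return float("inf")
    containers = doses / spec.doses_per_container
    return (spec.annual_fixed_cost + containers * spec.cost_per_container) / doses
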
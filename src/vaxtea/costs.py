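"""Cost model: CapEx, fixed and variable OpEx, cost per dose.

CapEx follows a power law in bioreactor working volume (the classic
six-tenths rule by default), calibrated per platform against published
facility-investment anchors.  Annualised CapEx (straight-line over ten
years plus a maintenance percentage) is folded into fixed OpEx together
with labour (crew x basic labour rate x staffed hours), the QC/QA charge
(a sampled percentage of labour cost) and a facility overhead proportional
to CapEx.  Variable OpEx is materials and consumables and accrues over
batch *starts* — a failed cGMP batch consumes its raw materials before it
is rejected.

RNA materials are costed per gram of RNA synthesised (5' cap analogue at
its sampled price plus a lumped term for nucleotides, plasmid template,
enzymes and LNP lipids); AVV materials are costed per litre of cell
culture per batch (media, consumables, resins).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PlatformConfig
from .factors import ParameterError, ScenarioSet

__all__ = ["capex", "annualised_capex", "opex", "cost_per_dose"]


def capex(scale, cfg: PlatformConfig):
    """Capital investment of one production line at the given working volume."""
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ParameterError("scale must be positive")
    out = cfg.capex_ref_usd * (scale / cfg.capex_ref_scale_l) ** cfg.capex_exponent
    return out if out.ndim else float(out)


def annualised_capex(capex_usd, cfg: PlatformConfig):
    """Annual CapEx charge folded into fixed OpEx (depreciation + maintenance)."""
    return np.asarray(capex_usd, dtype=float) * cfg.capex_annual_frac


def _materials(df: pd.DataFrame, amount_started, starts, cfg: PlatformConfig):
    if cfg.materials_kind == "per_gram":
        per_g = cfg.materials_other_usd_per_g + cfg.cap_usage_g_per_g * df[
            "cap_price"
        ].to_numpy(dtype=float)
        return per_g * np.asarray(amount_started, dtype=float)
    # per_litre_batch (AVV): media/consumables scale with culture volume
    return (
        cfg.materials_usd_per_litre_batch
        * df["scale"].to_numpy(dtype=float)
        * np.asarray(starts, dtype=float)
    )


def opex(scenarios, output: pd.DataFrame, cfg: PlatformConfig) -> pd.DataFrame:
    """Cost structure for every scenario.

    Returns columns ``capex``, ``opex_fixed``, ``opex_variable``,
    ``opex_total`` and ``cost_per_dose`` (``inf`` where annual output is
    zero).  ``opex_total = opex_fixed + opex_variable`` holds exactly.
    """
    df = scenarios.values if isinstance(scenarios, ScenarioSet) else scenarios
    cap = capex(df["scale"].to_numpy(dtype=float), cfg)
    labour = (
        cfg.crew_per_line
        * df["labour_rate"].to_numpy(dtype=float)
        * cfg.staffed_hours
        * cfg.parallel_lines
    )
    qc = df["qc_pct"].to_numpy(dtype=float) / 100.0
    fixed = annualised_capex(cap, cfg) + cfg.overhead_frac * cap + labour * (1.0 + qc)

    starts = output["batches_started"].to_numpy(dtype=float)
    amount_started = output["amount_per_batch"].to_numpy(dtype=float) * starts
    variable = _materials(df, amount_started, starts, cfg)

    total = fixed + variable
    dpy = output["doses_per_year"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "capex": np.broadcast_to(cap, dpy.shape).astype(float),
            "opex_fixed": fixed,
            "opex_variable": variable,
            "opex_total": total,
            "cost_per_dose": cost_per_dose(total, dpy),
        },
        index=df.index,
    )


def cost_per_dose(opex_total, doses_per_year):
    """USD per dose of drug substance; ``inf`` (flagged undefined) at zero output."""
    total = np.asarray(opex_total, dtype=float)
    dpy = np.asarray(doses_per_year, dtype=float)
    out = np.where(dpy > 0, total / np.where(dpy > 0, dpy, 1.0), np.inf)
    return out if out.ndim else float(out)
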
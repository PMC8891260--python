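"""Lumped batch production model.

Maps a scenario (scale, titre, failure rate, dose amount) plus the
platform's scheduling calibration (batch cycle time, operating days,
parallel lines) to physical output KPIs: batches started and released per
year, drug-substance amount per batch and per year, doses per batch and
per year, specific productivity (doses per litre of bioreactor working
volume per year) and the time needed to reach a dose target.

Batch failure discards whole lots: a failed batch consumes its materials
(see ``costs``) but contributes no product.  Fractional batch counts and
fractional years are campaign averages; no integer rounding is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PlatformConfig
from .factors import ParameterError, ScenarioSet

__all__ = ["batches_per_year", "amount_per_batch", "annual_output", "time_to_dose_target"]


def batches_per_year(cfg: PlatformConfig) -> float:
    """Batch starts per year on the platform's production line(s)."""
    if cfg.batch_cycle_days <= 0:
        raise ParameterError("batch cycle time must be positive")
    return cfg.operating_days / cfg.batch_cycle_days * cfg.parallel_lines


def amount_per_batch(scale, titre):
    """Drug substance per released batch: working volume x net titre.

    The titre is net of downstream recovery losses, so no further loss
    factor applies.
    """
    scale = np.asarray(scale, dtype=float)
    titre = np.asarray(titre, dtype=float)
    if np.any(scale <= 0) or np.any(titre < 0):
        raise ParameterError("scale must be positive and titre non-negative")
    out = scale * titre
    return out if out.ndim else float(out)


def _frame(scenarios) -> pd.DataFrame:
    return scenarios.values if isinstance(scenarios, ScenarioSet) else scenarios


def annual_output(scenarios, cfg: PlatformConfig) -> pd.DataFrame:
    """Physical production KPIs for every scenario in the design.

    Returns a DataFrame aligned with the scenario table, with columns
    ``batches_started``, ``batches_released``, ``amount_per_batch``,
    ``amount_per_year`` (released product), ``doses_per_batch``,
    ``doses_per_year`` and ``specific_productivity``.  Amounts are in grams
    for the RNA platforms and viral particles for AVV.
    """
    df = _frame(scenarios)
    dose = df["dose_amount"].to_numpy(dtype=float) * cfg.dose_unit_scale
    if np.any(dose <= 0):
        raise ParameterError("dose amount must be positive")
    failure = df["failure_pct"].to_numpy(dtype=float) / 100.0
    scale = df["scale"].to_numpy(dtype=float)

    starts = batches_per_year(cfg)
    released = starts * (1.0 - failure)
    per_batch = amount_per_batch(scale, df["titre"].to_numpy(dtype=float))
    per_year = per_batch * released
    doses_per_batch = per_batch / dose
    doses_per_year = per_year / dose

    return pd.DataFrame(
        {
            "batches_started": np.full(len(df), starts, dtype=float),
            "batches_released": released,
            "amount_per_batch": per_batch,
            "amount_per_year": per_year,
            "doses_per_batch": doses_per_batch,
            "doses_per_year": doses_per_year,
            "specific_productivity": doses_per_year / scale,
        },
        index=df.index,
    )


def time_to_dose_target(doses_per_year, target: float):
    """Years of campaign time to reach ``target`` doses of drug substance.

    QC lead times are excluded.  Scenarios with zero annual output are
    undefined and returned as ``inf`` (callers flag these explicitly).
    """
    if target <= 0:
        raise ParameterError("dose target must be positive")
    rate = np.asarray(doses_per_year, dtype=float)
    with np.errstate(divide="ignore"):
        years = np.where(rate > 0, target / np.where(rate > 0, rate, 1.0), np.inf)
    return years if years.ndim else float(years)
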
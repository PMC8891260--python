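"""Platform configuration: factor sets, calibration constants, fill-finish lines.

All numbers that are not first-principles arithmetic live in one packaged
YAML file (``data/platforms.yaml``): the uncertainty ranges of the input
factors, the lumped batch-scheduling constants (cycle time, operating
days), the cost-model constants (reference CapEx, scaling exponent,
annualisation, crew sizes, material unit costs) and the fill-to-finish
line specifications.  The calibration constants were fixed once so that
the model's baseline and design-median outputs land on published
industrial anchor values, and are deliberately kept out of the code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .factors import InputFactorSpec, ParameterError, PlatformFactorSet
from .fillfinish import FillFinishSpec

__all__ = ["PlatformConfig", "Config", "load_config", "PLATFORMS"]

PLATFORMS = ("avv", "mrna", "sarna")


@dataclass(frozen=True)
class PlatformConfig:
    """Calibrated lumped-model constants for one platform."""

    platform: str
    factor_set: PlatformFactorSet
    # scheduling
    batch_cycle_days: float
    operating_days: float
    parallel_lines: float
    # amount bookkeeping: grams per dose-unit (1e-6 for µg doses, 1 for vp)
    dose_unit_scale: float
    amount_units: str
    # cost model
    crew_per_line: float
    staffed_hours: float  # annual staffed coverage hours per crew member
    capex_ref_usd: float
    capex_ref_scale_l: float
    capex_exponent: float
    annualisation_years: float
    maintenance_frac: float
    overhead_frac: float
    materials_kind: str  # "per_gram" | "per_litre_batch"
    materials_other_usd_per_g: float = 0.0
    cap_usage_g_per_g: float = 0.0
    materials_usd_per_litre_batch: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_cycle_days <= 0:
            raise ParameterError("batch_cycle_days must be positive")
        if not 0 < self.operating_days <= 365:
            raise ParameterError("operating_days must be in (0, 365]")
        if self.materials_kind not in ("per_gram", "per_litre_batch"):
            raise ParameterError(f"unknown materials kind {self.materials_kind!r}")

    @property
    def capex_annual_frac(self) -> float:
        """Annualised CapEx charge: straight-line depreciation + maintenance."""
        return 1.0 / self.annualisation_years + self.maintenance_frac


@dataclass(frozen=True)
class Config:
    platforms: dict
    fill_finish: dict
    config_hash: str

    def platform(self, name: str) -> PlatformConfig:
        key = name.lower()
        if key not in self.platforms:
            raise ParameterError(f"unknown platform {name!r}; expected one of {PLATFORMS}")
        return self.platforms[key]

    def fill_finish_spec(self, name: str) -> FillFinishSpec:
        if name not in self.fill_finish:
            raise ParameterError(
                f"unknown fill-finish technology {name!r}; "
                f"expected one of {sorted(self.fill_finish)}"
            )
        return self.fill_finish[name]


def _factor(row: dict) -> InputFactorSpec:
    return InputFactorSpec(
        name=row["name"],
        units=row["units"],
        dist=row["dist"],
        low=float(row["low"]),
        high=float(row["high"]),
        mode=float(row["mode"]) if "mode" in row else None,
    )


def load_config(path: str | Path | None = None) -> Config:
    """Load the packaged platform configuration, or a user-supplied YAML."""
    if path is None:
        text = resources.files("vaxtea.data").joinpath("platforms.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cfg_hash = hashlib.sha256(text.encode()).hexdigest()[:16]

    shared = raw.get("shared", {})
    platforms = {}
    for name, p in raw["platforms"].items():
        factors = PlatformFactorSet(platform=name, factors=[_factor(r) for r in p["factors"]])
        mats = p["materials"]
        platforms[name] = PlatformConfig(
            platform=name,
            factor_set=factors,
            batch_cycle_days=float(p["batch_cycle_days"]),
            operating_days=float(p.get("operating_days", shared.get("operating_days", 330))),
            parallel_lines=float(p.get("parallel_lines", 1)),
            dose_unit_scale=float(p["dose_unit_scale"]),
            amount_units=p["amount_units"],
            crew_per_line=float(p["crew_per_line"]),
            staffed_hours=float(p.get("staffed_hours", shared.get("staffed_hours", 8760))),
            capex_ref_usd=float(p["capex_ref_musd"]) * 1e6,
            capex_ref_scale_l=float(p["capex_ref_scale_l"]),
            capex_exponent=float(p.get("capex_exponent", shared.get("capex_exponent", 0.6))),
            annualisation_years=float(shared.get("annualisation_years", 10)),
            maintenance_frac=float(shared.get("maintenance_frac", 0.04)),
            overhead_frac=float(shared.get("overhead_frac", 0.02)),
            materials_kind=mats["kind"],
            materials_other_usd_per_g=float(mats.get("other_usd_per_g", 0.0)),
            cap_usage_g_per_g=float(mats.get("cap_usage_g_per_g", 0.0)),
            materials_usd_per_litre_batch=float(mats.get("usd_per_litre_batch", 0.0)),
        )

    fill = {}
    for name, f in raw["fill_finish"].items():
        fill[name] = FillFinishSpec(
            technology=f["technology"],
            doses_per_container=int(f["doses_per_container"]),
            containers_per_minute=float(f["containers_per_minute"]),
            oee=float(f["oee"]),
            operating_minutes=float(f.get("operating_minutes", 525600)),
            cost_per_container=float(f["cost_per_container"]),
            capex_usd=float(f["capex_musd"]) * 1e6,
            operating_usd_per_year=float(f["operating_musd_per_year"]) * 1e6,
            annual_fixed_frac=float(shared.get("annualisation_years", 10)) ** -1
            + float(shared.get("maintenance_frac", 0.04)),
        )

    return Config(platforms=platforms, fill_finish=fill, config_hash=cfg_hash)
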
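"""Pipeline orchestration, distribution summaries and artifact I/O.

``run_pipeline`` executes the full chain for one platform — quasi-random
scenario design, production and cost KPIs, Sobol sensitivity indices and
capacity projections — deterministically for a given (config, n, seed),
and writes CSV/JSON artifacts with a manifest recording the config hash
and seeds so a run can be reproduced exactly.

Distributions are summarised by their median and interquartile range
computed on the *full* sample, matching the study's reporting convention;
the optional 5%/95% trimming applies only to plotting exports.  Quantiles
use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsa as gsa_mod
from .config import Config, load_config
from .factors import ParameterError, build_scenarios
from .kpis import KPI_COLUMNS, baseline_cost_per_dose, compute_kpis
from .projection import DEFAULT_TARGETS, project_resources

__all__ = ["DistributionSummary", "summarize", "trimmed", "run_pipeline", "run_gsa"]

log = logging.getLogger("vaxtea")

#: default fill-finish pairing per platform (10-dose vials for AVV,
#: 5-dose vials for the RNA platforms)
DEFAULT_FILL_FINISH = {"avv": "vial10", "mrna": "vial5", "sarna": "vial5"}


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    q25: float
    q75: float
    p5: float
    p95: float
    n: int
    trimmed_flag: bool = False


def summarize(samples, trim: bool = False) -> DistributionSummary:
    """Median/IQR/percentile summary of a KPI distribution.

    Medians and quartiles are always computed on the full sample; ``trim``
    only marks that plotting exports drop the outer 5% tails.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ParameterError(f"need at least 20 samples, got {x.size}")
    p5, q25, med, q75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
    return DistributionSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        p5=float(p5), p95=float(p95), n=int(x.size), trimmed_flag=bool(trim),
    )


def trimmed(samples) -> np.ndarray:
    """Drop the bottom and top 5% of values (plotting exports only)."""
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[np.isfinite(x)]
    lo, hi = np.percentile(x, [5, 95])
    return x[(x >= lo) & (x <= hi)]


def run_gsa(
    platform: str,
    config: Config,
    n_base: int = 1024,
    seed: int | None = 0,
    kpi_columns=None,
    n_boot: int = 200,
):
    """Sobol indices of every input factor on every KPI for one platform."""
    pcfg = config.platform(platform)
    d = pcfg.factor_set.dimension
    design = gsa_mod.saltelli_design(n_base, d, scramble=seed is not None, seed=seed)

    def evaluate(u):
        scen = pcfg.factor_set.transform(u)
        return compute_kpis(scen, pcfg)

    kpi_a = evaluate(design.a)
    kpi_b = evaluate(design.b)
    kpi_ab = [evaluate(m) for m in design.ab]

    results = {}
    for col in kpi_columns or KPI_COLUMNS:
        results[col] = gsa_mod.sobol_indices(
            kpi_a[col].to_numpy(),
            kpi_b[col].to_numpy(),
            np.vstack([k[col].to_numpy() for k in kpi_ab]),
            n_boot=n_boot,
            seed=0 if seed is None else seed,
            factor_names=pcfg.factor_set.names,
        )
    return results


def _gsa_frame(results: dict, platform: str) -> pd.DataFrame:
    rows = []
    for kpi, res in results.items():
        frame = res.to_frame()
        frame.insert(0, "kpi", kpi)
        frame.insert(0, "platform", platform)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(
    platform: str,
    config: Config | None = None,
    n_scenarios: int = 10_000,
    seed: int | None = 0,
    out_dir: str | Path | None = None,
    targets=DEFAULT_TARGETS,
    fill_finish: str | None = None,
    gsa_n_base: int = 1024,
    run_sensitivity: bool = True,
) -> dict:
    """End-to-end run for one platform; deterministic given (config, n, seed).

    Returns a dict with the ScenarioSet, the KPI table, per-target
    projection tables, KPI summaries, Sobol results and the manifest.
    When ``out_dir`` is given all artifacts are also written to disk.
    """
    t0 = time.time()
    config = config or load_config()
    pcfg = config.platform(platform)
    ff_name = fill_finish or DEFAULT_FILL_FINISH[platform.lower()]
    ff_spec = None if ff_name == "none" else config.fill_finish_spec(ff_name)

    scen = build_scenarios(
        pcfg.factor_set, n_scenarios, scramble=seed is not None, seed=seed
    )
    kpis = compute_kpis(scen, pcfg)
    n_undefined = int((~np.isfinite(kpis["cost_per_dose"])).sum())
    if n_undefined:
        log.warning("%s: %d scenarios with undefined KPIs", platform, n_undefined)

    projections = {
        float(t): project_resources(scen, pcfg, t, ff_spec=ff_spec) for t in targets
    }
    summaries = {
        col: asdict(summarize(kpis[col])) for col in kpis.columns
    }
    baseline = (
        baseline_cost_per_dose(pcfg, ff_spec) if ff_spec is not None else None
    )

    sobol = None
    if run_sensitivity:
        sobol = run_gsa(platform, config, n_base=gsa_n_base, seed=seed)

    manifest = {
        "platform": platform,
        "n_scenarios": n_scenarios,
        "seed": seed,
        "config_hash": config.config_hash,
        "scenario_metadata": {k: str(v) for k, v in scen.metadata.items()},
        "targets": [float(t) for t in targets],
        "fill_finish": ff_name,
        "gsa_n_base": gsa_n_base if run_sensitivity else None,
        "elapsed_s": None,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scen.to_csv(out / f"{platform}_scenarios.csv")
        kpis.to_csv(out / f"{platform}_kpis.csv", index=False)
        for t, proj in projections.items():
            proj.to_csv(out / f"{platform}_projection_{t:.3g}.csv", index=False)
        with open(out / f"{platform}_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=2)
        if baseline is not None:
            with open(out / f"{platform}_baseline.json", "w") as fh:
                json.dump(baseline, fh, indent=2)
        if sobol is not None:
            _gsa_frame(sobol, platform).to_csv(
                out / f"{platform}_sobol_indices.csv", index=False
            )

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    if out_dir is not None:
        with open(Path(out_dir) / f"{platform}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    log.info("%s pipeline: n=%d in %.2fs", platform, n_scenarios, manifest["elapsed_s"])

    return {
        "scenarios": scen,
        "kpis": kpis,
        "projections": projections,
        "summaries": summaries,
        "baseline": baseline,
        "sobol": sobol,
        "manifest": manifest,
    }
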
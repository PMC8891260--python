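"""Uncertain input factors and quasi-random scenario generation.

The uncertainty model of each vaccine platform consists of six (AVV) or
seven (mRNA, saRNA) independent input factors, each described by a
triangular or a uniform distribution over its plausible engineering range:
production scale, batch failure rate, bioreactor titre (net of downstream
recovery losses), 5' cap analogue purchase price (RNA platforms only),
basic labour rate, drug-substance amount per dose, and QC/QA cost as a
percentage of labour cost.  Factors with a well-supported most-likely value
are triangular with that value as the mode; failure rate and QC cost, for
which no value is more credible than another, are uniform.

Scenario matrices are produced by mapping a Sobol low-discrepancy point set
through each factor's inverse CDF, column by column.  A design of n
scenarios built this way fills the factor space far more evenly than
pseudo-random sampling, which speeds up the convergence of the medians,
interquartile ranges and variance-based sensitivity indices computed
downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ParameterError",
    "InputFactorSpec",
    "PlatformFactorSet",
    "ScenarioSet",
    "triangular_inverse_cdf",
    "uniform_inverse_cdf",
    "sobol_points",
    "build_scenarios",
    "central_scenario",
]


class ParameterError(ValueError):
    """Invalid distribution or model parameters."""


def triangular_inverse_cdf(low, mode, high, u):
    """Quantile function of the triangular distribution on [low, high].

    Parameters
    ----------
    low, mode, high
        Distribution support and mode, ``low <= mode <= high``, ``low < high``.
    u
        Probability level(s) in [0, 1]; scalar or array.

    Returns
    -------
    The u-quantile; monotone non-decreasing in ``u``.
    """
    if not (low <= mode <= high) or not (low < high):
        raise ParameterError(
            f"triangular requires low <= mode <= high and low < high, "
            f"got ({low}, {mode}, {high})"
        )
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ParameterError("u must lie in [0, 1]")
    fc = (mode - low) / (high - low)  # CDF value at the mode
    left = low + np.sqrt(np.clip(u, 0, None) * (high - low) * (mode - low))
    right = high - np.sqrt(np.clip(1 - u, 0, None) * (high - low) * (high - mode))
    x = np.where(u < fc, left, right)
    return x if x.ndim else float(x)


def uniform_inverse_cdf(low, high, u):
    """Quantile function of the uniform distribution on [low, high]."""
    if not low < high:
        raise ParameterError(f"uniform requires low < high, got ({low}, {high})")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ParameterError("u must lie in [0, 1]")
    x = low + u * (high - low)
    return x if x.ndim else float(x)


@dataclass(frozen=True)
class InputFactorSpec:
    """One uncertain input factor of a platform's techno-economic model."""

    name: str
    units: str
    dist: str  # "triangular" | "uniform"
    low: float
    high: float
    mode: float | None = None

    def __post_init__(self) -> None:
        if self.dist not in ("triangular", "uniform"):
            raise ParameterError(f"unknown distribution kind {self.dist!r}")
        if not self.low < self.high:
            raise ParameterError(f"{self.name}: low must be < high")
        if self.dist == "triangular":
            if self.mode is None:
                raise ParameterError(f"{self.name}: triangular factor needs a mode")
            if not (self.low <= self.mode <= self.high):
                raise ParameterError(f"{self.name}: mode outside [low, high]")
        elif self.mode is not None:
            raise ParameterError(f"{self.name}: uniform factor takes no mode")

    def ppf(self, u):
        """Map probability levels to factor values through the inverse CDF."""
        if self.dist == "triangular":
            return triangular_inverse_cdf(self.low, self.mode, self.high, u)
        return uniform_inverse_cdf(self.low, self.high, u)

    @property
    def mean(self) -> float:
        if self.dist == "triangular":
            return (self.low + self.mode + self.high) / 3.0
        return (self.low + self.high) / 2.0


@dataclass(frozen=True)
class PlatformFactorSet:
    """Ordered factor list of one platform; order is fixed because GSA
    indices are reported per factor position."""

    platform: str
    factors: tuple[InputFactorSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate factor names")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def dimension(self) -> int:
        return len(self.factors)

    def transform(self, u_matrix: np.ndarray) -> pd.DataFrame:
        """Map an (n, d) unit-hypercube matrix through the factor inverse CDFs."""
        u = np.atleast_2d(np.asarray(u_matrix, dtype=float))
        if u.shape[1] != self.dimension:
            raise ParameterError(
                f"expected {self.dimension} columns, got {u.shape[1]}"
            )
        cols = {f.name: f.ppf(u[:, j]) for j, f in enumerate(self.factors)}
        return pd.DataFrame(cols)


def sobol_points(
    n: int,
    d: int,
    skip: int = 1,
    scramble: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Sobol low-discrepancy point set in [0, 1)^(n x d).

    The first ``skip`` points of the sequence are discarded (default 1: the
    unscrambled sequence starts at the all-zeros corner, a degenerate
    scenario).  With ``scramble=True`` the sequence is Owen-scrambled and
    ``seed`` makes the scrambling reproducible.
    """
    if n < 1 or d < 1:
        raise ParameterError("n and d must be >= 1")
    try:
        sampler = qmc.Sobol(d=d, scramble=scramble, seed=seed)
    except ValueError as exc:  # dimension beyond available direction numbers
        raise ParameterError(str(exc)) from exc
    with warnings.catch_warnings():
        # non-power-of-two sample sizes trade a little balance for the exact
        # design size requested; that is intentional here
        warnings.simplefilter("ignore", UserWarning)
        if skip:
            sampler.fast_forward(skip)
        pts = sampler.random(n)
    return pts


@dataclass
class ScenarioSet:
    """A realized quasi-random design: n scenarios x d factors."""

    platform: str
    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return self.n

    def to_csv(self, path) -> None:
        """Write the design with a '#'-prefixed metadata header block."""
        buf = io.StringIO()
        buf.write(f"# platform: {self.platform}\n")
        for key, val in sorted(self.metadata.items()):
            buf.write(f"# {key}: {val}\n")
        self.values.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ScenarioSet":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
        platform = meta.pop("platform", "unknown")
        values = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        return cls(platform=platform, values=values, metadata=meta)


def build_scenarios(
    factor_set: PlatformFactorSet,
    n: int,
    skip: int = 1,
    scramble: bool = False,
    seed: int | None = None,
    u: np.ndarray | None = None,
) -> ScenarioSet:
    """Build a quasi-random ScenarioSet for one platform.

    Each column of the Sobol matrix is mapped through the corresponding
    factor's inverse CDF, preserving the fixed factor order.  ``u`` may be
    supplied directly (e.g. a Saltelli block, or a forced central point) in
    which case the generator metadata records it as external.
    """
    if u is None:
        u = sobol_points(n, factor_set.dimension, skip=skip, scramble=scramble, seed=seed)
        meta = {
            "sequence": "sobol",
            "n": n,
            "skip": skip,
            "scramble": scramble,
            "seed": seed if seed is not None else "",
        }
    else:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        meta = {"sequence": "external", "n": len(u), "skip": 0, "scramble": False, "seed": ""}
    return ScenarioSet(
        platform=factor_set.platform,
        values=factor_set.transform(u),
        metadata=meta,
    )


def central_scenario(factor_set: PlatformFactorSet) -> pd.DataFrame:
    """The baseline scenario: each triangular factor at its mode (the
    most-likely value) and each uniform factor at its range midpoint."""
    vals = {
        f.name: [f.mode if f.dist == "triangular" else 0.5 * (f.low + f.high)]
        for f in factor_set.factors
    }
    return pd.DataFrame(vals)
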
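"""Variance-based global sensitivity analysis.

First-order (Si) and total-effect (St) Sobol indices quantify the fraction
of a KPI's variance explained by each input factor alone and including all
its interactions.  Estimation uses the standard pick-freeze design: two
independent quasi-random blocks A and B of N scenarios each, plus d cross
blocks AB_i in which column i of A is replaced by B's, for N(d+2) model
evaluations in total.  The Jansen (1999) estimators are used for both
indices — the lowest-variance choices among the common forms:

    Si = 1 - mean((Y_B - Y_ABi)^2) / (2 V)
    St =     mean((Y_A - Y_ABi)^2) / (2 V)

with V the output variance over the A and B blocks.  Confidence intervals
come from a seeded percentile bootstrap over design rows.

An RS-HDMR (random-sampling high-dimensional model representation)
metamodel is provided as a fast surrogate: an additive expansion
f0 + sum_i f_i(x_i), optionally with second-order terms, in orthonormal
shifted-Legendre polynomials on each factor's unit-interval image, fitted
by least squares.  Component-function variances yield metamodel-based
sensitivity indices, and predictive quality is reported as R^2 on held-out
scenarios never used in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .factors import ParameterError, sobol_points

__all__ = [
    "GsaDesign",
    "SobolResult",
    "MetamodelFit",
    "saltelli_design",
    "sobol_indices",
    "additivity_gap",
    "fit_rshdmr",
]


@dataclass(frozen=True)
class GsaDesign:
    """Pick-freeze design: base blocks A, B (N x d) and cross blocks AB_i."""

    a: np.ndarray
    b: np.ndarray
    ab: tuple  # d arrays, each N x d

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def d(self) -> int:
        return self.a.shape[1]

    @property
    def n_evaluations(self) -> int:
        return self.n * (self.d + 2)

    def all_points(self) -> np.ndarray:
        """All N(d+2) unit-cube points stacked: A, B, AB_1..AB_d."""
        return np.vstack([self.a, self.b, *self.ab])


def saltelli_design(
    n: int, d: int, skip: int = 1, scramble: bool = False, seed: int | None = None
) -> GsaDesign:
    """Build the N(d+2)-evaluation pick-freeze design in [0,1)^d.

    A and B are disjoint column blocks of a single 2d-dimensional Sobol
    stream, which preserves the joint low-discrepancy structure; AB_i is A
    with column i substituted from B.
    """
    if n < 2:
        raise ParameterError("base sample count must be >= 2")
    joint = sobol_points(n, 2 * d, skip=skip, scramble=scramble, seed=seed)
    a, b = joint[:, :d].copy(), joint[:, d:].copy()
    ab = []
    for i in range(d):
        m = a.copy()
        m[:, i] = b[:, i]
        ab.append(m)
    return GsaDesign(a=a, b=b, ab=tuple(ab))


@dataclass
class SobolResult:
    """Per-factor first-order and total-effect indices with bootstrap CIs."""

    si: np.ndarray
    st: np.ndarray
    si_ci: np.ndarray  # (d, 2) percentile bounds
    st_ci: np.ndarray
    si_se: np.ndarray  # bootstrap standard errors
    st_se: np.ndarray
    variance: float
    defined: bool = True
    factor_names: list = field(default_factory=list)

    def to_frame(self, clip_negative: bool = False) -> pd.DataFrame:
        """Tidy table; negative estimates are clipped to 0 only for display."""
        si, st = self.si, self.st
        if clip_negative:
            si, st = np.clip(si, 0, None), np.clip(st, 0, None)
        names = self.factor_names or [f"x{i + 1}" for i in range(len(si))]
        return pd.DataFrame(
            {
                "factor": names,
                "Si": si,
                "Si_lo": self.si_ci[:, 0],
                "Si_hi": self.si_ci[:, 1],
                "St": st,
                "St_lo": self.st_ci[:, 0],
                "St_hi": self.st_ci[:, 1],
            }
        )


def _jansen(ya: np.ndarray, yb: np.ndarray, yab: np.ndarray):
    """Jansen estimators over stacked blocks; yab has shape (d, N)."""
    both = np.concatenate([ya, yb])
    v = both.var()
    si = 1.0 - np.mean((yb[None, :] - yab) ** 2, axis=1) / (2.0 * v)
    st = np.mean((ya[None, :] - yab) ** 2, axis=1) / (2.0 * v)
    return si, st, v


def sobol_indices(
    y_a,
    y_b,
    y_ab,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    factor_names: list | None = None,
) -> SobolResult:
    """Estimate Si and St from model outputs over a pick-freeze design.

    ``y_ab`` is a sequence of d output vectors (one per cross block).  A
    constant output (zero variance) has undefined indices and is returned
    flagged with ``defined=False`` and NaN indices.
    """
    ya = np.asarray(y_a, dtype=float)
    yb = np.asarray(y_b, dtype=float)
    yab = np.asarray(y_ab, dtype=float)
    if yab.ndim != 2 or yab.shape[1] != ya.size or yb.size != ya.size:
        raise ParameterError("inconsistent output block shapes")
    d, n = yab.shape

    v = np.concatenate([ya, yb]).var()
    if v <= 0 or not np.isfinite(v):
        nan = np.full(d, np.nan)
        return SobolResult(
            si=nan, st=nan.copy(), si_ci=np.full((d, 2), np.nan),
            st_ci=np.full((d, 2), np.nan), si_se=nan.copy(), st_se=nan.copy(),
            variance=float(v), defined=False, factor_names=factor_names or [],
        )

    si, st, v = _jansen(ya, yb, yab)

    rng = np.random.default_rng(seed)
    si_b = np.empty((n_boot, d))
    st_b = np.empty((n_boot, d))
    block = 100  # bootstrap in blocks to bound memory at large N
    for start in range(0, n_boot, block):
        stop = min(start + block, n_boot)
        idx = rng.integers(0, n, size=(stop - start, n))
        for k, row in enumerate(idx):
            si_b[start + k], st_b[start + k], _ = _jansen(ya[row], yb[row], yab[:, row])
    alpha = (1.0 - ci_level) / 2.0
    return SobolResult(
        si=si,
        st=st,
        si_ci=np.quantile(si_b, [alpha, 1 - alpha], axis=0).T,
        st_ci=np.quantile(st_b, [alpha, 1 - alpha], axis=0).T,
        si_se=si_b.std(axis=0),
        st_se=st_b.std(axis=0),
        variance=float(v),
        defined=True,
        factor_names=factor_names or [],
    )


def additivity_gap(result: SobolResult) -> np.ndarray:
    """Per-factor interaction share St - Si.

    Gaps near zero for every factor indicate a predominantly additive
    (separable) model; a large gap marks a factor whose influence is
    mostly through interactions.
    """
    if not result.defined:
        raise ParameterError("indices undefined (constant output)")
    return result.st - result.si


# ---------------------------------------------------------------------------
# RS-HDMR metamodel


def _shifted_legendre(x: np.ndarray, order: int) -> np.ndarray:
    """Orthonormal shifted Legendre basis on [0, 1], orders 1..order.

    Orthonormal w.r.t. the uniform measure: E[phi_j phi_k] = delta_jk.
    """
    t = 2.0 * x - 1.0
    cols = []
    p_prev, p_curr = np.ones_like(t), t
    for k in range(1, order + 1):
        cols.append(np.sqrt(2 * k + 1) * p_curr)
        p_next = ((2 * k + 1) * t * p_curr - k * p_prev) / (k + 1)
        p_prev, p_curr = p_curr, p_next
    return np.column_stack(cols)


@dataclass
class MetamodelFit:
    """Fitted RS-HDMR expansion for one output."""

    f0: float
    coef: np.ndarray  # flattened first-order (+ second-order) coefficients
    max_order: int
    d: int
    include_pairs: bool
    si: np.ndarray  # metamodel-based first-order indices
    total_variance: float
    r2_validation: float | None = None

    def _design(self, x: np.ndarray) -> np.ndarray:
        blocks = [np.ones((len(x), 1))]
        per_factor = [_shifted_legendre(x[:, i], self.max_order) for i in range(self.d)]
        blocks.extend(per_factor)
        if self.include_pairs:
            p = min(2, self.max_order)  # tensor products up to quadratic per pair
            for i, j in combinations(range(self.d), 2):
                for a in range(p):
                    for b in range(p):
                        blocks.append(
                            (per_factor[i][:, a] * per_factor[j][:, b])[:, None]
                        )
        return np.hstack(blocks)

    def predict(self, x_unit) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x_unit, dtype=float))
        if x.shape[1] != self.d:
            raise ParameterError(f"expected {self.d} columns")
        coef = np.concatenate([[self.f0], self.coef])
        return self._design(x) @ coef

    def validate(self, x_unit, y) -> float:
        """R^2 on held-out scenarios; stored on the fit."""
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(x_unit)
        r2 = 1.0 - resid.var() / y.var()
        self.r2_validation = float(r2)
        return self.r2_validation


def fit_rshdmr(
    x_unit,
    y,
    max_order: int = 3,
    include_pairs: bool = False,
) -> MetamodelFit:
    """Fit the RS-HDMR polynomial expansion by least squares.

    ``x_unit`` are the design points on the unit hypercube (the Sobol
    matrix before inverse-CDF mapping), ``y`` the model outputs.  Requires
    at least 10x more scenarios than coefficients.  Because the basis is
    orthonormal under the uniform design measure, the constant term is the
    sample mean of y and each factor's component-function variance is the
    sum of its squared coefficients, giving metamodel-based Si directly.
    """
    x = np.atleast_2d(np.asarray(x_unit, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = x.shape
    if len(y) != n:
        raise ParameterError("x and y lengths differ")
    pair_terms = min(2, max_order) ** 2 * (d * (d - 1) // 2) if include_pairs else 0
    n_coef = 1 + d * max_order + pair_terms
    if n < 10 * n_coef:
        raise ParameterError(
            f"need >= {10 * n_coef} scenarios for {n_coef} coefficients, got {n}"
        )

    fit = MetamodelFit(
        f0=0.0, coef=np.zeros(n_coef - 1), max_order=max_order, d=d,
        include_pairs=include_pairs, si=np.zeros(d), total_variance=float(y.var()),
    )
    design = fit._design(x)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ParameterError(
            f"rank-deficient RS-HDMR design (rank {rank} < {design.shape[1]}); "
            "increase the sample size or lower the polynomial order"
        )
    fit.f0 = float(coef[0])
    fit.coef = coef[1:]

    first_order = coef[1 : 1 + d * max_order].reshape(d, max_order)
    var_i = (first_order**2).sum(axis=1)
    v = y.var()
    fit.si = var_i / v if v > 0 else np.full(d, np.nan)
    fit.total_variance = float(v)
    return fit
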
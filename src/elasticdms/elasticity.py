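"""Expression–growth elasticity model for an essential protein.

Growth rate is modeled as a hyperbolic (binding-curve) function of *net
function*, the product of relative expression level E and per-molecule
function F::

    G(E, F) = G_max * (E * F) / (E_m + E * F)

where ``G_max`` is the maximal growth rate and ``E_m`` the relative
expression strength that yields half-maximal growth for the wild-type
protein (F = 1).  An effective selection coefficient for a mutant is the
growth-rate ratio to wild type minus one,

    s = G(E, F) / G(E, 1) - 1,

and inverting that relationship gives per-molecule function from a measured
selection coefficient::

    F = (1 + s) * E_m / (E_m - s * E)

The model deliberately carries no cost-of-expression term: fitness
saturates at G_max as net function grows.

This module also holds the fits that produce the model's parameters — a
log-linear growth-rate fit to OD600 time courses (with cumulative-dilution
bookkeeping) and a bounded least-squares fit of (E, growth-rate) points to
the elasticity curve — plus the "informative function range" logic: the
window of per-molecule function a given promoter construct can actually
resolve, bounded below by its null-like cutoff and above by the point where
mutant growth comes within a small margin of the construct's wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ElasticityParams",
    "Construct",
    "FunctionRange",
    "GrowthCurve",
    "ElasticityFit",
    "ElasticityError",
    "InsufficientDataError",
    "FitConvergenceError",
    "BelowDetectionError",
    "UnboundedFunctionError",
    "EmptyRangeError",
    "growth_rate",
    "selection_from_function",
    "invert_function",
    "fit_growth_rate",
    "fit_elasticity",
    "function_range",
    "hidden_defect_threshold",
]


class ElasticityError(ValueError):
    """Base class for elasticity-model errors."""


class InsufficientDataError(ElasticityError):
    """Too few observations to perform a fit."""


class FitConvergenceError(ElasticityError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class BelowDetectionError(ElasticityError):
    """Selection coefficient at or below -1: function is at or below the
    null detection limit and cannot be inverted to a positive value."""


class UnboundedFunctionError(ElasticityError):
    """Implied growth exceeds what any finite function can produce
    (s >= E_m / E); per-molecule function is unbounded above."""


class EmptyRangeError(ElasticityError):
    """Construct's null cutoff sits above the WT-coupling margin, leaving
    no informative window."""


@dataclass(frozen=True)
class ElasticityParams:
    """Fitted parameters of the hyperbolic elasticity function.

    g_max : maximal growth rate (per hour)
    e_m   : relative expression strength giving half-maximal growth
            (dimensionless; endogenous expression = 1)
    """

    g_max: float
    e_m: float

    def __post_init__(self):
        if not self.g_max > 0:
            raise ElasticityError(f"g_max must be positive, got {self.g_max}")
        if not self.e_m > 0:
            raise ElasticityError(f"e_m must be positive, got {self.e_m}")


@dataclass
class Construct:
    """One promoter/terminator configuration of the rescue plasmid.

    name        : label, e.g. GPD, TEF, TEFdTer, CYC, CYCdTer, ADH, ADHdTer
    e           : relative expression strength used for function inference
                  (dimensionless; endogenous = 1)
    g_wt        : wild-type-sequence monoculture growth rate under this
                  construct (per hour)
    s_cut       : null-like selection-coefficient cutoff (<= 0)
    e_measured  : directly measured expression strength, where it differs
                  from the growth-derived value used for inference
    e_0         : expression at the start of the modeled competition window
    tau         : linear expression-increase rate (per hour, >= 0)
    timepoints  : hours in dextrose at which samples were sequenced
    """

    name: str
    e: float
    g_wt: float
    s_cut: float
    e_measured: float | None = None
    e_0: float | None = None
    tau: float | None = None
    timepoints: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.e > 0:
            raise ElasticityError(f"{self.name}: expression strength must be > 0")
        if self.s_cut > 0:
            raise ElasticityError(f"{self.name}: s_cut must be <= 0, got {self.s_cut}")
        if self.tau is not None and self.tau < 0:
            raise ElasticityError(f"{self.name}: tau must be >= 0")


@dataclass(frozen=True)
class FunctionRange:
    """Window of per-molecule function a construct resolves.

    ``upper`` is ``math.inf`` when the construct cannot distinguish
    near-wild-type function levels (reported as "lower and above").
    """

    construct_name: str
    lower: float
    upper: float

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.upper)


@dataclass
class GrowthCurve:
    """Monoculture OD600 time course with dilution bookkeeping.

    times               : hours since the dextrose switch, strictly increasing
    od                  : optical density at 600 nm, positive
    cumulative_dilution : multiplicative factor accumulated before each
                          reading (>= 1); effective density is od * dilution
    """

    times: np.ndarray
    od: np.ndarray
    cumulative_dilution: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.cumulative_dilution = np.asarray(self.cumulative_dilution, dtype=float)
        if not (len(self.times) == len(self.od) == len(self.cumulative_dilution)):
            raise ElasticityError("growth curve arrays must share a length")
        if np.any(np.diff(self.times) <= 0):
            raise ElasticityError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ElasticityError("OD readings must be positive")
        if np.any(self.cumulative_dilution < 1):
            raise ElasticityError("cumulative dilution must be >= 1")


@dataclass(frozen=True)
class ElasticityFit:
    """Result of fitting the elasticity curve to (E, growth-rate) points."""

    params: ElasticityParams
    rss: float
    n_points: int


def growth_rate(e: float, f: float, params: ElasticityParams) -> float:
    """Growth rate at expression ``e`` and per-molecule function ``f``.

    Hyperbolic in net function e*f; zero iff e*f = 0 and bounded above by
    ``params.g_max``.
    """
    if e < 0 or f < 0:
        raise ElasticityError(f"expression and function must be >= 0, got E={e}, F={f}")
    net = e * f
    return params.g_max * net / (params.e_m + net)


def selection_from_function(e: float, f: float, params: ElasticityParams) -> float:
    """Effective selection coefficient of a mutant with function ``f``.

    s = G(E, F) / G(E, 1) - 1; equals 0 at F = 1 and -1 at F = 0, and is
    strictly increasing in F.
    """
    if e <= 0:
        raise ElasticityError("selection coefficient undefined at zero expression")
    if f < 0:
        raise ElasticityError(f"function must be >= 0, got {f}")
    # Ratio form: G_max and one factor of E cancel.
    return f * (params.e_m + e) / (params.e_m + e * f) - 1.0


def invert_function(s: float, e: float, params: ElasticityParams) -> float:
    """Per-molecule function implied by selection coefficient ``s``.

    Exact inverse of :func:`selection_from_function`:
    F = (1 + s) * E_m / (E_m - s * E).

    Raises
    ------
    BelowDetectionError
        if s <= -1 (function at or below the null detection limit).
    UnboundedFunctionError
        if s >= E_m / E (no finite function produces that much growth).
    """
    if e <= 0:
        raise ElasticityError("cannot invert at zero expression")
    if s <= -1:
        raise BelowDetectionError(
            f"s={s} is at or below the null limit; function not identifiable"
        )
    denom = params.e_m - s * e
    if denom <= 0:
        raise UnboundedFunctionError(
            f"s={s} exceeds the maximum attainable at E={e} "
            f"(needs s < E_m/E = {params.e_m / e:.4g})"
        )
    return (1.0 + s) * params.e_m / denom


def fit_growth_rate(curve: GrowthCurve) -> float:
    """Least-squares growth rate from a monoculture OD time course.

    Slope of ln(od * cumulative_dilution) against time, in per-hour units.
    """
    if len(curve.times) < 3:
        raise InsufficientDataError(
            f"need >= 3 readings to fit a growth rate, got {len(curve.times)}"
        )
    y = np.log(curve.od * curve.cumulative_dilution)
    res = stats.linregress(curve.times, y)
    return float(res.slope)


def _elasticity_residuals(x, es, gs):
    g_max, e_m = x
    return g_max * es / (e_m + es) - gs


def fit_elasticity(points: Sequence[tuple[float, float]]) -> ElasticityFit:
    """Fit (E, growth-rate) points to G = G_max * E / (E_m + E).

    Bounded trust-region least squares.  Initialized with G_max at the
    largest observed growth rate and E_m at the E value whose growth rate
    is nearest half of that; positivity enforced through bounds; iteration
    capped at 500 residual evaluations with convergence on relative
    parameter change below 1e-10.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ElasticityError("points must be (E, growth_rate) pairs")
    es, gs = pts[:, 0], pts[:, 1]
    if len(np.unique(es)) < 3:
        raise InsufficientDataError("need >= 3 distinct expression strengths")
    g0 = float(np.max(gs))
    half_idx = int(np.argmin(np.abs(gs - g0 / 2)))
    em0 = max(float(es[half_idx]), 1e-6)
    res = optimize.least_squares(
        _elasticity_residuals,
        x0=[g0, em0],
        args=(es, gs),
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-10,
        max_nfev=500,
    )
    if not res.success:
        raise FitConvergenceError(
            f"elasticity fit did not converge: {res.message}", last_iterate=res.x
        )
    params = ElasticityParams(g_max=float(res.x[0]), e_m=float(res.x[1]))
    rss = float(np.sum(res.fun**2))
    return ElasticityFit(params=params, rss=rss, n_points=len(es))


def function_range(
    construct: Construct,
    params: ElasticityParams,
    wt_margin: float = 0.05,
    unbounded_cap: float = 0.8,
) -> FunctionRange:
    """Informative per-molecule-function window for one construct.

    The lower edge is the function level at the construct's null-like
    cutoff; the upper edge is the level at which a mutant grows within
    ``wt_margin`` of the construct's own wild type (s = -wt_margin) and is
    therefore indistinguishable from it.  When that upper edge reaches
    ``unbounded_cap`` the construct effectively resolves everything above
    the lower edge, and the range is reported as unbounded ("x and above").
    """
    if construct.s_cut >= -wt_margin:
        raise EmptyRangeError(
            f"{construct.name}: null cutoff {construct.s_cut} is not below the "
            f"WT margin -{wt_margin}; no informative window"
        )
    lower = invert_function(construct.s_cut, construct.e, params)
    try:
        upper = invert_function(-wt_margin, construct.e, params)
    except UnboundedFunctionError:
        upper = math.inf
    if upper >= unbounded_cap:
        upper = math.inf
    return FunctionRange(construct_name=construct.name, lower=lower, upper=upper)


def hidden_defect_threshold(
    params: ElasticityParams, e: float, growth_defect: float
) -> tuple[float, float]:
    """Largest functional defect hidden below a given growth defect.

    Returns ``(f_star, percent_hidden)`` where ``f_star`` solves
    s(E, F*) = -growth_defect and ``percent_hidden = (1 - F*) * 100``:
    any mutant retaining more than ``f_star`` of wild-type per-molecule
    function grows within ``growth_defect`` of wild type at expression
    strength ``e`` and its defect is invisible to fitness measurement.
    """
    if not 0 < growth_defect < 1:
        raise ElasticityError(f"growth defect must be in (0, 1), got {growth_defect}")
    f_star = invert_function(-growth_defect, e, params)
    return f_star, (1.0 - f_star) * 100.0
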
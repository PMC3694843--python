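"""Per-molecule function estimates across expression strengths.

A selection coefficient measured under one promoter construct maps to a
per-molecule function value through the inverted elasticity relation, but
only inside that construct's informative window: null-like variants give a
bound BELOW the window's lower edge, variants growing within the WT margin
give a bound ABOVE its upper edge, and everything in between gives a
number.  Combining constructs then yields, per amino-acid substitution, an
unweighted mean of the numeric estimates (bounds never enter the average)
or, failing any numeric estimate, the intersection of the bounds.

Downstream summaries live here too: cross-construct consistency (R^2
between neighbouring expression strengths), the solvent-surface vs core
position split, BLOSUM62 similarity-to-wild-type versus function, the
optional join against an external per-mutation stability (ddG) table, and
the histogram/classification of fitness- and function-effect
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from .elasticity import (
    Construct,
    ElasticityParams,
    FunctionRange,
    UnboundedFunctionError,
    function_range,
    invert_function,
)
from .selection import Klass

__all__ = [
    "Bound",
    "FunctionEstimate",
    "per_construct_function",
    "combine_across_constructs",
    "function_table",
    "cross_construct_consistency",
    "partition_surface_core",
    "blosum_similarity_table",
    "ddg_function_join",
    "dfe_histogram",
    "SURFACE_POSITIONS",
    "CORE_POSITIONS",
    "HIGH_FUNCTION_FLAG",
]

# Positions oriented toward solvent vs the protein core in the analyzed loop.
SURFACE_POSITIONS = frozenset({582, 583, 585})
CORE_POSITIONS = frozenset({584, 586, 587, 588, 589, 590})

# Numeric estimates above this are flagged: likely artifacts of assuming
# function is independent of expression level.
HIGH_FUNCTION_FLAG = 1.2

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Bound:
    """One-sided bound on per-molecule function: kind 'above' or 'below'."""

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("above", "below"):
            raise ValueError(f"bound kind must be 'above' or 'below', got {self.kind}")


@dataclass
class FunctionEstimate:
    """Combined per-molecule function for one amino-acid substitution.

    per_construct maps construct name to a numeric F (float), a Bound, or
    None (filtered/missing).  combined_f averages numeric entries only;
    when none exist, ``bound`` carries the intersection of the one-sided
    bounds.  ``inconsistent`` flags contradictory bounds or a combined
    value falling outside them; ``flag_high`` marks combined_f > 1.2.
    """

    position: int
    aa: str
    per_construct: dict[str, float | Bound | None] = field(default_factory=dict)
    combined_f: float | None = None
    sd_across_constructs: float | None = None
    n_numeric: int = 0
    bound: Bound | None = None
    inconsistent: bool = False
    flag_high: bool = False

    @property
    def aa_key(self) -> str:
        return f"{self.position}{self.aa}"


def per_construct_function(
    s: float,
    klass: Klass | str,
    construct: Construct,
    params: ElasticityParams,
    wt_margin: float = 0.05,
    unbounded_cap: float = 0.8,
) -> float | Bound | None:
    """Map one construct's selection estimate to function or a bound.

    FILTERED -> None; NULL_LIKE -> below the construct range's lower edge;
    s within the WT margin -> above the range's upper edge (the raw
    inversion value, which may exceed the reporting cap); otherwise the
    numeric inversion of the elasticity relation.
    """
    klass = Klass(klass)
    if klass is Klass.FILTERED:
        return None
    rng = function_range(construct, params, wt_margin=wt_margin, unbounded_cap=unbounded_cap)
    if klass is Klass.NULL_LIKE or s <= -1:
        return Bound("below", rng.lower)
    if s > -wt_margin:
        try:
            upper_raw = invert_function(-wt_margin, construct.e, params)
        except UnboundedFunctionError:
            upper_raw = math.inf
        return Bound("above", upper_raw)
    try:
        return invert_function(s, construct.e, params)
    except UnboundedFunctionError:
        return Bound("above", math.inf)


def combine_across_constructs(
    position: int, aa: str, per_construct: Mapping[str, float | Bound | None]
) -> FunctionEstimate:
    """Combine one substitution's per-construct entries.

    The combined value is the unweighted mean of numeric entries, with a
    population (ddof=0) standard deviation across constructs.  If only
    bounds exist, their intersection is reported: ABOVE max(above values)
    and/or BELOW min(below values).  Contradictions (intersection empty,
    or a combined value outside the surviving bounds) are flagged, never
    raised.
    """
    # Sorted so the average is exactly permutation-invariant.
    numerics = sorted(v for v in per_construct.values() if isinstance(v, (int, float)))
    aboves = [b.value for b in per_construct.values() if isinstance(b, Bound) and b.kind == "above"]
    belows = [b.value for b in per_construct.values() if isinstance(b, Bound) and b.kind == "below"]
    est = FunctionEstimate(position=position, aa=aa, per_construct=dict(per_construct))
    lo = max(aboves) if aboves else -math.inf
    hi = min(belows) if belows else math.inf
    if numerics:
        est.combined_f = float(np.mean(numerics))
        est.sd_across_constructs = float(np.std(numerics))
        est.n_numeric = len(numerics)
        est.flag_high = est.combined_f > HIGH_FUNCTION_FLAG
        est.inconsistent = lo > hi or not (lo <= est.combined_f <= hi)
    elif aboves or belows:
        est.inconsistent = lo > hi
        if aboves and belows and not est.inconsistent:
            # Interval bound: report the tighter side as primary.
            est.bound = Bound("above", lo) if lo > 0 else Bound("below", hi)
        elif aboves:
            est.bound = Bound("above", lo)
        elif belows:
            est.bound = Bound("below", hi)
    return est


def function_table(
    aa_tables: Mapping[str, pd.DataFrame],
    constructs: Mapping[str, Construct],
    params: ElasticityParams,
    wt_margin: float = 0.05,
    unbounded_cap: float = 0.8,
) -> list[FunctionEstimate]:
    """Per-substitution function estimates from per-construct aa tables.

    ``aa_tables`` maps construct name to the per-amino-acid aggregate
    (columns position, aa, s, klass) from the selection stage.
    """
    per_sub: dict[tuple[int, str], dict[str, float | Bound | None]] = {}
    for name, df in aa_tables.items():
        construct = constructs[name]
        for row in df.itertuples():
            entry = per_construct_function(
                row.s, row.klass, construct, params, wt_margin, unbounded_cap
            )
            per_sub.setdefault((row.position, row.aa), {})[name] = entry
    return [
        combine_across_constructs(pos, aa, entries)
        for (pos, aa), entries in sorted(per_sub.items())
    ]


def cross_construct_consistency(
    estimates: list[FunctionEstimate],
    construct_order: list[str],
    min_shared: int = 3,
) -> dict:
    """R^2 between numeric function estimates of expression-adjacent pairs.

    ``construct_order`` lists constructs by descending expression
    strength; each neighbouring pair is compared on substitutions where
    both give numeric estimates.  Returns per-pair R^2 (None when fewer
    than ``min_shared`` shared values) and a pooled R^2 over all pairs.
    """
    pairs = {}
    pooled_x, pooled_y = [], []
    for a, b in zip(construct_order, construct_order[1:]):
        xs, ys = [], []
        for est in estimates:
            va, vb = est.per_construct.get(a), est.per_construct.get(b)
            if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
                xs.append(va)
                ys.append(vb)
        if len(xs) >= min_shared and np.std(xs) > 0 and np.std(ys) > 0:
            r, _ = stats.pearsonr(xs, ys)
            pairs[(a, b)] = float(r**2)
            pooled_x.extend(xs)
            pooled_y.extend(ys)
        else:
            pairs[(a, b)] = None
    pooled = None
    if len(pooled_x) >= min_shared and np.std(pooled_x) > 0:
        r, _ = stats.pearsonr(pooled_x, pooled_y)
        pooled = float(r**2)
    return {"pairs": pairs, "pooled": pooled}


def _representative_f(est: FunctionEstimate) -> float | None:
    """Value used for histograms: numeric mean, or a bound's edge."""
    if est.combined_f is not None:
        return est.combined_f
    if est.bound is not None and math.isfinite(est.bound.value):
        return est.bound.value
    return None


def partition_surface_core(
    estimates: list[FunctionEstimate],
) -> tuple[np.ndarray, np.ndarray]:
    """Split combined function values by structural orientation.

    Returns (surface, core) arrays of representative function values for
    the solvent-oriented positions {582, 583, 585} and the core-oriented
    positions {584, 586-590}; bounded-only substitutions contribute their
    bound edge so the distributions keep their null mass.
    """
    surface, core = [], []
    for est in estimates:
        v = _representative_f(est)
        if v is None:
            continue
        if est.position in SURFACE_POSITIONS:
            surface.append(v)
        elif est.position in CORE_POSITIONS:
            core.append(v)
    return np.asarray(surface), np.asarray(core)


def blosum_similarity_table(
    wt_aa: Mapping[int, str], estimates: list[FunctionEstimate]
) -> tuple[pd.DataFrame, float | None]:
    """BLOSUM62 similarity to wild type versus combined function.

    Returns a (position, aa, blosum62, f) table and the Spearman rank
    correlation over substitutions with numeric combined function.
    Self-substitutions (to the wild-type residue) are tabulated with the
    diagonal score but excluded from the correlation; stops have no BLOSUM
    score and are skipped.
    """
    rows = []
    for est in estimates:
        if est.aa == "*":
            continue
        wt = wt_aa.get(est.position)
        if wt is None:
            continue
        if wt not in _BLOSUM62.alphabet or est.aa not in _BLOSUM62.alphabet:
            raise ValueError(f"unknown amino acid code: {wt} or {est.aa}")
        rows.append(
            {
                "position": est.position,
                "aa": est.aa,
                "wt_aa": wt,
                "blosum62": float(_BLOSUM62[wt, est.aa]),
                "f": est.combined_f,
                "is_self": est.aa == wt,
            }
        )
    df = pd.DataFrame(rows, columns=["position", "aa", "wt_aa", "blosum62", "f", "is_self"])
    sub = df[(~df.is_self) & df.f.notna()]
    rho = None
    if len(sub) >= 3 and sub.blosum62.nunique() > 1 and sub.f.nunique() > 1:
        rho = float(stats.spearmanr(sub.blosum62, sub.f).statistic)
    return df, rho


def ddg_function_join(
    ddg: pd.DataFrame, estimates: list[FunctionEstimate]
) -> dict:
    """Join an external per-mutation stability table against function.

    ``ddg`` needs columns position, aa, ddg_kcal_mol.  Inner join on
    (position, aa) over numeric combined estimates; returns the joined
    frame, Pearson and Spearman correlations (None when undefined, e.g.
    zero variance or empty join), and the number of keys dropped.
    """
    fun = pd.DataFrame(
        [
            {"position": e.position, "aa": e.aa, "f": e.combined_f}
            for e in estimates
            if e.combined_f is not None
        ]
    )
    if fun.empty or ddg.empty:
        return {"table": pd.DataFrame(), "pearson": None, "spearman": None, "n_dropped": len(ddg)}
    joined = ddg.merge(fun, on=["position", "aa"], how="inner")
    n_dropped = len(ddg) - len(joined)
    pearson = spearman = None
    if len(joined) >= 3 and joined.ddg_kcal_mol.nunique() > 1 and joined.f.nunique() > 1:
        pearson = float(stats.pearsonr(joined.ddg_kcal_mol, joined.f).statistic)
        spearman = float(stats.spearmanr(joined.ddg_kcal_mol, joined.f).statistic)
    return {"table": joined, "pearson": pearson, "spearman": spearman, "n_dropped": n_dropped}


@dataclass
class Histogram:
    counts: np.ndarray
    edges: np.ndarray
    shares: dict


def dfe_histogram(
    values: np.ndarray,
    kind: str = "s",
    bin_width: float = 0.05,
    wt_margin: float = 0.05,
    null_mask: np.ndarray | None = None,
) -> Histogram:
    """Histogram of fitness (s) or function (F) effects with class shares.

    For ``kind='s'``: WT-like is s > -wt_margin, null-like is taken from
    ``null_mask`` (the NULL_LIKE classification) when given, else s <= -1
    + wt_margin; intermediate is the remainder.  For ``kind='f'``:
    intermediate is the 0.1-0.9 band, WT-like above it, null-like below.
    Out-of-range values land in the edge bins.
    """
    values = np.asarray(values, dtype=float)
    if kind == "s":
        lo, hi = -1.0 - bin_width, 0.5
        wt_like = values > -wt_margin
        if null_mask is not None:
            null_like = np.asarray(null_mask, dtype=bool)
        else:
            null_like = values <= -1.0 + wt_margin
        null_like = null_like & ~wt_like
    elif kind == "f":
        lo, hi = 0.0, max(1.0 + bin_width, bin_width * math.ceil(max(values.max(initial=1.0), 1.0) / bin_width))
        wt_like = values > 0.9
        null_like = values < 0.1
    else:
        raise ValueError(f"kind must be 's' or 'f', got {kind}")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(np.clip(values, lo, hi), bins=edges)
    n = max(len(values), 1)
    shares = {
        "wt_like": float(np.sum(wt_like)) / n,
        "null_like": float(np.sum(null_like)) / n,
        "intermediate": float(np.sum(~wt_like & ~null_like)) / n,
    }
    return Histogram(counts=counts, edges=edges, shares=shares)
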
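"""Effective selection coefficients from bulk-competition count tables.

Each promoter construct's bulk competition yields sequencing counts per
codon variant at several timepoints.  For each variant we fit a straight
line to ln((c_v + pc) / (c_wt + pc)) against time; the slope, in per-hour
units, is the growth-rate difference to wild type, and dividing by the
wild-type monoculture growth rate gives the effective selection
coefficient s = W - 1 (W the mutant/WT growth-rate ratio), so that a
non-growing mutant sits at s = -1 and wild type at s = 0.

Strongly deleterious variants deplete to the counting noise floor within a
few timepoints, flattening their trajectories; variants whose s falls
within two standard deviations of the stop-codon mean are therefore refit
on the first three selection timepoints only and binned as "null-like".
Variants with noisy fits (mean absolute residual per fitted timepoint
above 0.25) or low starting abundance (initial mutant/WT ratio below
0.004) are excluded.  Codon-level coefficients are averaged over
synonymous codons to give per-amino-acid values, and expression-by-
mutation epistasis is the difference in s between a reduced-expression
construct and the endogenous one, with null-like variants treated as true
nulls (s = -1) on both sides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Klass",
    "VariantId",
    "CountTable",
    "SelectionEstimate",
    "SelectionError",
    "InvalidTableError",
    "log_ratio_series",
    "estimate_selection",
    "estimate_table",
    "null_like_cutoff",
    "refit_null_like",
    "apply_filters",
    "run_estimation",
    "aggregate_synonyms",
    "epistasis",
    "epistasis_table",
]

STOP = "*"


class SelectionError(ValueError):
    pass


class InvalidTableError(SelectionError):
    pass


class Klass(str, enum.Enum):
    """Classification of a selection estimate."""

    NUMERIC = "NUMERIC"
    NULL_LIKE = "NULL_LIKE"
    FILTERED = "FILTERED"


@dataclass(frozen=True)
class VariantId:
    """One engineered codon substitution.

    position         : residue index (582-590 in the default library)
    codon            : DNA triplet over {A, C, G, T}
    aa               : encoded amino acid one-letter code, or '*' for stop
    is_wt_codon      : codon equals the wild-type codon at this position
    is_synonymous_wt : encodes the wild-type amino acid via another codon
    """

    position: int
    codon: str
    aa: str
    is_wt_codon: bool = False
    is_synonymous_wt: bool = False

    @property
    def key(self) -> str:
        return f"{self.position}.{self.codon}"

    @property
    def aa_key(self) -> str:
        return f"{self.position}{self.aa}"


@dataclass
class CountTable:
    """Variant-by-timepoint sequencing counts for one bulk competition.

    counts rows follow ``variants`` order; ``wt_counts`` is the wild-type
    reference row.  Counts may be floats only in the noise-free
    (infinite-depth) synthetic mode.
    """

    construct_name: str
    timepoints: np.ndarray
    variants: list[VariantId]
    counts: np.ndarray
    wt_counts: np.ndarray

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.wt_counts = np.asarray(self.wt_counts, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise InvalidTableError("timepoints must be strictly increasing")
        if self.counts.shape != (len(self.variants), len(self.timepoints)):
            raise InvalidTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.variants)} variants x {len(self.timepoints)} timepoints"
            )
        if np.any(self.counts < 0) or np.any(self.wt_counts < 0):
            raise InvalidTableError("counts must be non-negative")
        if not self.wt_counts[0] > 0:
            raise InvalidTableError("wild-type count must be positive at the first timepoint")


@dataclass
class SelectionEstimate:
    """Per-codon effective selection coefficient and fit diagnostics."""

    variant: VariantId
    s: float
    slope: float
    residual_per_timepoint: float
    initial_ratio: float
    n_timepoints_used: int
    klass: Klass = Klass.NUMERIC


def log_ratio_series(table: CountTable, pseudocount: float = 0.5) -> np.ndarray:
    """ln((c_v + pc) / (c_wt + pc)) per variant and timepoint.

    The pseudocount is applied uniformly to numerator and denominator so
    zero counts stay finite.
    """
    if np.all(table.wt_counts == 0):
        raise InvalidTableError("wild-type counts are zero at every timepoint")
    return np.log(
        (table.counts + pseudocount) / (table.wt_counts[None, :] + pseudocount)
    )


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and mean-absolute residual of an ordinary least-squares line."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return float(slope), float(np.mean(np.abs(resid)))


def estimate_selection(
    series: np.ndarray,
    timepoints: np.ndarray,
    g_wt: float,
    variant: VariantId | None = None,
    initial_ratio: float = np.nan,
    n_points: int | None = None,
) -> SelectionEstimate:
    """Fit one variant's log-ratio trajectory and normalize to s.

    ``s = slope / g_wt`` with the slope in per-hour units, so a variant
    tracking wild type exactly has s = 0 and a non-growing variant s = -1.
    Using only the first ``n_points`` timepoints supports the null-like
    refit.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    series = np.asarray(series, dtype=float)
    if g_wt <= 0:
        raise SelectionError(f"wild-type growth rate must be positive, got {g_wt}")
    if n_points is not None:
        series = series[:n_points]
        timepoints = timepoints[:n_points]
    if len(timepoints) < 3:
        raise SelectionError("need >= 3 timepoints for a selection estimate")
    slope, mean_abs_resid = _linear_fit(timepoints, series)
    n = len(timepoints)
    return SelectionEstimate(
        variant=variant,
        s=slope / g_wt,
        slope=slope,
        residual_per_timepoint=mean_abs_resid / n,
        initial_ratio=initial_ratio,
        n_timepoints_used=n,
    )


def estimate_table(
    table: CountTable, g_wt: float, pseudocount: float = 0.5
) -> list[SelectionEstimate]:
    """Selection estimates for every variant of a count table."""
    ratios = log_ratio_series(table, pseudocount)
    init = table.counts[:, 0] / table.wt_counts[0]
    return [
        estimate_selection(
            ratios[i],
            table.timepoints,
            g_wt,
            variant=v,
            initial_ratio=float(init[i]),
        )
        for i, v in enumerate(table.variants)
    ]


def null_like_cutoff(stop_s: Sequence[float]) -> float:
    """Null-like cutoff: mean of stop-codon s plus two standard deviations."""
    stop_s = np.asarray(stop_s, dtype=float)
    if len(stop_s) < 2:
        raise SelectionError("need >= 2 stop-codon estimates for a null cutoff")
    return float(np.mean(stop_s) + 2.0 * np.std(stop_s, ddof=1))


def refit_null_like(
    table: CountTable,
    estimates: list[SelectionEstimate],
    cutoff: float,
    g_wt: float,
    pseudocount: float = 0.5,
    n_null_points: int = 3,
) -> list[SelectionEstimate]:
    """Refit stop codons and sub-cutoff variants on the first timepoints.

    Fast-depleting variants flatten at the counting noise floor, so only
    the first ``n_null_points`` selection timepoints carry signal for
    them.  Refit estimates are binned NULL_LIKE; everything else (and
    anything already FILTERED) passes through unchanged.
    """
    if len(table.timepoints) < n_null_points:
        raise SelectionError(
            f"table has {len(table.timepoints)} timepoints; "
            f"null refit needs {n_null_points}"
        )
    ratios = log_ratio_series(table, pseudocount)
    index = {v.key: i for i, v in enumerate(table.variants)}
    out = []
    for est in estimates:
        if est.klass is Klass.FILTERED:
            out.append(est)
            continue
        if est.variant.aa == STOP or est.s <= cutoff:
            i = index[est.variant.key]
            refit = estimate_selection(
                ratios[i],
                table.timepoints,
                g_wt,
                variant=est.variant,
                initial_ratio=est.initial_ratio,
                n_points=n_null_points,
            )
            out.append(replace(refit, klass=Klass.NULL_LIKE))
        else:
            out.append(est)
    return out


def apply_filters(
    estimates: list[SelectionEstimate],
    residual_max: float = 0.25,
    min_initial_ratio: float = 0.004,
) -> list[SelectionEstimate]:
    """Flag noisy or poorly sampled estimates as FILTERED.

    A variant is dropped when its mean absolute residual per fitted
    timepoint exceeds ``residual_max`` (strict), or its first-timepoint
    mutant/WT ratio is below ``min_initial_ratio`` (strict).
    """
    out = []
    for est in estimates:
        fires = (
            est.residual_per_timepoint > residual_max
            or est.initial_ratio < min_initial_ratio
        )
        out.append(replace(est, klass=Klass.FILTERED) if fires else est)
    return out


def run_estimation(
    table: CountTable,
    g_wt: float,
    pseudocount: float = 0.5,
    residual_max: float = 0.25,
    min_initial_ratio: float = 0.004,
    n_null_points: int = 3,
    cutoff: float | None = None,
) -> tuple[list[SelectionEstimate], float]:
    """Full single-construct estimation pass.

    Fits every variant on all timepoints, derives the null-like cutoff
    from the stop codons (unless one is supplied), refits sub-cutoff
    variants on the first ``n_null_points`` timepoints, then applies the
    residual and initial-abundance filters.  Returns the estimates and the
    cutoff used.
    """
    ests = estimate_table(table, g_wt, pseudocount)
    if cutoff is None:
        stop_s = [e.s for e in ests if e.variant.aa == STOP]
        cutoff = null_like_cutoff(stop_s)
    ests = refit_null_like(table, ests, cutoff, g_wt, pseudocount, n_null_points)
    ests = apply_filters(ests, residual_max, min_initial_ratio)
    return ests, cutoff


def aggregate_synonyms(
    estimates: list[SelectionEstimate],
    persist_threshold: float = -0.1,
    cutoff: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average codon-level s over synonymous codons.

    Returns ``(aa_df, deviations_df)``.  ``aa_df`` has one row per
    (position, amino acid) with the mean s of its non-filtered synonymous
    codons, the number of codons averaged, and a class: NULL_LIKE when the
    averaged s falls at or below ``cutoff`` (or when every contributing
    codon was binned null-like if no cutoff is given), NUMERIC otherwise.
    ``deviations_df`` holds, for persisting codons only
    (s > ``persist_threshold``), the deviation of each codon's s from its
    synonym mean — the synonym-variance diagnostic.
    """
    rows = []
    dev_rows = []
    kept = [e for e in estimates if e.klass is not Klass.FILTERED]
    by_aa: dict[tuple[int, str], list[SelectionEstimate]] = {}
    for est in kept:
        by_aa.setdefault((est.variant.position, est.variant.aa), []).append(est)
    for (pos, aa), group in sorted(by_aa.items()):
        s_values = np.array([e.s for e in group])
        s_mean = float(np.mean(s_values))
        if cutoff is not None:
            klass = Klass.NULL_LIKE if s_mean <= cutoff else Klass.NUMERIC
        else:
            klass = (
                Klass.NULL_LIKE
                if all(e.klass is Klass.NULL_LIKE for e in group)
                else Klass.NUMERIC
            )
        rows.append(
            {
                "position": pos,
                "aa": aa,
                "s": s_mean,
                "n_codons": len(group),
                "klass": klass.value,
            }
        )
        persisting = [e for e in group if e.s > persist_threshold]
        if persisting:
            syn_mean = float(np.mean([e.s for e in persisting]))
            for e in persisting:
                dev_rows.append(
                    {
                        "position": pos,
                        "aa": aa,
                        "codon": e.variant.codon,
                        "s": e.s,
                        "deviation": e.s - syn_mean,
                    }
                )
    aa_df = pd.DataFrame(rows, columns=["position", "aa", "s", "n_codons", "klass"])
    dev_df = pd.DataFrame(
        dev_rows, columns=["position", "aa", "codon", "s", "deviation"]
    )
    return aa_df, dev_df


def epistasis(
    s_endog: float,
    s_reduced: float,
    endog_null: bool = False,
    reduced_null: bool = False,
) -> float:
    """Expression-by-mutation epistasis, ε = s_reduced - s_endog.

    Null-like estimates are treated as true nulls (s = -1) on either side,
    so a wild-type-like mutant at endogenous expression that becomes
    null-like at reduced expression has ε = -1.
    """
    a = -1.0 if endog_null else s_endog
    b = -1.0 if reduced_null else s_reduced
    return b - a


def epistasis_table(aa_endog: pd.DataFrame, aa_reduced: pd.DataFrame) -> pd.DataFrame:
    """Per-amino-acid epistasis between two constructs' aggregates.

    Inner-joins the per-amino-acid tables (rows absent or filtered on
    either side are dropped) and applies the null-as-true-null mapping.
    """
    merged = aa_endog.merge(
        aa_reduced, on=["position", "aa"], suffixes=("_endog", "_reduced")
    )
    eps = [
        epistasis(
            row.s_endog,
            row.s_reduced,
            endog_null=row.klass_endog == Klass.NULL_LIKE.value,
            reduced_null=row.klass_reduced == Klass.NULL_LIKE.value,
        )
        for row in merged.itertuples()
    ]
    merged["epistasis"] = eps
    return merged[["position", "aa", "s_endog", "s_reduced", "epistasis"]]
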
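"""Synthetic inputs for the whole pipeline.

Generates every artifact the analysis consumes, with known ground truth:
a saturation codon-substitution library over a nine-residue window (64
codons x 9 positions = 576 variants plus the wild-type reference), true
per-molecule function values drawn from configurable distributions of
functional effects, bulk-competition count tables produced by exponential
(or expression-dynamics-driven) growth with multinomial sequencing
sampling, monoculture OD600 growth curves with periodic dilution, and
GFP-reporter expression time courses.

Every generator is a pure function of its configuration and an integer
seed.  Synonymous codons share one true function value per amino acid,
stop codons are true nulls (F = 0), and codons encoding the wild-type
amino acid carry F = 1, mirroring the biological assumptions of the
analysis (expression and synthesis unaffected by single-codon changes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .dynamics import DynamicsConfig, expression_at
from .elasticity import Construct, ElasticityParams, GrowthCurve, growth_rate
from .selection import CountTable, VariantId

__all__ = [
    "LibrarySpec",
    "TrueVariantParams",
    "DEFAULT_WT_CODONS",
    "DFE_PRESETS",
    "build_library",
    "sample_true_function",
    "simulate_bulk_competition",
    "simulate_growth_curves",
    "simulate_gfp_timecourse",
    "fit_expression_increase",
]

CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Wild-type codons for the mutagenized window.  Residue identities at
# 583 (Phe), 585 (Trp), 586 (Ser), 587 (Ala) and 590 (Glu) are fixed by
# the study system; the remaining positions use arbitrary-but-fixed
# codons and are fully overridable.
DEFAULT_WT_CODONS = {
    582: "ATT",  # Ile (placeholder residue)
    583: "TTT",  # Phe
    584: "TTG",  # Leu (placeholder residue)
    585: "TGG",  # Trp
    586: "TCT",  # Ser
    587: "GCT",  # Ala
    588: "GAT",  # Asp (placeholder residue)
    589: "GGT",  # Gly (placeholder residue)
    590: "GAA",  # Glu
}

DFE_PRESETS = ("bimodal", "intermediate", "uniform", "planted")


class SyntheticConfigError(ValueError):
    pass


@dataclass
class LibrarySpec:
    """Saturation single-codon mutagenesis design: 64 codons x 9 positions."""

    wt_codons: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_WT_CODONS))

    def __post_init__(self):
        for pos, codon in self.wt_codons.items():
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise SyntheticConfigError(f"invalid codon {codon!r} at position {pos}")

    @property
    def positions(self) -> list[int]:
        return sorted(self.wt_codons)


@dataclass(frozen=True)
class TrueVariantParams:
    """Ground-truth per-molecule function of one library variant."""

    variant: VariantId
    f_true: float


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def build_library(spec: LibrarySpec | None = None) -> list[VariantId]:
    """Enumerate all single-codon substitutions of the design window."""
    spec = spec or LibrarySpec()
    variants = []
    for pos in spec.positions:
        wt_codon = spec.wt_codons[pos]
        wt_aa = translate(wt_codon)
        for codon in CODONS:
            aa = translate(codon)
            variants.append(
                VariantId(
                    position=pos,
                    codon=codon,
                    aa=aa,
                    is_wt_codon=codon == wt_codon,
                    is_synonymous_wt=aa == wt_aa and codon != wt_codon,
                )
            )
    return variants


def _draw_aa_function(rng: np.random.Generator, preset: str, cfg: dict) -> float:
    if preset == "bimodal":
        if rng.random() < cfg.get("p_null", 0.4):
            return 0.0
        return float(np.clip(rng.normal(cfg.get("loc_wt", 1.0), cfg.get("sd_wt", 0.03)), 0.0, 1.2))
    if preset == "intermediate":
        if rng.random() < cfg.get("p_null", 0.4):
            return 0.0
        return float(rng.uniform(cfg.get("low", 0.1), cfg.get("high", 0.9)))
    if preset == "uniform":
        return float(rng.uniform(cfg.get("low", 0.0), cfg.get("high", 1.0)))
    raise SyntheticConfigError(f"unknown DFE preset {preset!r}")


def sample_true_function(
    library: list[VariantId], dfe_config: dict, seed: int
) -> list[TrueVariantParams]:
    """Draw ground-truth per-molecule function for every variant.

    ``dfe_config`` names a preset — 'bimodal' (mass at ~1 and at 0),
    'intermediate' (a null component plus uniform intermediate defects),
    'uniform', or 'planted' (explicit {(position, aa): F} values) — with
    optional parameters.  One value is drawn per (position, amino-acid)
    class so synonymous codons share their truth; stop codons are forced
    to 0 and wild-type-amino-acid codons to 1.
    """
    preset = dfe_config.get("preset")
    if preset not in DFE_PRESETS:
        raise SyntheticConfigError(
            f"unknown preset {preset!r}; expected one of {DFE_PRESETS}"
        )
    rng = np.random.default_rng(seed)
    planted = dfe_config.get("values", {}) if preset == "planted" else {}
    default_planted = dfe_config.get("default", 1.0)
    draws: dict[tuple[int, str], float] = {}
    truth = []
    for v in sorted(library, key=lambda v: (v.position, v.codon)):
        key = (v.position, v.aa)
        if v.aa == "*":
            f = 0.0
        elif v.is_wt_codon or v.is_synonymous_wt:
            f = 1.0
        elif key in draws:
            f = draws[key]
        else:
            if preset == "planted":
                f = float(planted.get(key, default_planted))
            else:
                f = _draw_aa_function(rng, preset, dfe_config)
            draws[key] = f
        truth.append(TrueVariantParams(variant=v, f_true=f))
    return truth


def _growth_factors(
    fs: np.ndarray,
    construct: Construct,
    params: ElasticityParams,
    dts: np.ndarray,
    dynamics: DynamicsConfig | None,
) -> np.ndarray:
    """Cumulative growth multiplier per variant at each sampled offset."""
    if dynamics is None:
        g = params.g_max * construct.e * fs / (params.e_m + construct.e * fs)
        return np.exp(np.outer(g, dts))
    # Same piecewise-constant-rate stepping as the dynamics module.
    n_steps = int(round(dts[-1] / dynamics.dt))
    times = np.arange(n_steps + 1) * dynamics.dt
    factors = np.ones((len(fs), n_steps + 1))
    for k in range(n_steps):
        e_t = expression_at(times[k], dynamics)
        g = dynamics.params.g_max * e_t * fs / (dynamics.params.e_m + e_t * fs)
        factors[:, k + 1] = factors[:, k] * np.exp(g * dynamics.dt)
    idx = np.searchsorted(times, dts)
    idx = np.clip(idx, 0, n_steps)
    return factors[:, idx]


def simulate_bulk_competition(
    truth: list[TrueVariantParams],
    construct: Construct,
    params: ElasticityParams,
    depths: int | list[int] | None = 500_000,
    timepoints: list[float] | None = None,
    seed: int = 0,
    dynamics: DynamicsConfig | None = None,
    wt_fraction: float = 0.1,
    init_freqs: np.ndarray | None = None,
) -> CountTable:
    """Bulk-competition count table under a construct's growth conditions.

    Expected variant frequencies follow exponential growth at
    G(E, F_true) from the first timepoint onward (or Euler-integrated
    growth when a ``dynamics`` config is given); observed counts are
    multinomial draws at the stated sequencing ``depths`` per timepoint.
    ``depths=None`` switches to the noise-free infinite-depth mode, where
    expected counts (scaled to 1e6) are returned as floats and log-ratio
    slopes are exact.  The wild-type reference row starts at
    ``wt_fraction`` of the culture; the engineered variants share the rest
    uniformly unless ``init_freqs`` is given.
    """
    timepoints = np.asarray(
        construct.timepoints if timepoints is None else timepoints, dtype=float
    )
    if timepoints.size < 3:
        raise SyntheticConfigError("need >= 3 timepoints")
    variants = [t.variant for t in truth]
    fs = np.array([t.f_true for t in truth])
    n = len(variants)
    if init_freqs is None:
        init_freqs = np.full(n, (1.0 - wt_fraction) / n)
    else:
        init_freqs = np.asarray(init_freqs, dtype=float)
        init_freqs = init_freqs / init_freqs.sum() * (1.0 - wt_fraction)
    if np.any(init_freqs <= 0) or not 0 < wt_fraction < 1:
        raise SyntheticConfigError("initial frequencies must be positive")
    dts = timepoints - timepoints[0]
    all_fs = np.concatenate([fs, [1.0]])
    all_f0 = np.concatenate([init_freqs, [wt_fraction]])
    factors = _growth_factors(all_fs, construct, params, dts, dynamics)
    masses = all_f0[:, None] * factors
    freqs = masses / masses.sum(axis=0, keepdims=True)
    if depths is None:
        counts = freqs * 1e6
    else:
        depths_arr = np.broadcast_to(
            np.asarray(depths, dtype=int), (len(timepoints),)
        )
        rng = np.random.default_rng(seed)
        counts = np.empty_like(freqs)
        for j in range(len(timepoints)):
            counts[:, j] = rng.multinomial(depths_arr[j], freqs[:, j])
    return CountTable(
        construct_name=construct.name,
        timepoints=timepoints,
        variants=variants,
        counts=counts[:-1],
        wt_counts=counts[-1],
    )


def simulate_growth_curves(
    e_grid: list[float],
    params: ElasticityParams,
    noise_sd: float = 0.02,
    seed: int = 0,
    duration_hr: float = 24.0,
    step_hr: float = 2.0,
    od_start: float = 0.1,
    od_ceiling: float = 0.7,
    od_after_dilution: float = 0.15,
) -> dict[float, GrowthCurve]:
    """Monoculture OD600 time courses across an expression ladder.

    Each culture grows exponentially at G(E, 1); whenever the underlying
    density would exceed ``od_ceiling`` it is diluted back to
    ``od_after_dilution`` with the factor accumulated into the cumulative
    dilution column, keeping readings in log phase.  Readings carry
    multiplicative lognormal noise of scale ``noise_sd``.
    """
    if not e_grid:
        raise SyntheticConfigError("expression grid must be non-empty")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_hr + step_hr / 2, step_hr)
    curves = {}
    for e in e_grid:
        g = growth_rate(e, 1.0, params)
        od_true = od_start
        cum_dil = 1.0
        od_readings, dils = [], []
        for i, t in enumerate(times):
            if i > 0:
                od_true *= np.exp(g * step_hr)
                if od_true > od_ceiling:
                    cum_dil *= od_true / od_after_dilution
                    od_true = od_after_dilution
            noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            od_readings.append(od_true * noise)
            dils.append(cum_dil)
        curves[e] = GrowthCurve(
            times=times, od=np.array(od_readings), cumulative_dilution=np.array(dils)
        )
    return curves


def simulate_gfp_timecourse(
    e_0: float,
    tau: float,
    times: list[float],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Mean reporter expression over time: E_0 * (1 + tau * (t - t0)).

    Multiplicative lognormal noise of scale ``noise_sd`` per sampled time.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SyntheticConfigError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    mean = e_0 * (1.0 + tau * (times - times[0]))
    noise = np.exp(rng.normal(0.0, noise_sd, size=times.shape)) if noise_sd > 0 else 1.0
    return mean * noise


def fit_expression_increase(times: np.ndarray, values: np.ndarray) -> float:
    """Fractional expression-increase rate from a reporter time course.

    Fits fold change relative to the first sampled time to the linear
    model 1 + tau * (t - t0) and returns the fitted tau (per hour).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    fold = values / values[0]
    slope, _ = np.polyfit(times - times[0], fold, 1)
    return float(slope)
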
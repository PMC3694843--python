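"""Pipeline configuration: study constants, thresholds, serialization.

The default configuration encodes the seven-construct promoter/terminator
ladder of the study system — expression strengths, null-like selection
cutoffs, sequenced timepoints — together with the fitted elasticity
parameters (G_max = 0.45 per hour, E_m = 0.014) and the estimation
thresholds (pseudocount 0.5, residual cap 0.25 per timepoint, minimum
initial mutant/WT ratio 0.004, WT-coupling margin 0.05, synonym
persistence gate s > -0.1).

Expression strengths for the four weak constructs are the growth-derived
values (estimated from observed growth rate through the elasticity
function), which are less noisy than the direct Western/GFP measurements;
the measured values are retained alongside in ``e_measured``.  The
CYCdTer null cutoff is stored as -0.44 (the magnitude reported for that
construct; cutoffs are non-positive by construction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .elasticity import Construct, ElasticityParams, growth_rate

__all__ = [
    "PipelineConfig",
    "EstimationConfig",
    "SyntheticConfig",
    "DynamicsDefaults",
    "default_constructs",
    "default_config",
    "read_config",
    "write_config",
    "config_hash",
    "DEFAULT_PARAMS",
    "TIMEPOINTS_STRONG",
    "TIMEPOINTS_WEAK",
]

DEFAULT_PARAMS = ElasticityParams(g_max=0.45, e_m=0.014)

# Hours in dextrose at which samples were sequenced.  The three strong
# constructs include the 12 h point; the weak four start at 16 h where
# deleterious variants deplete more slowly.
TIMEPOINTS_STRONG = [12.0, 16.0, 20.0, 24.0, 32.0, 40.0, 48.0]
TIMEPOINTS_WEAK = [16.0, 20.0, 24.0, 32.0, 40.0, 48.0]


def default_constructs(params: ElasticityParams = DEFAULT_PARAMS) -> list[Construct]:
    """The seven promoter/terminator constructs with study constants.

    Wild-type growth rates are the elasticity function evaluated at F = 1,
    the same anchoring used to derive the weak-promoter expression values.
    """
    rows = [
        # name, e (used), e_measured, s_cut, timepoints, e_0, tau
        ("GPD", 1.0, 1.0, -0.28, TIMEPOINTS_STRONG, None, None),
        ("TEF", 0.32, 0.32, -0.37, TIMEPOINTS_STRONG, None, None),
        ("TEFdTer", 0.094, 0.094, -0.40, TIMEPOINTS_STRONG, None, None),
        ("CYC", 0.028, 0.044, -0.35, TIMEPOINTS_WEAK, None, None),
        ("CYCdTer", 0.015, 0.019, -0.44, TIMEPOINTS_WEAK, 0.016, 0.11),
        ("ADH", 0.014, 0.014, -0.46, TIMEPOINTS_WEAK, None, None),
        ("ADHdTer", 0.010, 0.008, -0.43, TIMEPOINTS_WEAK, None, None),
    ]
    return [
        Construct(
            name=name,
            e=e,
            e_measured=e_meas,
            g_wt=growth_rate(e, 1.0, params),
            s_cut=s_cut,
            timepoints=list(tps),
            e_0=e_0,
            tau=tau,
        )
        for name, e, e_meas, s_cut, tps, e_0, tau in rows
    ]


@dataclass
class EstimationConfig:
    pseudocount: float = 0.5
    residual_max: float = 0.25
    min_initial_ratio: float = 0.004
    wt_margin: float = 0.05
    persist_threshold: float = -0.1
    unbounded_cap: float = 0.8
    n_null_points: int = 3
    # 'stops' derives the null cutoff from stop codons per table;
    # 'config' uses each construct's stored s_cut.
    cutoff_mode: str = "stops"


@dataclass
class SyntheticConfig:
    preset: str = "intermediate"
    seed: int = 1
    depth: int = 500_000
    wt_fraction: float = 0.1
    dfe: dict = field(default_factory=dict)


@dataclass
class DynamicsDefaults:
    dt: float = 0.1
    horizon: float = 36.0


@dataclass
class PipelineConfig:
    g_max: float = DEFAULT_PARAMS.g_max
    e_m: float = DEFAULT_PARAMS.e_m
    constructs: list[Construct] = field(default_factory=default_constructs)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    dynamics: DynamicsDefaults = field(default_factory=DynamicsDefaults)
    # Directory of count tables keyed by construct name; None -> synthetic.
    counts_dir: str | None = None

    @property
    def params(self) -> ElasticityParams:
        return ElasticityParams(g_max=self.g_max, e_m=self.e_m)

    def construct(self, name: str) -> Construct:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(f"no construct named {name!r} in configuration")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "constructs" in d:
            d["constructs"] = [Construct(**c) for c in d["constructs"]]
        if "estimation" in d:
            d["estimation"] = EstimationConfig(**d["estimation"])
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if "dynamics" in d:
            d["dynamics"] = DynamicsDefaults(**d["dynamics"])
        return cls(**d)


def default_config() -> PipelineConfig:
    return PipelineConfig()


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the full configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]
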
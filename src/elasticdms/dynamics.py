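"""Competition models under constant or rising expression.

Weak promoters are under selection to increase expression during the
competition; these models quantify how much that drift matters to the
fitted selection coefficients.  Two variants of dN/dt = G(E(t), F) * N
are integrated on a fixed grid:

CE  (constant expression):          E(t) = E_0
LIE (linearly increasing expression): E(t) = E_0 * (1 + tau * t)

with the elasticity function G supplying growth rates.  The update is
piecewise-constant-rate exponential stepping,
N_{k+1} = N_k * exp(G(E(t_k), F) * dt): growth within a step is exactly
exponential, so the discretization error comes only from holding the
time-varying expression fixed across each step — the CE model therefore
matches its closed form N(0)*exp(G*t) to machine precision.  Time zero is
the start of the fitted competition window, and the expression-increase
rate tau comes from linear fits to GFP-fusion fold changes.  Comparing
the fitted ln(mutant/WT) slopes between the two models bounds the error
the constant-expression assumption introduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elasticity import ElasticityParams, Construct, ElasticityError, growth_rate

__all__ = [
    "DynamicsConfig",
    "expression_at",
    "simulate_competition",
    "trajectory_slope",
    "predict_growth_increase",
]


@dataclass
class DynamicsConfig:
    """Configuration of a numerical-integration competition model.

    model   : 'CE' (constant expression) or 'LIE' (linearly increasing)
    e_0     : relative expression at the start of the modeled window
    tau     : fractional expression increase rate (per hour; ignored by CE)
    dt      : forward-Euler step (hours), default 0.1
    params  : elasticity parameters
    horizon : simulated duration (hours)
    """

    model: str
    e_0: float
    params: ElasticityParams
    horizon: float
    tau: float = 0.0
    dt: float = 0.1

    def __post_init__(self):
        if self.model not in ("CE", "LIE"):
            raise ElasticityError(f"model must be 'CE' or 'LIE', got {self.model}")
        if self.dt <= 0:
            raise ElasticityError("dt must be positive")
        if self.horizon < self.dt:
            raise ElasticityError("horizon must be >= dt")
        if self.tau < 0:
            raise ElasticityError("tau must be >= 0")
        if not self.e_0 > 0:
            raise ElasticityError("e_0 must be positive")


def expression_at(t: float, config: DynamicsConfig) -> float:
    """Expression level at time ``t`` hours into the modeled window."""
    if np.any(np.asarray(t) < 0):
        raise ElasticityError("time must be >= 0")
    if config.model == "CE":
        return config.e_0 * np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else config.e_0
    return config.e_0 * (1.0 + config.tau * t)


def simulate_competition(
    f_list: list[float],
    config: DynamicsConfig,
    n0: list[float] | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Step-integrated abundance trajectories for a set of variants.

    A wild-type column (F = 1, label 'WT') is always appended.  Initial
    abundances default to 1 for every variant.  Returns a DataFrame
    indexed by time with one column per variant.
    """
    if any(f < 0 for f in f_list):
        raise ElasticityError("per-molecule function must be >= 0")
    fs = np.asarray(list(f_list) + [1.0], dtype=float)
    if labels is None:
        labels = [f"F={f:g}" for f in f_list]
    labels = list(labels) + ["WT"]
    if n0 is None:
        n0 = np.ones_like(fs)
    else:
        n0 = np.asarray(list(n0) + [1.0], dtype=float)
    n_steps = int(round(config.horizon / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    traj = np.empty((n_steps + 1, len(fs)))
    traj[0] = n0
    for k in range(n_steps):
        e_t = expression_at(times[k], config)
        g = np.array([growth_rate(e_t, f, config.params) for f in fs])
        traj[k + 1] = traj[k] * np.exp(g * config.dt)
    return pd.DataFrame(traj, index=pd.Index(times, name="time_hr"), columns=labels)


def trajectory_slope(
    trajectories: pd.DataFrame,
    fit_window: tuple[float, float] | None = None,
    wt_label: str = "WT",
) -> pd.Series:
    """Least-squares slope of ln(N_v / N_WT) against time per variant."""
    df = trajectories
    if fit_window is not None:
        lo, hi = fit_window
        df = df[(df.index >= lo) & (df.index <= hi)]
    if len(df) < 3:
        raise ElasticityError("need >= 3 sampled times in the fit window")
    t = df.index.to_numpy(dtype=float)
    log_ratio = np.log(df.div(df[wt_label], axis=0))
    slopes = {}
    for col in df.columns:
        if col == wt_label:
            slopes[col] = 0.0
        else:
            slopes[col] = float(np.polyfit(t, log_ratio[col].to_numpy(), 1)[0])
    return pd.Series(slopes, name="slope")


def predict_growth_increase(
    construct: Construct,
    params: ElasticityParams,
    t_from: float,
    t_to: float,
) -> float | None:
    """Predicted growth rate at ``t_to`` from expression rise since ``t_from``.

    Uses the construct's fitted linear expression model,
    E(t_to) = E_0 * (1 + tau * (t_to - t_from)), pushed through the
    elasticity function at F = 1.  Returns None when the construct has no
    fitted tau.
    """
    if construct.tau is None or construct.e_0 is None:
        return None
    if t_to < t_from:
        raise ElasticityError("t_to must be >= t_from")
    e_t = construct.e_0 * (1.0 + construct.tau * (t_to - t_from))
    return growth_rate(e_t, 1.0, params)
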
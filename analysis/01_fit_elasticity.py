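#!/usr/bin/env python
"""Fit the expression-growth elasticity function from monoculture curves.

Simulates OD600 time courses for the seven-construct expression ladder
(2% multiplicative reading noise, periodic dilution), fits each growth
rate from ln(OD x cumulative dilution) vs time, then fits the hyperbolic
elasticity curve G = G_max * E / (E_m + E).  Writes the fitted rates and
the elasticity parameters under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from elasticdms import io
from elasticdms.config import DEFAULT_PARAMS, default_constructs
from elasticdms.elasticity import fit_elasticity, fit_growth_rate, growth_rate
from elasticdms.synthetic import simulate_growth_curves


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    constructs = default_constructs()
    curves = simulate_growth_curves(
        [c.e for c in constructs], DEFAULT_PARAMS, noise_sd=0.02, seed=args.seed
    )
    rows = []
    for c in constructs:
        rate = fit_growth_rate(curves[c.e])
        rows.append(
            {"construct": c.name, "e": c.e, "fitted_rate": rate,
             "generating_rate": growth_rate(c.e, 1.0, DEFAULT_PARAMS)}
        )
        print(f"{c.name:8s} E={c.e:<6g} growth rate {rate:.4f}/hr "
              f"(generating {rows[-1]['generating_rate']:.4f})")
    df = pd.DataFrame(rows)
    io.write_tsv(df, args.outdir / "growth_rates.tsv", seed=args.seed)

    fit = fit_elasticity(list(zip(df.e, df.fitted_rate)))
    io.write_elasticity_fit(fit, args.outdir / "elasticity.json")
    print(f"\nElasticity fit: G_max = {fit.params.g_max:.4f}/hr, "
          f"E_m = {fit.params.e_m:.4g} (rss = {fit.rss:.3g}, n = {fit.n_points})")
    print("Expression can drop far below endogenous before growth suffers: "
          f"half-maximal growth needs only E = {fit.params.e_m:.3f}.")


if __name__ == "__main__":
    main()
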
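# Methods

## The elasticity model

Growth rate is modeled as a hyperbola in net function, `G(E, F) =
G_max·E·F/(E_m + E·F)`, the standard flux-control form for an essential
enzyme whose product saturates downstream demand. Default parameters are
`G_max = 0.45 /hr` (maximal growth under the strongest construct) and
`E_m = 0.014` (relative expression for half-maximal growth), both
dimensionless in `E` (endogenous expression = 1) and per-hour in `G`.
The model deliberately omits a cost-of-expression term: fitness
saturates at `G_max`, an assumption appropriate over the ≤ 1×-endogenous
range analyzed here, where expression costs are below growth-rate
detection.

Two further simplifying assumptions are inherited by everything
downstream: expression level is independent of coding mutations (so a
single `E` per construct applies to all variants), and per-molecule
function is independent of expression level (so one `F` per amino-acid
substitution describes all constructs). The cross-construct standard
deviation reported with every combined estimate is the empirical check on
the second assumption.

The effective selection coefficient is `s = G(E,F)/G(E,1) − 1`, and the
closed-form inverse `F = (1+s)·E_m/(E_m − s·E)` is exact; the
implementation raises explicit markers rather than returning numbers when
the inverse is undefined (`s ≤ −1`: function at or below the null
detection limit; `s ≥ E_m/E`: no finite function produces that growth).

## Selection-coefficient estimation

For each codon variant, `ln((c_v + pc)/(c_wt + pc))` is fit against time
(hours) by ordinary least squares; the slope divided by the construct's
wild-type monoculture growth rate gives `s`. The normalization makes
`s = W − 1` with `W` the growth-rate ratio: a non-growing variant sits at
`s = −1` regardless of construct. The pseudocount `pc = 0.5` (uniform on
numerator and denominator, configurable) keeps zero counts finite; fits
without sampling noise are exact, so `pc = 0` is used in noise-free
checks.

Null binning is a single pass: stop codons are fit on all timepoints, the
cutoff is their mean + 2 SD (sample SD), and every variant at or below
the cutoff — plus all stop codons — is refit on the first three selection
timepoints and classed NULL_LIKE. The rationale is trajectory
flattening: a fast-depleting variant reaches the counting floor within a
few timepoints, after which its log-ratio carries no signal and an
all-timepoint slope is biased toward zero.

Two filters remove unreliable codons, both strict inequalities: mean
absolute fit residual per fitted timepoint > 0.25 (the "residuals per
time point" statistic; the exact formula — mean |residual| divided by the
number of fitted points — is this package's reading of that quotient), and
first-timepoint mutant/WT ratio < 0.004. Filtered codons are excluded
from all downstream aggregation.

Per-amino-acid coefficients are unweighted means over non-filtered
synonymous codons; an amino acid is classed NULL_LIKE when its averaged
`s` falls at or below the construct cutoff. Synonym deviations
(codon − synonym mean) are reported only for persisting codons
(`s > −0.1`), where counting statistics are informative.

Expression-by-mutation epistasis is `ε = s_reduced − s_endogenous` with
NULL_LIKE mapped to `s = −1` on both sides, so a wild-type-like mutant
that becomes null-like at reduced expression has `ε = −1` exactly.

## Function inference and bounds

Within one construct, a NULL_LIKE amino acid maps to a bound BELOW the
construct's informative-window lower edge; an amino acid with
`s > −wt_margin` (default 0.05) maps to a bound ABOVE the upper edge;
anything between maps to the numeric inverse. Two genuinely open design
choices are resolved as follows:

- **Upper-edge reading.** The window's upper edge is where a mutant grows
  within 5% of *its construct's own wild type* (`s = −wt_margin`), not
  within 5% of the global `G_max`. Only this relative reading reproduces
  the strong-construct windows self-consistently across expression
  strengths; the margin is configurable.
- **Unbounded cap.** When the computed upper edge reaches 0.8, the window
  is reported as "lower and above": near `F = 1` the inversion's
  steepness makes upper edges numerically meaningless for weak
  constructs. The cap of 0.8 is an interpretation choice and is
  configurable.

Known numerical discrepancies, flagged and deliberately not forced: with
the stored constants, the TEF upper edge computes to 0.44 (commonly
quoted as 0.45) and the ADH lower edge to 0.37 (quoted as 0.39); the
remaining window edges reproduce quoted values to the printed decimals.
Weak-promoter expression strengths use the growth-derived values
(E = 0.028, 0.015, 0.014, 0.010 for CYC, CYCΔter, ADH, ADHΔter), which
are the self-consistent choice under the elasticity model; the direct
measurements (0.044, 0.019, 0.014, 0.008) ship alongside in the
configuration as `e_measured`.

Combined estimates average numeric entries only (unweighted; bounds never
enter), with a population (ddof = 0) standard deviation across
constructs; summands are sorted so the result is exactly
permutation-invariant. When a substitution has only bounds, their
intersection is reported (ABOVE max of lower edges and/or BELOW min of
upper edges); contradictory bounds, or a combined value outside the
surviving bounds, set an `inconsistent` flag rather than raising — the
right reconciliation is not knowable from the data, so both facts are
surfaced. Numeric values above 1 (apparently beneficial at low
expression) are retained, since clipping would hide violations of the
constant-function assumption; values above 1.2 carry a `flag_high`.

BLOSUM62 similarity uses Biopython's canonical half-bit matrix
(`Bio.Align.substitution_matrices`) rather than an embedded copy — the
dependency is already required for codon translation. Self-substitutions
are tabulated with the diagonal score but excluded from the Spearman
correlation.

## Competition dynamics

The CE (constant expression) and LIE (linearly increasing expression,
`E(t) = E_0·(1 + τ·t)`) models integrate `dN/dt = G(E(t), F)·N` on a
fixed grid with piecewise-constant-rate exponential stepping,
`N_{k+1} = N_k·exp(G(E(t_k), F)·Δt)`, at `Δt = 0.1 h`. Growth within a
step is exactly exponential, so the discretization error comes only from
holding the time-varying expression fixed across a step: the CE model
matches its closed form to machine precision, LIE converges first-order
in `Δt` (halving `Δt` moves fitted slopes by < 0.5% at the default
parameters), and `τ = 0` reduces LIE to CE bitwise. A linearized update
(`N_{k+1} = N_k·(1 + G·Δt)`) was rejected because it accumulates ~10%
abundance error over 36 h at these growth rates for no compensating
benefit. Time zero is the start of the fitted competition window; the
reporter-measurement offset is absorbed into `E_0` (default window
parameters `E_0 = 0.016`, `τ = 0.11 /hr` for the weakest-but-one
construct). Total abundance is not conserved — this is a growth model,
not a frequency model — and frequencies are obtained by normalization.

## Synthetic data: what it does and does not emulate

The generator reproduces the experiment's *design*: 576 engineered
variants (64 codons × 9 positions) plus a wild-type reference row at 10%
of the initial culture; exponential growth at elasticity-determined
rates from the first sequenced timepoint (12 h in dextrose for the three
strong constructs, 16 h for the weak four, samples through 48 h);
multinomial sequencing sampling at 5×10⁵ reads per timepoint (matching
the order of the real per-sample depth); synonymous codons sharing one
true function value, stop codons fixed at `F = 0`, wild-type-amino-acid
codons at `F = 1`; optional linear expression increase via the LIE model;
OD600 growth curves with periodic dilution keeping cultures in log phase;
and reporter time courses with multiplicative noise. Truth presets:
`bimodal` (40% nulls, the rest near `F = 1`), `intermediate` (40% nulls,
the rest uniform on 0.1–0.9 — the scenario indistinguishable from bimodal
at endogenous expression), `uniform`, and `planted` (explicit values).
Every generator is a pure function of (configuration, seed).

It does **not** emulate PCR jackpots or sequencing error, read-level
quality, cell-to-cell expression heterogeneity, plasmid copy-number
noise, or day-to-day batch effects. Consequences worth stating plainly:
passing recovery tests demonstrate the estimator is correct under the
stated sampling model, not that real-data error is this small; and the
stop-codon-derived null cutoffs on synthetic data land deeper (−0.5 to
−0.9 down the ladder) than the empirically reported −0.28…−0.46, because
the real trajectories flatten earlier under their richer noise floor.
For this reason the configuration stores the study's cutoffs per
construct (`cutoff_mode: "config"`) alongside the default
derive-from-stops mode used for synthetic runs, and the informative-range
table is always computed from the stored study cutoffs.

## Numerical choices and degenerate inputs

- Growth-rate fits: ordinary least squares on `ln(OD × cumulative
  dilution)` vs time, natural log, hours throughout; ≥ 3 readings
  required.
- Elasticity fit: bounded trust-region least squares; `G_max` initialized
  at the maximum observed rate, `E_m` at the expression value nearest
  half of it; positivity enforced by bounds; ≤ 500 residual evaluations,
  convergence at relative parameter change < 1e-10; non-convergence
  raises an error carrying the last iterate. ≥ 3 distinct expression
  values required.
- Null cutoff needs ≥ 2 stop-codon estimates; with zero spread the cutoff
  equals the stop mean.
- Filters use strict inequalities, so a residual of exactly 0.25 or an
  initial ratio of exactly 0.004 is retained.
- Histograms default to 0.05-wide bins; out-of-range values land in edge
  bins. For function distributions, "intermediate" is the 0.1–0.9 band.
- An empty informative window (null cutoff not below the WT margin)
  raises rather than returning a degenerate range.

## Problem sizes

Tests and the analysis scripts run the full seven-construct pipeline at
depth 5×10⁵ per timepoint with the complete 576-variant library —
recovery batteries use 10 seeds (100 for the elasticity-fit noise
study), which characterizes the estimator's behavior well at these
sampling depths since per-seed variation is far smaller than the
tolerances checked.

## Known limitations

- The constant-function assumption makes apparent `F > 1` at very low
  expression an expected artifact; flagged, not corrected.
- Bounds from different constructs can contradict numeric estimates; the
  package flags rather than reconciles.
- The null-refit uses a fixed three-timepoint window; no attempt is made
  to detect per-variant flattening points.
- Epistasis treats null-like as exactly `s = −1`; true selection
  coefficients below −1 (active killing) are not representable.
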
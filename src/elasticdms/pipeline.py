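"""End-to-end orchestration: counts -> selection -> function -> report.

``run_pipeline`` executes the full analysis for one configuration: obtain
count tables (from disk or the synthetic generator), estimate codon-level
selection coefficients per construct with null binning and filtering,
aggregate synonyms, invert to per-molecule function across the expression
ladder, compute expression-by-mutation epistasis against the endogenous
construct, tabulate the informative function ranges, and write the result
bundle with a summary report.

The null-like cutoffs used for binning and bounds are derived from each
table's stop codons (the study's procedure) unless the configuration
pins them to the stored per-construct values; the informative-range table
is always also reported for the configured study cutoffs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig, config_hash
from .elasticity import Construct, function_range
from .function_inference import (
    FunctionEstimate,
    blosum_similarity_table,
    cross_construct_consistency,
    dfe_histogram,
    function_table,
    partition_surface_core,
)
from .selection import CountTable, Klass, aggregate_synonyms, epistasis_table, run_estimation
from .synthetic import (
    LibrarySpec,
    build_library,
    sample_true_function,
    simulate_bulk_competition,
    translate,
)

logger = logging.getLogger("elasticdms")

__all__ = ["PipelineResult", "run_pipeline", "generate_synthetic_tables", "ranges_frame"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    seed: int
    count_tables: dict[str, CountTable] = field(default_factory=dict)
    truth: dict | None = None
    estimates: dict[str, list] = field(default_factory=dict)
    cutoffs: dict[str, float] = field(default_factory=dict)
    aa_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    synonym_deviations: dict[str, pd.DataFrame] = field(default_factory=dict)
    function_estimates: list[FunctionEstimate] = field(default_factory=list)
    consistency: dict = field(default_factory=dict)
    epistasis: dict[str, pd.DataFrame] = field(default_factory=dict)
    ranges: pd.DataFrame | None = None
    dfe_shares: dict[str, dict] = field(default_factory=dict)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(seed).spawn(index + 1)[index].generate_state(1)[0] % 2**31)


def generate_synthetic_tables(
    config: PipelineConfig, seed: int
) -> tuple[dict[str, CountTable], dict]:
    """Synthetic count tables for every configured construct.

    One truth draw (shared across constructs: the same library competes
    under every promoter) and one independent sampling seed per construct.
    """
    spec = LibrarySpec()
    library = build_library(spec)
    dfe = {"preset": config.synthetic.preset, **config.synthetic.dfe}
    truth = sample_true_function(library, dfe, seed=_child_seed(seed, 0))
    tables = {}
    for i, construct in enumerate(config.constructs):
        tables[construct.name] = simulate_bulk_competition(
            truth,
            construct,
            config.params,
            depths=config.synthetic.depth,
            seed=_child_seed(seed, i + 1),
            wt_fraction=config.synthetic.wt_fraction,
        )
    truth_map = {t.variant.key: t.f_true for t in truth}
    wt_aa = {pos: translate(codon) for pos, codon in spec.wt_codons.items()}
    return tables, {"by_variant": truth_map, "wt_aa": wt_aa, "library": library}


def ranges_frame(constructs: list[Construct], params, wt_margin=0.05, cap=0.8) -> pd.DataFrame:
    """Informative function-range table (one row per construct)."""
    rows = []
    for c in constructs:
        rng = function_range(c, params, wt_margin=wt_margin, unbounded_cap=cap)
        rows.append(
            {
                "construct": c.name,
                "expression_strength": c.e,
                "s_cut": c.s_cut,
                "lower": rng.lower,
                "upper": None if rng.unbounded else rng.upper,
                "range": (
                    f"{rng.lower:.2g} and above"
                    if rng.unbounded
                    else f"{rng.lower:.2g}-{rng.upper:.2g}"
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None, seed: int = 1
) -> PipelineResult:
    """Run every stage; optionally write the result bundle under ``outdir``."""
    if not config.constructs:
        raise ValueError("configuration lists no constructs")
    est_cfg = config.estimation
    params = config.params
    digest = config_hash(config)
    result = PipelineResult(config=config, seed=seed)

    if config.counts_dir is not None:
        counts_dir = Path(config.counts_dir)
        for construct in config.constructs:
            path = counts_dir / f"{construct.name}.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    f"no count table for construct {construct.name!r} at {path}"
                )
            result.count_tables[construct.name] = io.read_count_table(path)
        truth_info = None
    else:
        logger.info("generating synthetic count tables (preset=%s)", config.synthetic.preset)
        result.count_tables, truth_info = generate_synthetic_tables(config, seed)
    result.truth = truth_info

    effective_constructs = []
    for construct in config.constructs:
        table = result.count_tables[construct.name]
        fixed = construct.s_cut if est_cfg.cutoff_mode == "config" else None
        ests, cutoff = run_estimation(
            table,
            g_wt=construct.g_wt,
            pseudocount=est_cfg.pseudocount,
            residual_max=est_cfg.residual_max,
            min_initial_ratio=est_cfg.min_initial_ratio,
            n_null_points=est_cfg.n_null_points,
            cutoff=fixed,
        )
        result.estimates[construct.name] = ests
        result.cutoffs[construct.name] = cutoff
        aa_df, dev_df = aggregate_synonyms(
            ests, persist_threshold=est_cfg.persist_threshold, cutoff=cutoff
        )
        result.aa_tables[construct.name] = aa_df
        result.synonym_deviations[construct.name] = dev_df
        effective_constructs.append(dataclasses.replace(construct, s_cut=min(cutoff, 0.0)))
        n_filtered = sum(1 for e in ests if e.klass is Klass.FILTERED)
        logger.info(
            "%s: cutoff=%.3f, %d/%d filtered", construct.name, cutoff, n_filtered, len(ests)
        )
        shares = dfe_histogram(
            aa_df.s.to_numpy(),
            kind="s",
            wt_margin=est_cfg.wt_margin,
            null_mask=(aa_df.klass == Klass.NULL_LIKE.value).to_numpy(),
        ).shares
        result.dfe_shares[construct.name] = shares

    constructs_by_name = {c.name: c for c in effective_constructs}
    result.function_estimates = function_table(
        result.aa_tables,
        constructs_by_name,
        params,
        wt_margin=est_cfg.wt_margin,
        unbounded_cap=est_cfg.unbounded_cap,
    )
    order = [c.name for c in sorted(config.constructs, key=lambda c: -c.e)]
    result.consistency = cross_construct_consistency(result.function_estimates, order)

    endogenous = order[0]
    for name in order[1:]:
        result.epistasis[name] = epistasis_table(
            result.aa_tables[endogenous], result.aa_tables[name]
        )

    result.ranges = ranges_frame(
        config.constructs, params, wt_margin=est_cfg.wt_margin, cap=est_cfg.unbounded_cap
    )

    if outdir is not None:
        _write_bundle(result, Path(outdir), digest, truth_info)
    return result


def _function_frame(estimates: list[FunctionEstimate], order: list[str]) -> pd.DataFrame:
    def cell(v):
        if v is None:
            return ""
        if isinstance(v, (int, float)):
            return f"{v:.4f}"
        return f"{v.kind} {v.value:.4f}" if np.isfinite(v.value) else f"{v.kind} inf"

    rows = []
    for est in estimates:
        row = {"position": est.position, "aa": est.aa}
        for name in order:
            row[name] = cell(est.per_construct.get(name))
        row["combined_f"] = est.combined_f
        row["sd"] = est.sd_across_constructs
        row["n_numeric"] = est.n_numeric
        row["bound"] = cell(est.bound)
        row["inconsistent"] = int(est.inconsistent)
        row["flag_high"] = int(est.flag_high)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_bundle(result: PipelineResult, outdir: Path, digest: str, truth_info) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = result.seed
    for name, table in result.count_tables.items():
        io.write_count_table(table, outdir / "counts" / f"{name}.tsv", seed, digest)
    for name, ests in result.estimates.items():
        io.write_selection_table(ests, outdir / "selection" / f"{name}.tsv", seed, digest)
        io.write_tsv(
            result.aa_tables[name], outdir / "selection" / f"{name}_aa.tsv", seed, digest
        )
        io.write_tsv(
            result.synonym_deviations[name],
            outdir / "selection" / f"{name}_synonym_deviations.tsv",
            seed,
            digest,
        )
    order = [c.name for c in sorted(result.config.constructs, key=lambda c: -c.e)]
    io.write_tsv(
        _function_frame(result.function_estimates, order),
        outdir / "function_estimates.tsv",
        seed,
        digest,
    )
    for name, df in result.epistasis.items():
        io.write_tsv(df, outdir / "epistasis" / f"{name}.tsv", seed, digest)
    io.write_tsv(result.ranges, outdir / "function_ranges.tsv", seed, digest)
    write_report(result, outdir / "report.md", truth_info)


def write_report(result: PipelineResult, path: Path, truth_info=None) -> None:
    """Markdown summary: DFE shares, function distribution, ranges."""
    lines = ["# Bulk-competition analysis report", ""]
    lines.append(f"Configuration digest: {config_hash(result.config)}; seed: {result.seed}")
    lines.append("")
    lines.append("## Distribution of fitness effects per construct")
    lines.append("")
    lines.append("| construct | null-like cutoff | WT-like | intermediate | null-like |")
    lines.append("|---|---|---|---|---|")
    for name, shares in result.dfe_shares.items():
        cut = result.cutoffs[name]
        lines.append(
            f"| {name} | {cut:.3f} | {shares['wt_like']:.2f} | "
            f"{shares['intermediate']:.2f} | {shares['null_like']:.2f} |"
        )
    lines.append("")
    lines.append("## Informative function ranges")
    lines.append("")
    lines.append(result.ranges.to_string(index=False))
    lines.append("")
    numeric = [e.combined_f for e in result.function_estimates if e.combined_f is not None]
    if numeric:
        hist = dfe_histogram(np.array(numeric), kind="f")
        lines.append("## Distribution of per-molecule function (combined estimates)")
        lines.append("")
        lines.append(
            f"n={len(numeric)}; shares: WT-like {hist.shares['wt_like']:.2f}, "
            f"intermediate {hist.shares['intermediate']:.2f}, "
            f"null-like {hist.shares['null_like']:.2f}"
        )
        lines.append("")
    if result.consistency.get("pooled") is not None:
        lines.append(
            f"Cross-construct consistency (pooled R^2 over expression-adjacent pairs): "
            f"{result.consistency['pooled']:.3f}"
        )
        lines.append("")
    surface, core = partition_surface_core(result.function_estimates)
    if len(surface) and len(core):
        lines.append(
            f"Surface positions (582/583/585): median F {np.median(surface):.2f} "
            f"(n={len(surface)}); core positions: median F {np.median(core):.2f} "
            f"(n={len(core)})"
        )
        lines.append("")
    if truth_info is not None:
        wt_aa = truth_info["wt_aa"]
        _, rho = blosum_similarity_table(wt_aa, result.function_estimates)
        if rho is not None:
            lines.append(f"Spearman correlation of BLOSUM62 similarity with function: {rho:.3f}")
            lines.append("")
    path.write_text("\n".join(lines))
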
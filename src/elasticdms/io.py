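"""TSV/JSON input and output for all pipeline artifacts.

Tabular data travel as tab-separated text with ``#``-prefixed header
lines recording the tool version, configuration digest, and seed; fitted
parameters travel as JSON records.  Count tables follow the dialect the
estimation stage reads: one row per codon variant
(``variant_id = POS.CODON``) plus a wild-type reference row flagged
``wt=1``, with one ``t<hours>`` column per sequenced timepoint.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .elasticity import ElasticityFit, ElasticityParams, GrowthCurve
from .selection import CountTable, SelectionEstimate, VariantId

__all__ = [
    "ParseError",
    "header_lines",
    "write_tsv",
    "read_tsv",
    "write_count_table",
    "read_count_table",
    "selection_to_frame",
    "write_selection_table",
    "write_elasticity_fit",
    "read_elasticity_fit",
    "read_growth_curve",
    "write_growth_curve",
    "read_ddg_table",
]

WT_ROW_ID = "WT"


class ParseError(ValueError):
    pass


def header_lines(seed=None, config_digest=None, extra: dict | None = None) -> list[str]:
    lines = [f"# elasticdms {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_digest is not None:
        lines.append(f"# config_hash={config_digest}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def write_tsv(df: pd.DataFrame, path, seed=None, config_digest=None, extra=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(seed, config_digest, extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_count_table(table: CountTable, path, seed=None, config_digest=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tcols = [f"t{g:g}" for g in table.timepoints]
    with open(path, "w") as fh:
        for line in header_lines(seed, config_digest, {"construct": table.construct_name}):
            fh.write(line + "\n")
        fh.write(
            "\t".join(["variant_id", "position", "codon", "aa", "wt_codon", "syn_wt", "wt"] + tcols)
            + "\n"
        )
        for v, row in zip(table.variants, table.counts):
            fields = [
                v.key,
                str(v.position),
                v.codon,
                v.aa,
                str(int(v.is_wt_codon)),
                str(int(v.is_synonymous_wt)),
                "0",
            ] + [_fmt_count(c) for c in row]
            fh.write("\t".join(fields) + "\n")
        wt_fields = [WT_ROW_ID, "0", "", "", "0", "0", "1"] + [
            _fmt_count(c) for c in table.wt_counts
        ]
        fh.write("\t".join(wt_fields) + "\n")


def read_count_table(path) -> CountTable:
    path = Path(path)
    construct_name = path.stem
    header = None
    variants, rows = [], []
    wt_counts = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# construct="):
                    construct_name = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                tcols = [c for c in header if c.startswith("t")]
                try:
                    timepoints = [float(c[1:]) for c in tcols]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad timepoint column: {exc}")
                n_meta = len(header) - len(tcols)
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                counts = [float(x) for x in fields[n_meta:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed count: {exc}")
            if any(c < 0 for c in counts):
                raise ParseError(f"{path}:{lineno}: negative count")
            rec = dict(zip(header[:n_meta], fields[:n_meta]))
            if rec.get("wt") == "1" or rec.get("variant_id") == WT_ROW_ID:
                wt_counts = counts
                continue
            try:
                variants.append(
                    VariantId(
                        position=int(rec["position"]),
                        codon=rec["codon"],
                        aa=rec["aa"],
                        is_wt_codon=rec.get("wt_codon") == "1",
                        is_synonymous_wt=rec.get("syn_wt") == "1",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed variant row: {exc}")
            rows.append(counts)
    if header is None:
        raise ParseError(f"{path}: empty count table")
    if wt_counts is None:
        raise ParseError(
            f"{path}: count table for construct {construct_name!r} has no wild-type row"
        )
    return CountTable(
        construct_name=construct_name,
        timepoints=np.array(timepoints),
        variants=variants,
        counts=np.array(rows),
        wt_counts=np.array(wt_counts),
    )


def selection_to_frame(estimates: list[SelectionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": e.variant.key if e.variant else "",
                "position": e.variant.position if e.variant else None,
                "codon": e.variant.codon if e.variant else "",
                "aa": e.variant.aa if e.variant else "",
                "s": e.s,
                "slope": e.slope,
                "residual_per_timepoint": e.residual_per_timepoint,
                "initial_ratio": e.initial_ratio,
                "n_timepoints_used": e.n_timepoints_used,
                "klass": e.klass.value,
            }
            for e in estimates
        ]
    )


def write_selection_table(estimates, path, seed=None, config_digest=None) -> None:
    write_tsv(selection_to_frame(estimates), path, seed, config_digest)


def write_elasticity_fit(fit: ElasticityFit, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record = {
        "G_max": fit.params.g_max,
        "E_m": fit.params.e_m,
        "rss": fit.rss,
        "n_points": fit.n_points,
    }
    path.write_text(json.dumps(record, indent=2) + "\n")


def read_elasticity_fit(path) -> ElasticityFit:
    record = json.loads(Path(path).read_text())
    return ElasticityFit(
        params=ElasticityParams(g_max=record["G_max"], e_m=record["E_m"]),
        rss=record["rss"],
        n_points=record["n_points"],
    )


def write_growth_curve(curve: GrowthCurve, path) -> None:
    df = pd.DataFrame(
        {
            "time_hr": curve.times,
            "od600": curve.od,
            "cumulative_dilution": curve.cumulative_dilution,
        }
    )
    write_tsv(df, path)


def read_growth_curve(path) -> GrowthCurve:
    df = read_tsv(path)
    missing = {"time_hr", "od600", "cumulative_dilution"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: growth curve missing columns {sorted(missing)}")
    return GrowthCurve(
        times=df.time_hr.to_numpy(),
        od=df.od600.to_numpy(),
        cumulative_dilution=df.cumulative_dilution.to_numpy(),
    )


def read_ddg_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"position", "aa", "ddg_kcal_mol"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: ddG table missing columns {sorted(missing)}")
    return df
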
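"""Readers and writers for every table the pipeline touches.

Conventions: UTF-8, tab-separated, "." decimal separator, missing values
spelled ``NA``. Floats are written with Python's shortest round-trip
representation, so write-then-read reproduces values exactly. Metadata rides
in ``#``-prefixed header comment lines (``# key=value``). The beta-matrix
reader additionally understands the GEO series-matrix dialect
(``!``-prefixed metadata, data between the table begin/end markers, quoted
identifiers).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, ValidationError
from .types import (
    BetaMatrix,
    ControlProfile,
    CtTable,
    GroundTruth,
    ImprintedSiteSet,
    ProbeAnnotation,
    SampleSheet,
    SignalMatrix,
    StateMatrix,
)

_TRUE_TOKENS = {"true", "True", "TRUE", "1"}
_FALSE_TOKENS = {"false", "False", "FALSE", "0"}

GEO_TABLE_BEGIN = "!series_matrix_table_begin"
GEO_TABLE_END = "!series_matrix_table_end"


# ---------------------------------------------------------------------------
# low-level helpers


def _header_block(table: str, params: Mapping[str, Any] | None = None) -> str:
    lines = [f"# imprintarray={__version__}", f"# table={table}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def _read_lines(path: str | Path) -> list[str]:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return text.splitlines()


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _data_lines(lines: list[str]) -> list[str]:
    return [ln for ln in lines if ln.strip() and not ln.startswith("#")]


def _parse_tsv(data: list[str], path: str | Path) -> pd.DataFrame:
    if not data:
        raise FormatError(f"{path}: empty table")
    widths = {ln.count("\t") for ln in data}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (inconsistent column counts)")
    return pd.read_csv(
        _io.StringIO("\n".join(data)),
        sep="\t",
        dtype=str,
        na_values=["NA"],
        keep_default_na=False,
    )


def _parse_bool(series: pd.Series, column: str, path: str | Path) -> pd.Series:
    def one(token: Any) -> bool:
        if token in _TRUE_TOKENS:
            return True
        if token in _FALSE_TOKENS:
            return False
        raise FormatError(f"{path}: bad boolean {token!r} in column {column}")

    return series.map(one)


def _cell_to_float(token: Any) -> float:
    """Correctly-rounded float parse; anything non-numeric becomes missing."""
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    try:
        return float(token)
    except (TypeError, ValueError):
        return np.nan


def _float_columns(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.apply(lambda col: col.map(_cell_to_float)).astype(float)


def _write_text(path: str | Path, text: str) -> None:
    try:
        Path(path).write_text(text, encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def _frame_tsv(frame: pd.DataFrame, index: bool = True) -> str:
    # repr(float(v)) is Python's shortest round-trip rendering, so
    # write-then-read reproduces every float bit-exactly
    return frame.to_csv(
        sep="\t", na_rep="NA", index=index, float_format=lambda v: repr(float(v))
    )


# ---------------------------------------------------------------------------
# annotation / sample sheet


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    frame = annotation.frame.copy()
    frame["is_imprinted_gene"] = frame["is_imprinted_gene"].map({True: "true", False: "false"})
    _write_text(path, _header_block("annotation") + _frame_tsv(frame))


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = _parse_tsv(_data_lines(_read_lines(path)), path)
    required = ["probe_id", "gene_symbol", "is_imprinted_gene", "imprint_direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    df["is_imprinted_gene"] = _parse_bool(df["is_imprinted_gene"], "is_imprinted_gene", path)
    df = df.set_index("probe_id")
    try:
        return ProbeAnnotation(df[["gene_symbol", "is_imprinted_gene", "imprint_direction"]])
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_sheet(samples: SampleSheet, path: str | Path) -> None:
    _write_text(path, _header_block("samples") + _frame_tsv(samples.frame))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _parse_tsv(_data_lines(_read_lines(path)), path)
    required = ["sample_id", "line_id", "sample_class", "replicate_index"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sample-sheet columns {missing}")
    try:
        df["replicate_index"] = df["replicate_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: replicate_index must be an integer") from exc
    try:
        return SampleSheet(df.set_index("sample_id"))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# numeric matrices (plain TSV and GEO series-matrix dialects)


def write_matrix(
    values: pd.DataFrame,
    path: str | Path,
    dialect: str = "plain_tsv",
    table: str = "matrix",
    params: Mapping[str, Any] | None = None,
) -> None:
    if dialect == "plain_tsv":
        frame = values.copy()
        frame.index.name = "probe_id"
        _write_text(path, _header_block(table, params) + _frame_tsv(frame))
    elif dialect == "geo_series_matrix":
        out = ["!Series_title\t\"imprintarray export\""]
        for key, value in (params or {}).items():
            out.append(f"!Series_{key}\t\"{value}\"")
        out.append(GEO_TABLE_BEGIN)
        header = "\t".join(['"ID_REF"'] + [f'"{c}"' for c in values.columns])
        out.append(header)
        body = values.to_csv(
            sep="\t", na_rep="null", header=False, float_format=lambda v: repr(float(v))
        )
        for line in body.splitlines():
            probe, _, rest = line.partition("\t")
            out.append(f'"{probe}"\t{rest}')
        out.append(GEO_TABLE_END)
        _write_text(path, "\n".join(out) + "\n")
    else:
        raise FormatError(f"unknown matrix dialect {dialect!r}")


def _numeric_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise FormatError(f"{path}: matrix needs a probe column and at least one sample")
    idx = df.columns[0]
    if df[idx].duplicated().any():
        dupes = df[idx][df[idx].duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate probe ids {dupes[:5]}")
    out = df.set_index(idx)
    out.index.name = "probe_id"
    return _float_columns(out)


def read_matrix(path: str | Path, dialect: str = "plain_tsv") -> pd.DataFrame:
    """Read a probe x sample numeric grid; non-numeric cells become missing."""
    lines = _read_lines(path)
    if dialect == "plain_tsv":
        return _numeric_frame(_parse_tsv(_data_lines(lines), path), path)
    if dialect == "geo_series_matrix":
        try:
            begin = lines.index(GEO_TABLE_BEGIN)
            end = lines.index(GEO_TABLE_END)
        except ValueError as exc:
            raise FormatError(f"{path}: missing series-matrix table markers") from exc
        block = [ln for ln in lines[begin + 1 : end] if ln.strip()]
        block = ["\t".join(tok.strip('"') for tok in ln.split("\t")) for ln in block]
        df = _parse_tsv(block, path)
        df = df.replace({"null": None})
        return _numeric_frame(df, path)
    raise FormatError(f"unknown matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# signals, beta, states, truth


def write_signals(signals: SignalMatrix, path: str | Path) -> None:
    """Paired channels in one table: columns ``<sample>:methylated`` etc."""
    merged = pd.concat(
        {
            "methylated": signals.methylated,
            "unmethylated": signals.unmethylated,
        },
        axis=1,
    )
    merged.columns = [f"{sample}:{channel}" for channel, sample in merged.columns]
    # interleave per sample for readability
    order = [
        f"{sample}:{channel}"
        for sample in signals.sample_ids
        for channel in ("methylated", "unmethylated")
    ]
    merged = merged[order]
    merged.index.name = "probe_id"
    _write_text(path, _header_block("signals") + _frame_tsv(merged))


def read_signals(path: str | Path) -> SignalMatrix:
    grid = read_matrix(path, dialect="plain_tsv")
    meth_cols = [c for c in grid.columns if c.endswith(":methylated")]
    unmeth_cols = [c for c in grid.columns if c.endswith(":unmethylated")]
    samples_m = [c.rsplit(":", 1)[0] for c in meth_cols]
    samples_u = [c.rsplit(":", 1)[0] for c in unmeth_cols]
    if not samples_m or samples_m != samples_u:
        raise FormatError(f"{path}: signals table needs paired :methylated/:unmethylated columns")
    meth = grid[meth_cols]
    meth.columns = samples_m
    unmeth = grid[unmeth_cols]
    unmeth.columns = samples_u
    try:
        return SignalMatrix(methylated=meth, unmethylated=unmeth)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_beta(beta: BetaMatrix, path: str | Path) -> None:
    write_matrix(
        beta.values, path, table="beta", params={"normalized": str(beta.normalized).lower()}
    )


def read_beta(path: str | Path) -> BetaMatrix:
    lines = _read_lines(path)
    meta = _parse_header(lines)
    values = _numeric_frame(_parse_tsv(_data_lines(lines), path), path)
    normalized = meta.get("normalized", "false") in _TRUE_TOKENS
    try:
        return BetaMatrix(values=values, normalized=normalized)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_anchors(profile: ControlProfile, path: str | Path) -> None:
    frame = profile.frame.copy()
    frame["usable"] = frame["usable"].map({True: "true", False: "false"})
    frame.index.name = "probe_id"
    _write_text(
        path,
        _header_block("anchors", {"eps_range": profile.eps_range}) + _frame_tsv(frame),
    )


def read_anchors(path: str | Path) -> ControlProfile:
    lines = _read_lines(path)
    meta = _parse_header(lines)
    df = _parse_tsv(_data_lines(lines), path)
    required = ["probe_id", "beta_full", "beta_zero", "beta_half", "usable"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing anchor columns {missing}")
    df = df.set_index("probe_id")
    for col in ("beta_full", "beta_zero", "beta_half"):
        df[col] = df[col].map(_cell_to_float).astype(float)
    df["usable"] = _parse_bool(df["usable"], "usable", path)
    return ControlProfile(frame=df, eps_range=float(meta.get("eps_range", "nan")))


def write_states(states: StateMatrix, path: str | Path) -> None:
    frame = states.states.copy()
    frame.index.name = "probe_id"
    params = {
        "t_low": states.t_low,
        "t_high": states.t_high,
        "aggregation": states.aggregation,
    }
    _write_text(path, _header_block("states", params) + _frame_tsv(frame))


def read_states(path: str | Path) -> StateMatrix:
    lines = _read_lines(path)
    meta = _parse_header(lines)
    df = _parse_tsv(_data_lines(lines), path)
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first column must be probe_id")
    df = df.set_index("probe_id")
    try:
        return StateMatrix(
            states=df,
            t_low=float(meta.get("t_low", "nan")),
            t_high=float(meta.get("t_high", "nan")),
            aggregation=meta.get("aggregation", "replicate_mean"),
        )
    except (ValidationError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    frame = truth.frame.copy()
    frame["is_true_dmr"] = frame["is_true_dmr"].map({True: "true", False: "false"})
    means = truth.class_means.add_prefix("mean:")
    merged = pd.concat([frame, means], axis=1)
    merged.index.name = "probe_id"
    _write_text(path, _header_block("truth") + _frame_tsv(merged))


def read_truth(path: str | Path) -> GroundTruth:
    df = _parse_tsv(_data_lines(_read_lines(path)), path)
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: missing probe_id column")
    df = df.set_index("probe_id")
    mean_cols = [c for c in df.columns if c.startswith("mean:")]
    if "is_true_dmr" not in df.columns or not mean_cols:
        raise FormatError(f"{path}: truth table needs is_true_dmr and mean:* columns")
    means = _float_columns(df[mean_cols])
    means.columns = [c.split(":", 1)[1] for c in mean_cols]
    frame = df[["is_true_dmr", "imprint_direction"]].copy()
    frame["is_true_dmr"] = _parse_bool(frame["is_true_dmr"], "is_true_dmr", path)
    return GroundTruth(frame=frame, class_means=means)


def write_site_set(sites: ImprintedSiteSet, annotation: ProbeAnnotation, path: str | Path) -> None:
    frame = sites.states.copy()
    frame.insert(0, "gene_symbol", annotation.frame.loc[sites.probe_ids, "gene_symbol"])
    frame.index.name = "probe_id"
    params = {"discordance": sites.discordance, "n_sites": sites.n_sites, "n_genes": sites.n_genes}
    _write_text(path, _header_block("imprinted_sites", params) + _frame_tsv(frame))


def read_site_set(path: str | Path) -> ImprintedSiteSet:
    lines = _read_lines(path)
    meta = _parse_header(lines)
    data = _data_lines(lines)
    if not data:
        raise FormatError(f"{path}: empty site-set table")
    df = _parse_tsv(data, path)
    if df.columns[0] != "probe_id" or "gene_symbol" not in df.columns:
        raise FormatError(f"{path}: site set needs probe_id and gene_symbol columns")
    df = df.set_index("probe_id")
    genes = sorted(df["gene_symbol"].unique()) if len(df) else []
    return ImprintedSiteSet(
        discordance=int(meta.get("discordance", "0")),
        probe_ids=list(df.index),
        states=df.drop(columns=["gene_symbol"]),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# qPCR tables


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    frame = ct.data.copy()
    frame["is_housekeeping"] = (
        frame["gene"].isin(ct.housekeeping_genes).map({True: "true", False: "false"})
    )
    _write_text(path, _header_block("ct") + _frame_tsv(frame, index=False))


def read_ct_table(path: str | Path) -> CtTable:
    df = _parse_tsv(_data_lines(_read_lines(path)), path)
    required = ["gene", "group", "replicate", "ct", "is_housekeeping"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing Ct columns {missing}")
    df["ct"] = df["ct"].map(_cell_to_float).astype(float)
    hk_flags = _parse_bool(df["is_housekeeping"], "is_housekeeping", path)
    housekeeping = frozenset(df.loc[hk_flags, "gene"])
    try:
        return CtTable(
            data=df[["gene", "group", "replicate", "ct"]].copy(), housekeeping_genes=housekeeping
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# generic report writer


def write_report(
    frame: pd.DataFrame,
    path: str | Path,
    table: str = "report",
    params: Mapping[str, Any] | None = None,
    index: bool = True,
) -> None:
    """Deterministic, diff-stable TSV with a version-stamped header.

    The same frame and parameters always produce byte-identical output; an
    empty frame yields a header-only table.
    """
    _write_text(path, _header_block(table, params) + _frame_tsv(frame, index=index))
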
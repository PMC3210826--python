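"""File formats, run configuration and the run log.

All tabular formats are plain text: UTF-8, tab-separated matrices with '.'
decimals and unquoted identifiers, GMT gene-set files (name TAB description
TAB members...), comma-separated design tables and long-format Ct tables.
Gene identifiers are case-sensitive opaque strings; matching between GMT
files and matrices is exact.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import (
    RESERVED_ANNOTATION_COLUMNS,
    CtTable,
    DesignTable,
    ExpressionMatrix,
    GeneSetCollection,
)

_FLOAT_FORMAT = "%.10g"


# -- expression matrices -------------------------------------------------
def read_expression_tsv(path: str | Path, log_scale: bool = False) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column ``probe``; the reserved
    annotation columns ``negative_control`` and ``target`` are split off)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "probe" not in df.columns:
        raise ValueError(f"{path}: expected a 'probe' column")
    df = df.set_index("probe")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate probe identifiers: {dup}")
    ann_cols = [c for c in RESERVED_ANNOTATION_COLUMNS if c in df.columns]
    annotations = None
    if ann_cols:
        annotations = df[ann_cols].copy()
        if "negative_control" in annotations:
            annotations["negative_control"] = annotations[
                "negative_control"
            ].map({"True": True, "False": False, "1": True, "0": False})
        df = df.drop(columns=ann_cols)
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[probe, col]!r} "
                f"at probe {probe!r}, sample {col!r}"
            )
        values[col] = converted
    values.index.name = None
    if annotations is not None:
        annotations.index.name = None
    return ExpressionMatrix(values, annotations=annotations, log_scale=log_scale)


def write_expression_tsv(x: ExpressionMatrix, path: str | Path) -> None:
    out = pd.DataFrame(index=x.probes)
    if x.annotations is not None:
        for c in RESERVED_ANNOTATION_COLUMNS:
            if c in x.annotations:
                out[c] = x.annotations[c]
    out = pd.concat([out, x.values], axis=1)
    out.index.name = "probe"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


# -- gene sets -----------------------------------------------------------
def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, members")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name '{name}'")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *collection[name]]) + "\n")


# -- design tables -------------------------------------------------------
def read_design_csv(
    path: str | Path, matrix: ExpressionMatrix | None = None
) -> DesignTable:
    """Read a design CSV (columns ``sample``, ``group``, optional ``dye``,
    ``array``, ``include``). With ``matrix`` given, design samples missing
    from the matrix — or matrix samples missing from the design — raise."""
    design = DesignTable(pd.read_csv(path))
    if matrix is not None:
        matrix_samples = set(matrix.samples)
        extra = [s for s in design.samples if s not in matrix_samples]
        if extra:
            raise ValueError(f"{path}: design samples not in matrix: {extra}")
        known = set(design.table["sample"])
        unknown = [s for s in matrix.samples if s not in known]
        if unknown:
            raise ValueError(f"{path}: matrix samples not in design: {unknown}")
    return design


def write_design_csv(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


# -- Ct tables -----------------------------------------------------------
def read_ct_csv(
    path: str | Path,
    housekeeping: list[str] | tuple[str, ...],
    efficiency: float | Mapping[str, float] = 2.0,
) -> CtTable:
    return CtTable(pd.read_csv(path), tuple(housekeeping), efficiency)


def write_ct_csv(t: CtTable, path: str | Path) -> None:
    t.wells.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# -- run configuration ---------------------------------------------------
@dataclass
class RunConfig:
    """Configuration of an orchestrated pipeline run.

    Every stochastic stage has an explicit seed derived from ``seed``;
    ``stages`` toggles individual stages on or off.
    """

    out_dir: str = "toxsetpipe_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True,
            "normalize": True,
            "de": True,
            "gsea": True,
            "pcr": True,
            "dose": True,
        }
    )
    simulate: dict[str, Any] = field(default_factory=dict)
    normalize: dict[str, Any] = field(
        default_factory=lambda: {"span": 0.4, "trim": 0.05}
    )
    de: dict[str, Any] = field(
        default_factory=lambda: {"stat": "fs", "n_perm": 500, "alpha": 0.05}
    )
    gsea: dict[str, Any] = field(
        default_factory=lambda: {
            "method": "both",
            "n_resample": 500,
            "alpha": 0.05,
            "rank_scope": "global",
        }
    )
    pcr: dict[str, Any] = field(default_factory=lambda: {"n_rand": 2000})
    dose: dict[str, Any] = field(
        default_factory=lambda: {
            "days": 11,
            "hours_per_day": 1.0,
            "concentration_mg_m3": 42.4,
            "inhaled_volume_rate_m3_hr": 0.0018,
            "organ_mass_mg": 274.0,
            "ssa_m2_per_g": 107.7,
            "measured_mg_per_kg": None,
        }
    )
    exclude_arrays: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        config = cls()
        for key, value in raw.items():
            if not hasattr(config, key):
                raise ValueError(f"unknown configuration key '{key}'")
            current = getattr(config, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(config, key, value)
        return config

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "stages": self.stages,
            "simulate": self.simulate,
            "normalize": self.normalize,
            "de": self.de,
            "gsea": self.gsea,
            "pcr": self.pcr,
            "dose": self.dose,
            "exclude_arrays": self.exclude_arrays,
        }
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


class RunLog:
    """Timestamped record of every filtering decision and parameter.

    Each dropped probe count, excluded array, seed and threshold count is
    recorded exactly once; ``write`` emits a stable text log (timestamps
    are recorded but not written, so reruns are byte-identical).
    """

    def __init__(self) -> None:
        self.entries: list[dict[str, Any]] = []

    def record(self, stage: str, event: str, **details: Any) -> None:
        self.entries.append(
            {
                "time": _dt.datetime.now().isoformat(timespec="seconds"),
                "stage": stage,
                "event": event,
                **details,
            }
        )

    def counts_reconcile(self, rows_in: int, rows_out: int, rows_dropped: int) -> bool:
        return rows_in == rows_out + rows_dropped

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for entry in self.entries:
                details = {
                    k: v for k, v in entry.items() if k not in ("time", "stage", "event")
                }
                detail_str = " ".join(f"{k}={v}" for k, v in sorted(details.items()))
                handle.write(f"[{entry['stage']}] {entry['event']} {detail_str}".rstrip() + "\n")


def write_table_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Deterministic TSV writer used for all report tables."""
    table.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)
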
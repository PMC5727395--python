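"""Table readers/writers and run manifests.

All tables are UTF-8 TSV with a header row and "." decimals. Genotype
presence columns accept either 1/0 or "+"/"-" (including the Unicode
minus) and are normalized to integers on read. Schema violations raise
:class:`TableSchemaError` naming the offending row and column.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableSchemaError",
    "read_table",
    "write_table",
    "read_isolate_table",
    "write_isolate_table",
    "read_fitness_table_frame",
    "read_allele_series",
    "read_ramp_series",
    "read_fluctuation_counts",
    "write_fluctuation_counts",
    "RunManifest",
    "write_manifest",
]

_PLUS_MINUS = {"+": 1, "-": 0, "−": 0, "1": 1, "0": 0}


class TableSchemaError(ValueError):
    """A table did not match its expected schema."""


def _normalize_mark(value, row: int, column: str) -> int:
    s = str(value).strip()
    if s not in _PLUS_MINUS:
        raise TableSchemaError(
            f"row {row}, column {column!r}: {value!r} is not a presence mark (+/- or 1/0)"
        )
    return _PLUS_MINUS[s]


def read_table(
    path,
    required: Sequence[str],
    numeric: Sequence[str] = (),
    mark_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV, check required columns, coerce numeric and presence
    columns; errors name the row (0-based data row) and column."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in required:
        if col not in df.columns:
            raise TableSchemaError(f"missing required column {col!r} in {path}")
    for col in numeric:
        vals = []
        for i, v in enumerate(df[col]):
            try:
                vals.append(float(v))
            except (TypeError, ValueError):
                raise TableSchemaError(
                    f"row {i}, column {col!r}: {v!r} is not numeric"
                ) from None
        df[col] = vals
    for col in mark_columns:
        df[col] = [_normalize_mark(v, i, col) for i, v in enumerate(df[col])]
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_isolate_table(path) -> pd.DataFrame:
    """Isolate x mutation presence matrix; all columns are marks."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns.duplicated().any():
        raise TableSchemaError("mutation ids must be unique")
    for col in df.columns:
        df[col] = [_normalize_mark(v, i, col) for i, v in enumerate(df[col])]
    return df.astype(int)


def write_isolate_table(df: pd.DataFrame, path) -> None:
    write_table(df.astype(int), path)


def read_fitness_table_frame(path) -> pd.DataFrame:
    """Fitness-table TSV: gene mark columns + fitness_improvement, sem, n."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    meta = [c for c in ("fitness_improvement", "sem", "n") if c in df.columns]
    if "fitness_improvement" not in meta:
        raise TableSchemaError("missing required column 'fitness_improvement'")
    gene_cols = [c for c in df.columns if c not in meta]
    if not gene_cols:
        raise TableSchemaError("no genotype mark columns found")
    return read_table(path, required=meta, numeric=meta, mark_columns=gene_cols)


def read_allele_series(path) -> pd.DataFrame:
    """Long-format allele-frequency series: timepoint, mutation,
    frequency[, sd]."""
    df = read_table(
        path,
        required=("timepoint", "mutation", "frequency"),
        numeric=("timepoint", "frequency") + (("sd",) if "sd" in pd.read_csv(path, sep="\t", nrows=0).columns else ()),
    )
    return df


def read_ramp_series(path) -> pd.DataFrame:
    """Ramp trajectory: (transfer, generations, concentration[, growth_rate])."""
    cols = pd.read_csv(path, sep="\t", nrows=0).columns
    numeric = [c for c in ("transfer", "generations", "concentration", "growth_rate") if c in cols]
    return read_table(path, required=("generations", "concentration"), numeric=numeric)


def read_fluctuation_counts(path):
    """Fluctuation-test TSV: a ``# N_t=<cells>`` header comment followed
    by a single ``count`` column, one culture per line. Returns
    (counts, N_t)."""
    path = Path(path)
    n_t = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "N_t" in line:
                n_t = float(line.split("=", 1)[1])
                break
    if n_t is None:
        raise TableSchemaError("missing '# N_t=<cells>' header comment")
    df = read_table(path, required=("count",), numeric=("count",))
    counts = df["count"].to_numpy()
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise TableSchemaError("counts must be non-negative integers")
    return tuple(int(c) for c in counts), n_t


def write_fluctuation_counts(counts, n_t: float, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# N_t={n_t!r}\n")
        fh.write("count\n")
        for c in counts:
            fh.write(f"{int(c)}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Everything needed to re-execute a run bit-identically: config
    echo, seed, package version, timestamps and file digests."""

    def __init__(self, command: str, config: Mapping | None = None, seed: int | None = None):
        from . import __version__

        self.data = {
            "command": command,
            "config": dict(config) if config else {},
            "seed": seed,
            "package": "clonalforge",
            "version": __version__,
            "started_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "inputs": {},
            "outputs": {},
        }

    def add_input(self, path) -> None:
        self.data["inputs"][str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.data["outputs"][str(path)] = _sha256(path)

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data["finished_utc"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)
            fh.write("\n")


def write_manifest(path, command: str, config=None, seed=None, inputs=(), outputs=()):
    m = RunManifest(command, config=config, seed=seed)
    for p in inputs:
        m.add_input(p)
    for p in outputs:
        m.add_output(p)
    m.write(path)
    return m
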
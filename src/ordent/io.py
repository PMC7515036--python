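"""Series input and result output.

Accepted inputs are plain text (one value per line) and CSV with an
optional header, selecting a column by name or index.  Results are written
as TSV or JSON with 17 significant digits so a round trip reproduces every
value bit-exactly.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import EntropyTriangle


def read_series(path, column=None) -> np.ndarray:
    """Read a numeric series from a text or CSV file (``-`` for stdin).

    Without ``column`` the file is parsed as one value per line; with
    ``column`` (name or integer index) it is parsed as CSV, header
    detected automatically.
    """
    if str(path) == "-":
        source = sys.stdin
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no such series file: {p}")
        source = p
    if column is None:
        try:
            values = np.loadtxt(source, dtype=np.float64, ndmin=1)
        except ValueError as exc:
            raise ValueError(f"could not parse {path!s} as numbers: {exc}") from exc
        if values.ndim != 1:
            raise ValueError(
                f"{path!s} has {values.shape[1]} columns; pass column= to pick one"
            )
    else:
        header = "infer"
        if isinstance(column, str) and column.isdigit():
            column = int(column)
        if isinstance(column, int):
            header = None
            # tolerate a header line in positional selection
            df = pd.read_csv(source, header=None, skip_blank_lines=True)
            col = df.iloc[:, column]
            if not np.issubdtype(col.dtype, np.number):
                col = pd.to_numeric(col.iloc[1:], errors="raise")
            values = col.to_numpy(dtype=np.float64)
        else:
            df = pd.read_csv(source, header=0, skip_blank_lines=True)
            if column not in df.columns:
                raise ValueError(
                    f"column {column!r} not in {list(df.columns)} of {path!s}"
                )
            values = df[column].to_numpy(dtype=np.float64)
    if values.size < 2:
        raise ValueError(
            f"{path!s} holds {values.size} value(s); a series needs at least 2"
        )
    return values


def write_series(values, path) -> None:
    """Write a series as plain text, one full-precision value per line."""
    out = sys.stdout if str(path) == "-" else open(path, "w")
    try:
        for v in np.asarray(values).ravel():
            out.write(f"{v:.17g}\n")
    finally:
        if out is not sys.stdout:
            out.close()


def write_triangle(triangle: EntropyTriangle, path, fmt: str = "tsv") -> None:
    """Write an entropy triangle as TSV (d, m, n_words, H_nats) or JSON."""
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
    out = sys.stdout if str(path) == "-" else open(path, "w")
    try:
        if fmt == "tsv":
            out.write("d\tm\tn_words\tH_nats\n")
            for (d, m), h in sorted(triangle.values.items()):
                out.write(f"{d}\t{m}\t{triangle.n_words[(d, m)]}\t{h:.17g}\n")
        else:
            payload = {
                "max_order": triangle.max_order,
                "cells": [
                    {
                        "d": d,
                        "m": m,
                        "n_words": triangle.n_words[(d, m)],
                        "H_nats": float(f"{h:.17g}"),
                    }
                    for (d, m), h in sorted(triangle.values.items())
                ],
            }
            json.dump(payload, out, indent=2)
            out.write("\n")
    finally:
        if out is not sys.stdout:
            out.close()


def read_triangle(path) -> EntropyTriangle:
    """Read back a triangle written by :func:`write_triangle` (either format)."""
    text = Path(path).read_text()
    values: dict[tuple[int, int], float] = {}
    n_words: dict[tuple[int, int], int] = {}
    if text.lstrip().startswith("{"):
        payload = json.loads(text)
        max_order = payload["max_order"]
        for cell in payload["cells"]:
            values[(cell["d"], cell["m"])] = cell["H_nats"]
            n_words[(cell["d"], cell["m"])] = cell["n_words"]
    else:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        for row in df.itertuples(index=False):
            values[(int(row.d), int(row.m))] = float(row.H_nats)
            n_words[(int(row.d), int(row.m))] = int(row.n_words)
        max_order = max(d + m - 1 for d, m in values)
    return EntropyTriangle(max_order=max_order, values=values, n_words=n_words)
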
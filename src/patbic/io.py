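"""Readers for matrix / network files and the biclustering solution writer.

Matrix files: ARFF (via scipy) or delimited text whose first line holds the
column identifiers and whose first field per line holds the row identifier
(tab, space or comma delimited; ``auto`` sniffs the header).  Network
files: delimited edge lists with user-specified column indexes for the two
nodes and the interaction weight.

Solutions are written as human-readable text plus a JSON sidecar
(``<path>.json``) carrying row ids, column ids, pattern symbols, the
assumption and per-row adjustments, so solutions round-trip exactly.
"""

from __future__ import annotations

import json
import math
from fractions import Fraction
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .datasets import NumericDataset, WeightedNetwork
from .errors import ConfigError, FormatError
from .models import Bicluster

__all__ = ["read_matrix", "read_network", "write_biclusters", "read_biclusters"]

DEFAULT_MISSING_MARKERS = ("", "NA", "NaN", "?")

_DELIMITERS = {"tab": "\t", "comma": ",", "space": None}


def _sniff(header: str) -> str:
    for name in ("tab", "comma", "space"):
        if len(header.split(_DELIMITERS[name])) >= 2:
            return name
    raise FormatError("could not sniff a delimiter from the header line")


def _split(line: str, delimiter: str) -> List[str]:
    sep = _DELIMITERS[delimiter]
    return [f.strip() for f in (line.split(sep) if sep else line.split())]


def read_matrix(
    path,
    format: str = "delimited",
    delimiter: str = "auto",
    missing_marker=None,
) -> NumericDataset:
    """Read a real-valued matrix from an ARFF or delimited text file.

    Unparseable cells and cells equal to a missing marker become missing.
    """
    path = Path(path)
    if format == "arff":
        return _read_arff(path)
    if format != "delimited":
        raise ConfigError(f"unknown matrix format {format!r}")
    if missing_marker is None:
        markers = set(DEFAULT_MISSING_MARKERS)
    elif isinstance(missing_marker, str):
        markers = {missing_marker}
    else:
        markers = set(missing_marker)

    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() != ""
    ]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header line and at least one data line")
    if delimiter == "auto":
        delimiter = _sniff(lines[0])
    elif delimiter not in _DELIMITERS:
        raise ConfigError(f"unknown delimiter {delimiter!r}")
    header = _split(lines[0], delimiter)
    col_ids = header[1:] if len(header) > 1 else header
    # headers may or may not carry a corner label for the id column; detect
    # by field count on the first data line
    first = _split(lines[1], delimiter)
    if len(first) == len(header) + 1:
        col_ids = header
    n_cols = len(col_ids)

    row_ids: List[str] = []
    rows: List[List[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = _split(ln, delimiter)
        if len(fields) != n_cols + 1:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, "
                f"expected {n_cols + 1}"
            )
        row_ids.append(fields[0])
        vals = []
        for f in fields[1:]:
            if f in markers:
                vals.append(math.nan)
                continue
            try:
                vals.append(float(f))
            except ValueError:
                vals.append(math.nan)
        rows.append(vals)
    return NumericDataset(row_ids, col_ids, np.array(rows, dtype=float))


def _read_arff(path: Path) -> NumericDataset:
    from scipy.io import arff

    data, meta = arff.loadarff(str(path))
    names = list(meta.names())
    numeric = [n for n in names if meta[n][0] == "numeric"]
    # a nominal/string attribute, when present, provides row identifiers
    id_attr = next((n for n in names if n not in numeric), None)
    if id_attr is not None:
        raw = data[id_attr]
        row_ids = [
            v.decode() if isinstance(v, bytes) else str(v) for v in raw
        ]
    else:
        row_ids = [f"i{k}" for k in range(len(data))]
    grid = np.column_stack([np.asarray(data[n], dtype=float) for n in numeric])
    return NumericDataset(row_ids, numeric, grid)


def read_network(
    path,
    node1_idx: int,
    node2_idx: int,
    weight_idx: int,
    bidirectional: bool = False,
    delimiter: str = "auto",
) -> WeightedNetwork:
    """Read a weighted edge list (one interaction per line after the
    header); the three column indexes select the nodes and the weight."""
    path = Path(path)
    idxs = (node1_idx, node2_idx, weight_idx)
    if len(set(idxs)) != 3 or any(i < 0 for i in idxs):
        raise ConfigError(
            f"node/weight column indexes must be distinct and >= 0, got {idxs}"
        )
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header line and at least one entry")
    if delimiter == "auto":
        delimiter = _sniff(lines[0])
    header = _split(lines[0], delimiter)
    if max(idxs) >= len(header):
        raise ConfigError(
            f"column index {max(idxs)} out of range for header with "
            f"{len(header)} columns"
        )
    edges = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = _split(ln, delimiter)
        if max(idxs) >= len(fields):
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, "
                f"needs at least {max(idxs) + 1}"
            )
        try:
            w = float(fields[weight_idx])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric weight "
                f"{fields[weight_idx]!r}"
            ) from None
        edges.append((fields[node1_idx], fields[node2_idx], w))
    return WeightedNetwork(edges, bidirectional=bidirectional)


# ---------------------------------------------------------------------------
# solution writer
# ---------------------------------------------------------------------------

def _adjustment_json(v):
    if isinstance(v, Fraction):
        return [v.numerator, v.denominator]
    return v


def _adjustment_from_json(v):
    if isinstance(v, list):
        return Fraction(v[0], v[1])
    return v


def write_biclusters(
    solution: Sequence[Bicluster], path, detail: str = "rows_cols"
) -> None:
    """Write a solution as human-readable text plus a JSON sidecar.

    detail levels: ``stats`` (sizes, assumption, quality, p-value),
    ``rows_cols`` (adds the row and column identifiers), ``values`` (adds
    pattern symbols and per-row adjustments).
    """
    if detail not in ("stats", "rows_cols", "values"):
        raise ConfigError(f"unknown detail level {detail!r}")
    if not solution and detail != "stats":
        raise ConfigError("empty solution: only detail='stats' is writable")
    path = Path(path)
    lines = [f"# biclustering solution: {len(solution)} bicluster(s)"]
    for k, b in enumerate(solution, 1):
        lines.append(
            f"bicluster {k}: |I|={b.n_rows} |J|={b.n_cols} "
            f"assumption={b.assumption} noisy={b.noisy_fraction:.3f} "
            f"missing={b.missing_fraction:.3f}"
            + (f" p_value={b.p_value:.3e} (binomial stand-in model)"
               if b.p_value is not None else "")
        )
        if detail in ("rows_cols", "values"):
            lines.append("  rows: " + " ".join(b.rows))
            lines.append("  cols: " + " ".join(b.cols))
        if detail == "values":
            lines.append(
                "  pattern: " + " ".join(str(p) for p in b.pattern)
            )
            if b.adjustments:
                lines.append(
                    "  adjustments: " + " ".join(
                        f"{r}={b.adjustments[r]}" for r in b.rows
                        if r in b.adjustments
                    )
                )
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "n_biclusters": len(solution),
        "biclusters": [
            {
                "rows": list(b.rows),
                "cols": list(b.cols),
                "pattern": [
                    int(p) if isinstance(p, (int, np.integer)) else p
                    for p in b.pattern
                ],
                "assumption": b.assumption,
                "orientation": b.orientation,
                "adjustments": {
                    r: _adjustment_json(v) for r, v in b.adjustments.items()
                },
                "noisy_fraction": b.noisy_fraction,
                "missing_fraction": b.missing_fraction,
                "p_value": b.p_value,
            }
            for b in solution
        ],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_biclusters(path) -> List[Bicluster]:
    """Load a solution from the JSON sidecar written by write_biclusters."""
    raw = json.loads(Path(path).read_text())
    out = []
    for d in raw["biclusters"]:
        out.append(Bicluster(
            rows=tuple(d["rows"]),
            cols=tuple(d["cols"]),
            pattern=tuple(d["pattern"]),
            assumption=d["assumption"],
            adjustments={
                r: _adjustment_from_json(v)
                for r, v in d.get("adjustments", {}).items()
            },
            noisy_fraction=d.get("noisy_fraction", 0.0),
            missing_fraction=d.get("missing_fraction", 0.0),
            p_value=d.get("p_value"),
            orientation=d.get("orientation", "rows"),
        ))
    return out
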
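"""In-memory containers for real-valued matrices and weighted networks.

A :class:`NumericDataset` is the matrix ``A`` over identified rows ``X`` and
columns ``Y``; cells are finite reals or missing.  Dense data is backed by a
NumPy array with NaN marking missing cells; network-derived data is backed by
a dict keyed on ``(row, col)`` so storage stays proportional to the number of
observed interactions (absent edges are missing, never zero).
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

from .errors import IdentifierError, ValidationError

__all__ = ["NumericDataset", "WeightedNetwork"]


def _check_ids(ids: Sequence[str], kind: str) -> List[str]:
    ids = [str(i) for i in ids]
    if len(ids) == 0:
        raise ValidationError(f"dataset needs at least one {kind}")
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise IdentifierError(f"duplicate {kind} identifier(s): {dup}")
    return ids


class NumericDataset:
    """Real-valued grid over identified rows and columns, with missings.

    Parameters
    ----------
    row_ids, col_ids
        Ordered, unique identifiers.
    values
        Either a dense 2-D float array (NaN = missing) or a dict mapping
        ``(row_index, col_index)`` to a finite float (absent = missing).
    """

    def __init__(self, row_ids, col_ids, values):
        self.row_ids: List[str] = _check_ids(row_ids, "row")
        self.col_ids: List[str] = _check_ids(col_ids, "column")
        self._dense: np.ndarray | None = None
        self._sparse: Dict[Tuple[int, int], float] | None = None
        if isinstance(values, dict):
            for (i, j), v in values.items():
                if not (0 <= i < len(self.row_ids) and 0 <= j < len(self.col_ids)):
                    raise ValidationError(f"cell index {(i, j)} out of bounds")
                if not math.isfinite(v):
                    raise ValidationError(f"non-finite value at {(i, j)}")
            self._sparse = dict(values)
        else:
            arr = np.asarray(values, dtype=float)
            if arr.shape != (len(self.row_ids), len(self.col_ids)):
                raise ValidationError(
                    f"values shape {arr.shape} does not match "
                    f"{len(self.row_ids)}x{len(self.col_ids)} identifiers"
                )
            self._dense = arr

    # -- basic geometry ----------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_sparse(self) -> bool:
        return self._sparse is not None

    @property
    def n_stored(self) -> int:
        """Number of explicitly stored cells (edge count for sparse data)."""
        if self._sparse is not None:
            return len(self._sparse)
        return int(self._dense.size)

    # -- cell access -------------------------------------------------------
    def get(self, i: int, j: int) -> float:
        """Value at (i, j); NaN when missing."""
        if self._sparse is not None:
            return self._sparse.get((i, j), math.nan)
        return float(self._dense[i, j])

    def is_missing(self, i: int, j: int) -> bool:
        return math.isnan(self.get(i, j))

    def iter_nonmissing(self) -> Iterator[Tuple[int, int, float]]:
        if self._sparse is not None:
            yield from ((i, j, v) for (i, j), v in self._sparse.items())
        else:
            ii, jj = np.nonzero(~np.isnan(self._dense))
            for i, j in zip(ii.tolist(), jj.tolist()):
                yield i, j, float(self._dense[i, j])

    def nonmissing_values(self) -> np.ndarray:
        if self._sparse is not None:
            return np.array(list(self._sparse.values()), dtype=float)
        return self._dense[~np.isnan(self._dense)]

    @property
    def n_nonmissing(self) -> int:
        return len(self.nonmissing_values())

    def to_dense(self) -> np.ndarray:
        """Dense NaN-filled copy of the grid."""
        if self._dense is not None:
            return self._dense.copy()
        out = np.full(self.shape, np.nan)
        for (i, j), v in self._sparse.items():
            out[i, j] = v
        return out

    # -- derived quantities ------------------------------------------------
    @property
    def amplitude(self) -> float:
        """Max minus min over non-missing cells (the amplitude of A)."""
        vals = self.nonmissing_values()
        if len(vals) == 0:
            return 0.0
        return float(vals.max() - vals.min())

    def has_negatives(self) -> bool:
        vals = self.nonmissing_values()
        return bool(len(vals)) and bool((vals < 0).any())

    # -- transforms ----------------------------------------------------------
    def transpose(self) -> "NumericDataset":
        if self._sparse is not None:
            flipped = {(j, i): v for (i, j), v in self._sparse.items()}
            return NumericDataset(self.col_ids, self.row_ids, flipped)
        return NumericDataset(self.col_ids, self.row_ids, self._dense.T)

    def with_masked(self, cells: Sequence[Tuple[int, int]]) -> "NumericDataset":
        """Copy with the given (row, col) index cells set to missing."""
        if self._sparse is not None:
            sp = dict(self._sparse)
            for c in cells:
                sp.pop(tuple(c), None)
            return NumericDataset(self.row_ids, self.col_ids, sp)
        dense = self._dense.copy()
        for i, j in cells:
            dense[i, j] = np.nan
        return NumericDataset(self.row_ids, self.col_ids, dense)

    def __repr__(self) -> str:  # pragma: no cover
        kind = "sparse" if self.is_sparse else "dense"
        return f"NumericDataset({self.n_rows}x{self.n_cols}, {kind})"


class WeightedNetwork:
    """Weighted edge list over identified nodes.

    Edges are canonicalized on construction: exact duplicate lines collapse
    to one edge; two entries for the same (source, target) with different
    weights are contradictory and rejected.
    """

    def __init__(self, edges: Sequence[Tuple[str, str, float]], bidirectional: bool = False):
        canon: Dict[Tuple[str, str], float] = {}
        for u, v, w in edges:
            u, v, w = str(u), str(v), float(w)
            if not math.isfinite(w):
                raise ValidationError(f"non-finite weight on edge ({u}, {v})")
            key = (u, v)
            if key in canon and canon[key] != w:
                raise ValidationError(
                    f"contradictory duplicate edge ({u}, {v}): {canon[key]} vs {w}"
                )
            canon[key] = w
        if bidirectional:
            for (u, v), w in list(canon.items()):
                rkey = (v, u)
                if rkey in canon and canon[rkey] != w:
                    raise ValidationError(
                        f"contradictory bidirectional edge ({u}, {v})"
                    )
                canon[rkey] = w
        self.bidirectional = bool(bidirectional)
        self.edges: List[Tuple[str, str, float]] = [
            (u, v, w) for (u, v), w in canon.items()
        ]
        nodes: List[str] = []
        seen = set()
        for u, v, _ in self.edges:
            for n in (u, v):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
        self.nodes: List[str] = nodes

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def source_nodes(self) -> List[str]:
        seen, out = set(), []
        for u, _, _ in self.edges:
            if u not in seen:
                seen.add(u)
                out.append(u)
        return out

    def target_nodes(self) -> List[str]:
        seen, out = set(), []
        for _, v, _ in self.edges:
            if v not in seen:
                seen.add(v)
                out.append(v)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedNetwork({len(self.nodes)} nodes, {self.n_edges} edges)"
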
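"""Preprocessing: normalization, discretization and item-space adjustments.

Real-valued data is mapped onto an ordered alphabet of |L| integer symbols.
|L| controls the coherency strength delta = amplitude/|L|: fewer symbols
tolerate larger deviations from a perfectly coherent model.  Symmetric
alphabets center on zero so that sign flips are meaningful (expression
activation vs repression, positive vs negative interaction weights).

The multi-item noise handler softens discretization: an element whose value
falls near a bin boundary (relative distance below ``boundary_fraction``)
additionally receives the adjacent bin's symbol, so downstream mining can
absorb borderline assignments instead of treating them as noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .datasets import NumericDataset
from .errors import ConfigError, ValidationError

__all__ = [
    "Alphabet",
    "SymbolicDataset",
    "normalize",
    "discretize",
    "assign_symbols",
    "apply_noise_handler",
    "handle_missings",
    "remove_uninformative",
]


@dataclass(frozen=True)
class Alphabet:
    """Ordered integer symbol set L.

    Non-symmetric: {0, ..., size-1}.  Symmetric with odd size:
    {-(size-1)/2, ..., 0, ..., +(size-1)/2}.  Symmetric with even size:
    {-size/2, ..., -1, 1, ..., +size/2} (no zero), so that multiplicative
    scales stay consistent.
    """

    size: int
    symmetric: bool = False

    def __post_init__(self):
        if self.size < 2:
            raise ConfigError(f"alphabet needs at least 2 symbols, got {self.size}")

    @property
    def symbols(self) -> Tuple[int, ...]:
        if not self.symmetric:
            return tuple(range(self.size))
        if self.size % 2 == 1:
            h = (self.size - 1) // 2
            return tuple(range(-h, h + 1))
        h = self.size // 2
        return tuple(list(range(-h, 0)) + list(range(1, h + 1)))

    @property
    def min_symbol(self) -> int:
        return self.symbols[0]

    @property
    def max_symbol(self) -> int:
        return self.symbols[-1]

    def rank(self, symbol: int) -> int:
        """Position of a symbol in the ordered alphabet."""
        return self.symbols.index(symbol)

    def __contains__(self, symbol: int) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return self.size


@dataclass
class SymbolicDataset:
    """Post-mapping grid: each cell holds a set of 1-2 adjacent symbols.

    ``cells`` maps ``(row_index, col_index)`` to an ascending tuple of
    symbols; missing cells are simply absent.  ``bin_edges`` keeps the full
    discretization grid (|L|+1 edges, outer edges possibly widened to the
    observed data range) so the noise handler can locate bin boundaries.
    """

    row_ids: List[str]
    col_ids: List[str]
    alphabet: Alphabet
    cells: Dict[Tuple[int, int], Tuple[int, ...]]
    bin_edges: Optional[np.ndarray] = None
    amplitude: float = 0.0

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def cutoffs(self) -> Optional[np.ndarray]:
        """The |L|-1 interior thresholds delimiting the discretization bins."""
        if self.bin_edges is None:
            return None
        return self.bin_edges[1:-1]

    @property
    def coherency_strength(self) -> float:
        """delta = amplitude / |L| (derived, not stored independently)."""
        return self.amplitude / self.alphabet.size

    def primary_symbol(self, i: int, j: int) -> Optional[int]:
        """The symbol assigned by discretization proper (lowest of the set)."""
        cell = self.cells.get((i, j))
        if not cell:
            return None
        return cell[0] if len(cell) == 1 else self._primaries[(i, j)]

    # primary symbols are tracked explicitly once multi-items may exist
    _primaries: Dict[Tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        symbols = set(self.alphabet.symbols)
        for key, cell in self.cells.items():
            if any(s not in symbols for s in cell):
                raise ValidationError(f"cell {key} holds out-of-alphabet symbols {cell}")
            if len(cell) == 2 and abs(
                self.alphabet.rank(cell[1]) - self.alphabet.rank(cell[0])
            ) != 1:
                raise ValidationError(f"cell {key} multi-symbols {cell} not adjacent")
            if len(cell) > 2:
                raise ValidationError(f"cell {key} has more than 2 symbols")
        if not self._primaries:
            self._primaries = {
                k: c[0] for k, c in self.cells.items() if len(c) == 1
            }

    def transpose(self) -> "SymbolicDataset":
        return SymbolicDataset(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            alphabet=self.alphabet,
            cells={(j, i): c for (i, j), c in self.cells.items()},
            bin_edges=self.bin_edges,
            amplitude=self.amplitude,
            _primaries={(j, i): s for (i, j), s in self._primaries.items()},
        )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(data: NumericDataset, mode: str = "row") -> NumericDataset:
    """Standardize to mean 0 / sd 1 per row, per column, or overall.

    Zero-variance units (including single-value units) map to all zeros;
    missing cells are preserved untouched.
    """
    if mode == "none":
        return data
    if mode not in ("row", "column", "overall"):
        raise ConfigError(f"unknown normalization mode {mode!r}")

    if not data.is_sparse:
        dense = data.to_dense()
        with np.errstate(invalid="ignore"):
            if mode == "overall":
                mu = np.nanmean(dense)
                sd = np.nanstd(dense)
                out = np.where(np.isnan(dense), np.nan,
                               (dense - mu) / sd if sd > 0 else 0.0)
            else:
                axis = 1 if mode == "row" else 0
                mu = np.nanmean(dense, axis=axis, keepdims=True)
                sd = np.nanstd(dense, axis=axis, keepdims=True)
                # all-missing units: nanmean is NaN; pass through as zeros
                mu = np.where(np.isnan(mu), 0.0, mu)
                safe = np.where(sd > 0, sd, 1.0)
                out = (dense - mu) / safe
                out = np.where(np.broadcast_to(sd > 0, dense.shape), out,
                               np.where(np.isnan(dense), np.nan, 0.0))
                out = np.where(np.isnan(dense), np.nan, out)
        return NumericDataset(data.row_ids, data.col_ids, out)

    # sparse path: group values per unit
    groups: Dict[int, List[float]] = {}
    for i, j, v in data.iter_nonmissing():
        key = 0 if mode == "overall" else (i if mode == "row" else j)
        groups.setdefault(key, []).append(v)
    mus = {k: float(np.mean(v)) for k, v in groups.items()}
    sds = {k: float(np.std(v)) for k, v in groups.items()}
    out_sp: Dict[Tuple[int, int], float] = {}
    for i, j, v in data.iter_nonmissing():
        key = 0 if mode == "overall" else (i if mode == "row" else j)
        sd = sds[key]
        out_sp[(i, j)] = (v - mus[key]) / sd if sd > 0 else 0.0
    return NumericDataset(data.row_ids, data.col_ids, out_sp)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _gaussian_edges(values: np.ndarray, n_items: int) -> np.ndarray:
    """Interior cutoffs at the k/|L| quantiles of a fitted normal; outer
    edges at the observed extremes (widened to enclose all values)."""
    mu = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0:
        cut = np.full(n_items - 1, mu)
        # degenerate: all values equal; single occupied bin
        cut = mu + np.arange(1, n_items) * 0.0
        return np.concatenate([[mu - 0.5], cut, [mu + 0.5]])
    qs = np.arange(1, n_items) / n_items
    cut = stats.norm.ppf(qs, loc=mu, scale=sd)
    lo = min(float(values.min()), cut[0] - 1e-9)
    hi = max(float(values.max()), cut[-1] + 1e-9)
    return np.concatenate([[lo], cut, [hi]])


def _fixed_edges(values: np.ndarray, n_items: int) -> np.ndarray:
    """Equal-width bins over mean +/- 3 sd (outliers clamped to end bins)."""
    mu = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0:
        return np.concatenate([[mu - 0.5], mu + np.zeros(n_items - 1), [mu + 0.5]])
    lo, hi = mu - 3 * sd, mu + 3 * sd
    return np.linspace(lo, hi, n_items + 1)


def assign_symbols(
    data: NumericDataset, bin_edges: np.ndarray, alphabet: Alphabet
) -> SymbolicDataset:
    """Map each non-missing value to the alphabet symbol of its bin.

    ``bin_edges`` must hold |L|+1 ascending edges; values outside the grid
    clamp to the extreme bins.  Bins map in order onto the alphabet.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) != alphabet.size + 1:
        raise ConfigError(
            f"need {alphabet.size + 1} bin edges for |L|={alphabet.size}, "
            f"got {len(bin_edges)}"
        )
    symbols = alphabet.symbols
    interior = bin_edges[1:-1]
    cells: Dict[Tuple[int, int], Tuple[int, ...]] = {}
    for i, j, v in data.iter_nonmissing():
        k = int(np.searchsorted(interior, v, side="right"))
        cells[(i, j)] = (symbols[k],)
    return SymbolicDataset(
        row_ids=list(data.row_ids),
        col_ids=list(data.col_ids),
        alphabet=alphabet,
        cells=cells,
        bin_edges=bin_edges,
        amplitude=data.amplitude,
    )


def discretize(
    data: NumericDataset,
    n_items: int = 5,
    method: str = "gaussian",
    symmetric: bool = False,
) -> SymbolicDataset:
    """Discretize a real-valued dataset into an |L|-symbol grid.

    gaussian (default): cutoffs at the k/|L| quantiles of a normal fitted to
    all non-missing values, giving approximately balanced symbol frequencies
    on normal data.  fixed_range: equal-width bins over mean +/- 3 sd with
    clamping.  none: values must already be integer symbols of the target
    alphabet.
    """
    if n_items < 2:
        raise ConfigError(f"n_items must be >= 2, got {n_items}")
    alphabet = Alphabet(n_items, symmetric=symmetric)
    if method == "none":
        symbols = set(alphabet.symbols)
        cells: Dict[Tuple[int, int], Tuple[int, ...]] = {}
        for i, j, v in data.iter_nonmissing():
            s = int(round(v))
            if s != v or s not in symbols:
                raise ValidationError(
                    f"value {v} at ({i},{j}) is not a symbol of {alphabet.symbols}"
                )
            cells[(i, j)] = (s,)
        return SymbolicDataset(
            row_ids=list(data.row_ids),
            col_ids=list(data.col_ids),
            alphabet=alphabet,
            cells=cells,
            bin_edges=None,
            amplitude=data.amplitude,
        )
    vals = data.nonmissing_values()
    if len(vals) == 0:
        raise ValidationError("cannot discretize a fully-missing dataset")
    if method == "gaussian":
        edges = _gaussian_edges(vals, n_items)
    elif method == "fixed_range":
        edges = _fixed_edges(vals, n_items)
    else:
        raise ConfigError(f"unknown discretization method {method!r}")
    return assign_symbols(data, edges, alphabet)


# ---------------------------------------------------------------------------
# multi-item noise handling
# ---------------------------------------------------------------------------

def apply_noise_handler(
    data: NumericDataset,
    symbolic: SymbolicDataset,
    boundary_fraction: float = 0.25,
) -> SymbolicDataset:
    """Assign a second, adjacent symbol to near-boundary elements.

    An element with value c in bin [a, b] also receives the neighboring
    bin's symbol on the near side iff min(b-c, c-a)/(b-a) < boundary_fraction
    and that neighbor exists in the alphabet.  Primary symbols are never
    changed.
    """
    if not (0 < boundary_fraction < 0.5):
        raise ConfigError(
            f"boundary_fraction must lie in (0, 0.5), got {boundary_fraction}"
        )
    if symbolic.bin_edges is None:
        raise ConfigError("noise handler requires recorded discretization bins")
    edges = symbolic.bin_edges
    symbols = symbolic.alphabet.symbols
    interior = edges[1:-1]
    cells = dict(symbolic.cells)
    primaries = dict(symbolic._primaries)
    for i, j, v in data.iter_nonmissing():
        k = int(np.searchsorted(interior, v, side="right"))
        a, b = float(edges[k]), float(edges[k + 1])
        if b <= a:
            continue
        c = min(max(v, a), b)  # clamped values sit on the edge of end bins
        rel = min(b - c, c - a) / (b - a)
        if rel >= boundary_fraction:
            continue
        near_upper = (b - c) <= (c - a)
        nk = k + 1 if near_upper else k - 1
        if not (0 <= nk < len(symbols)):
            continue  # outermost boundary: no adjacent symbol to add
        own, neighbor = symbols[k], symbols[nk]
        cells[(i, j)] = tuple(sorted((own, neighbor), key=symbolic.alphabet.rank))
        primaries[(i, j)] = own
    return SymbolicDataset(
        row_ids=symbolic.row_ids,
        col_ids=symbolic.col_ids,
        alphabet=symbolic.alphabet,
        cells=cells,
        bin_edges=symbolic.bin_edges,
        amplitude=symbolic.amplitude,
        _primaries=primaries,
    )


# ---------------------------------------------------------------------------
# missing values
# ---------------------------------------------------------------------------

def handle_missings(data: NumericDataset, mode: str = "remove") -> NumericDataset:
    """remove (default): keep missings as-is, they contribute no items.

    replace: impute by the row mean of non-missing values, falling back to
    the column mean and finally the overall mean.
    """
    if mode == "remove":
        return data
    if mode != "replace":
        raise ConfigError(f"unknown missings mode {mode!r}")
    if data.n_nonmissing == 0:
        raise ValidationError("cannot impute a fully-missing dataset")
    if data.is_sparse:
        # imputation densifies sparse data by construction
        data = NumericDataset(data.row_ids, data.col_ids, data.to_dense())
    dense = data.to_dense()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN units
        row_mu = np.nanmean(dense, axis=1)
        col_mu = np.nanmean(dense, axis=0)
    overall = float(np.nanmean(dense))
    for i in range(dense.shape[0]):
        fill = row_mu[i]
        if math.isnan(fill):
            fill = None
        for j in range(dense.shape[1]):
            if math.isnan(dense[i, j]):
                v = fill
                if v is None:
                    v = col_mu[j]
                if v is None or math.isnan(v):
                    v = overall
                dense[i, j] = v
    return NumericDataset(data.row_ids, data.col_ids, dense)


# ---------------------------------------------------------------------------
# uninformative elements
# ---------------------------------------------------------------------------

def remove_uninformative(symbolic: SymbolicDataset, mode: str = "none") -> SymbolicDataset:
    """Drop symbols that carry no analytical signal.

    zero_entries deletes the 0 symbol everywhere (weak interactions,
    unchanged expression); differential keeps only the floor(|L|/3) most
    extreme symbols at each end of the alphabet (e.g. {-3,-2,2,3} at |L|=6).
    """
    if mode == "none":
        return symbolic
    alphabet = symbolic.alphabet
    if mode == "zero_entries":
        if 0 not in alphabet.symbols:
            raise ConfigError(
                "zero_entries removal needs 0 in the alphabet "
                "(symmetric even alphabets have none)"
            )
        keep = set(alphabet.symbols) - {0}
    elif mode == "differential":
        k = alphabet.size // 3
        if k < 1:
            raise ConfigError(f"differential removal needs |L| >= 3, got {alphabet.size}")
        keep = set(alphabet.symbols[:k]) | set(alphabet.symbols[-k:])
    else:
        raise ConfigError(f"unknown uninformative mode {mode!r}")
    cells: Dict[Tuple[int, int], Tuple[int, ...]] = {}
    primaries: Dict[Tuple[int, int], int] = {}
    for key, cell in symbolic.cells.items():
        kept = tuple(s for s in cell if s in keep)
        cells[key] = kept  # may be empty: item-free cell
        p = symbolic._primaries.get(key, cell[0] if cell else None)
        if p in keep:
            primaries[key] = p
        elif kept:
            primaries[key] = kept[0]
    return SymbolicDataset(
        row_ids=symbolic.row_ids,
        col_ids=symbolic.col_ids,
        alphabet=alphabet,
        cells=cells,
        bin_edges=symbolic.bin_edges,
        amplitude=symbolic.amplitude,
        _primaries=primaries,
    )
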
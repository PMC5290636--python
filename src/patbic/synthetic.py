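"""Planted-bicluster data generation and recovery scoring.

The generator emulates the row-coherency model a_ij = k_j + gamma_i + eta_ij:
a background grid (uniform over the alphabet symbols, or standard normal)
is overwritten by planted blocks following a chosen coherency assumption,
with uniform noise eta in [-delta/2, delta/2] scaled by ``noise_rate``
(delta = one symbol width) and a ``missing_rate`` fraction of block cells
masked.  For additive and multiplicative plants, the off-block cells of
planted rows are constrained so that the row's planted shift or scale
remains admissible for whole-row variant enumeration.

Recovery scoring is standard best-match element-Jaccard: ``recovery``
averages, over planted modules, the best Jaccard against the found
solution; ``relevance`` averages the converse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Sequence, Tuple

import numpy as np

from .datasets import NumericDataset, WeightedNetwork
from .errors import ValidationError
from .mapping import Alphabet
from .models import Bicluster

__all__ = ["PlantedBlock", "PlantSpec", "generate", "match_score"]


@dataclass
class PlantedBlock:
    """One planted bicluster: size, coherency model and corruption rates."""

    n_rows: int
    n_cols: int
    assumption: str = "constant"
    noise_rate: float = 0.0
    missing_rate: float = 0.0
    gamma_range: Tuple[int, int] = (0, 4)     # additive shifts (inclusive)
    scale_set: Tuple[int, ...] = (1, 2)       # multiplicative scales

    def __post_init__(self):
        if not (0 <= self.noise_rate <= 1 and 0 <= self.missing_rate <= 1):
            raise ValidationError("noise_rate / missing_rate must lie in [0, 1]")


@dataclass
class PlantSpec:
    """Generator configuration: grid, background and planted modules."""

    n_rows: int = 100
    n_cols: int = 30
    background: str = "uniform"   # uniform over symbols | gaussian N(0,1)
    n_items: int = 5
    symmetric: bool = False
    planted: List[PlantedBlock] = field(default_factory=list)
    overlap: str = "disjoint"     # disjoint | free
    seed: int = 0
    as_network: bool = False      # emit a WeightedNetwork instead
    density: float = 0.01         # background edge density for networks


def _choose(rng, pool: List[int], k: int, overlap: str) -> List[int]:
    if overlap == "disjoint":
        if len(pool) < k:
            raise ValidationError("planted blocks do not fit disjointly")
        picked = [pool.pop(rng.integers(len(pool))) for _ in range(k)]
        return sorted(picked)
    return sorted(rng.choice(len(pool), size=k, replace=False).tolist())


def _block_values(
    block: PlantedBlock, alphabet: Alphabet, rng
) -> Tuple[np.ndarray, Tuple[int, ...], dict]:
    """Noise-free block cell values, pattern and per-row adjustments."""
    symbols = alphabet.symbols
    nr, nc = block.n_rows, block.n_cols
    if block.assumption == "constant":
        pattern = tuple(int(rng.choice(symbols)) for _ in range(nc))
        vals = np.tile(np.array(pattern, dtype=float), (nr, 1))
        return vals, pattern, {}
    if block.assumption == "additive":
        lo = alphabet.min_symbol
        gmin, gmax = block.gamma_range
        gmax = min(gmax, alphabet.max_symbol - lo)
        # canonical pattern: minimum at the alphabet minimum
        span = alphabet.max_symbol - lo - gmax
        pattern = [lo] + [
            lo + int(rng.integers(0, span + 1)) for _ in range(nc - 1)
        ]
        rng.shuffle(pattern)
        pattern[int(rng.integers(nc))] = lo  # keep the canonical anchor
        pattern = tuple(pattern)
        gammas = [int(rng.integers(gmin, gmax + 1)) for _ in range(nr)]
        vals = np.array(
            [[k + g for k in pattern] for g in gammas], dtype=float
        )
        return vals, pattern, {"gamma": gammas}
    if block.assumption == "multiplicative":
        scales = [int(rng.choice(block.scale_set)) for _ in range(nr)]
        # primitive pattern whose scaled copies stay inside the alphabet
        base = [
            s for s in symbols
            if s != 0 and all(s * sc in symbols for sc in block.scale_set)
        ]
        if not base:
            raise ValidationError(
                "no pattern symbols admit the requested scale set within "
                f"the alphabet {symbols}"
            )
        pattern = [int(rng.choice(base)) for _ in range(nc)]
        # keep the pattern primitive (gcd 1) so planted scales are the
        # canonical ones the search reports
        g = 0
        for k in pattern:
            g = math.gcd(g, abs(k))
        units = [s for s in base if abs(s) == 1]
        if g > 1 and units:
            pattern[int(rng.integers(nc))] = units[0]
        pattern = tuple(pattern)
        vals = np.array(
            [[k * sc for k in pattern] for sc in scales], dtype=float
        )
        return vals, pattern, {"scale": scales}
    if block.assumption == "symmetric":
        if not alphabet.symmetric:
            raise ValidationError("symmetric plants need a symmetric alphabet")
        pattern = [int(rng.choice(symbols)) for _ in range(nc)]
        signs = [int(rng.choice((1, -1))) for _ in range(nr)]
        # canonical representative: first nonzero pattern symbol positive
        first = next((k for k in pattern if k != 0), 0)
        if first < 0:
            pattern = [-k for k in pattern]
            signs = [-c for c in signs]
        pattern = tuple(pattern)
        vals = np.array(
            [[k * c for k in pattern] for c in signs], dtype=float
        )
        return vals, pattern, {"sign": signs}
    if block.assumption == "order_preserving":
        # shared column ordering; symbols spread over the alphabet so ties
        # are consistent across rows
        order = rng.permutation(nc)
        L = alphabet.size
        level = {
            int(c): symbols[min(L - 1, int(p * L / nc))]
            for p, c in enumerate(order)
        }
        vals = np.array(
            [[level[c] for c in range(nc)] for _ in range(nr)], dtype=float
        )
        return vals, tuple(int(c) for c in order), {"order": tuple(int(c) for c in order)}
    raise ValidationError(f"unknown assumption {block.assumption!r}")


def generate(spec: PlantSpec):
    """Sample a dataset (or network) with planted biclusters.

    Returns ``(data, truth)`` where truth is the list of planted modules as
    :class:`Bicluster` objects.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = Alphabet(spec.n_items, symmetric=spec.symmetric)
    symbols = np.array(alphabet.symbols, dtype=float)

    if spec.as_network:
        return _generate_network(spec, rng, alphabet)

    if spec.background == "uniform":
        grid = rng.choice(symbols, size=(spec.n_rows, spec.n_cols))
    elif spec.background == "gaussian":
        grid = rng.normal(size=(spec.n_rows, spec.n_cols))
    else:
        raise ValidationError(f"unknown background {spec.background!r}")

    row_pool = list(range(spec.n_rows))
    col_pool = list(range(spec.n_cols))
    truth: List[Bicluster] = []
    row_ids = [f"r{i}" for i in range(spec.n_rows)]
    col_ids = [f"c{j}" for j in range(spec.n_cols)]

    for block in spec.planted:
        rows = _choose(rng, row_pool, block.n_rows, spec.overlap)
        cols = _choose(rng, col_pool, block.n_cols, spec.overlap)
        vals, pattern, adj = _block_values(block, alphabet, rng)

        # keep whole-row shift/scale variants admissible: constrain the
        # off-block cells of planted rows
        if spec.background == "uniform" and block.assumption == "additive":
            for r, g in zip(rows, adj["gamma"]):
                allowed = symbols[symbols >= alphabet.min_symbol + g]
                for j in range(spec.n_cols):
                    if j not in cols:
                        grid[r, j] = rng.choice(allowed)
        if spec.background == "uniform" and block.assumption == "multiplicative":
            for r, sc in zip(rows, adj["scale"]):
                allowed = np.array(
                    [s for s in alphabet.symbols
                     if Fraction(int(s), sc).denominator == 1
                     and int(Fraction(int(s), sc)) in alphabet.symbols],
                    dtype=float,
                )
                for j in range(spec.n_cols):
                    if j not in cols:
                        grid[r, j] = rng.choice(allowed)

        noise = block.noise_rate * rng.uniform(-0.5, 0.5, size=vals.shape)
        for a, r in enumerate(rows):
            for b, c in enumerate(cols):
                grid[r, c] = vals[a, b] + noise[a, b]
        if block.missing_rate > 0:
            n_mask = int(round(block.missing_rate * vals.size))
            flat = rng.choice(vals.size, size=n_mask, replace=False)
            for f in flat:
                a, b = divmod(int(f), len(cols))
                grid[rows[a], cols[b]] = np.nan

        if block.assumption == "order_preserving":
            ordered_cols = tuple(col_ids[cols[c]] for c in adj["order"])
            truth.append(Bicluster(
                rows=tuple(row_ids[r] for r in rows),
                cols=ordered_cols,
                pattern=tuple(range(len(cols))),
                assumption=block.assumption,
            ))
        else:
            adjustments = {}
            if "gamma" in adj:
                adjustments = {row_ids[r]: g for r, g in zip(rows, adj["gamma"])}
            elif "scale" in adj:
                adjustments = {row_ids[r]: s for r, s in zip(rows, adj["scale"])}
            elif "sign" in adj:
                adjustments = {row_ids[r]: s for r, s in zip(rows, adj["sign"])}
            truth.append(Bicluster(
                rows=tuple(row_ids[r] for r in rows),
                cols=tuple(col_ids[c] for c in cols),
                pattern=pattern,
                assumption=block.assumption,
                adjustments=adjustments,
            ))
    return NumericDataset(row_ids, col_ids, grid), truth


def _generate_network(spec: PlantSpec, rng, alphabet: Alphabet):
    """Background edges at ``spec.density`` plus planted coherent modules
    (missing_rate removes module interactions)."""
    n = spec.n_rows
    ids = [f"n{i}" for i in range(n)]
    symbols = [s for s in alphabet.symbols]
    pos_symbols = [s for s in symbols if s > 0] or symbols
    edges = {}
    n_bg = int(round(spec.density * n * n))
    ii = rng.integers(0, n, size=n_bg)
    jj = rng.integers(0, n, size=n_bg)
    ww = rng.choice(np.array(symbols, dtype=float), size=n_bg)
    for i, j, w in zip(ii, jj, ww):
        edges[(int(i), int(j))] = float(w)

    truth: List[Bicluster] = []
    used: set = set()
    for block in spec.planted:
        pool = [i for i in range(n) if i not in used]
        rows = sorted(rng.choice(len(pool), size=block.n_rows, replace=False).tolist())
        rows = [pool[i] for i in rows]
        used.update(rows)
        pool = [i for i in range(n) if i not in used]
        cols = sorted(rng.choice(len(pool), size=block.n_cols, replace=False).tolist())
        cols = [pool[i] for i in cols]
        used.update(cols)
        pattern = tuple(int(rng.choice(pos_symbols)) for _ in range(block.n_cols))
        size = block.n_rows * block.n_cols
        n_drop = int(round(block.missing_rate * size))
        dropped = set(rng.choice(size, size=n_drop, replace=False).tolist())
        keep = np.array(
            [[(a * block.n_cols + b) not in dropped
              for b in range(block.n_cols)] for a in range(block.n_rows)]
        )
        noise = block.noise_rate * rng.uniform(-0.5, 0.5,
                                               (block.n_rows, block.n_cols))
        for a, r in enumerate(rows):
            for b, c in enumerate(cols):
                if keep[a, b]:
                    edges[(r, c)] = pattern[b] + float(noise[a, b])
                else:
                    edges.pop((r, c), None)
        truth.append(Bicluster(
            rows=tuple(ids[r] for r in rows),
            cols=tuple(ids[c] for c in cols),
            pattern=pattern,
            assumption="constant",
        ))
    net = WeightedNetwork(
        [(ids[i], ids[j], w) for (i, j), w in edges.items()],
        bidirectional=False,
    )
    return net, truth


def _jaccard(a: Bicluster, b: Bicluster) -> float:
    ea, eb = a.elements(), b.elements()
    union = len(ea | eb)
    return len(ea & eb) / union if union else 0.0


def match_score(
    found: Sequence[Bicluster], planted: Sequence[Bicluster]
) -> Tuple[float, float]:
    """(recovery, relevance): mean best element-Jaccard, planted-vs-found
    and found-vs-planted."""
    def mean_best(src, dst):
        if not src:
            return 0.0
        scores = []
        for s in src:
            scores.append(max((_jaccard(s, d) for d in dst), default=0.0))
        return float(np.mean(scores))

    return mean_best(planted, found), mean_best(found, planted)
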
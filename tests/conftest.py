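"""Shared fixtures and independent brute-force oracles.

The oracles enumerate pattern lattices directly with scan-based support
counting; they share no code with the package's miners.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Sequence, Tuple

import numpy as np
import pytest

from patbic import NumericDataset


# ---------------------------------------------------------------------------
# brute-force itemset oracle
# ---------------------------------------------------------------------------

def brute_itemsets(
    transactions: Sequence[FrozenSet[int]],
    min_support: int,
    representation: str = "simple",
) -> Dict[FrozenSet[int], FrozenSet[int]]:
    """All frequent itemsets of the requested representation, by direct
    lattice enumeration with anti-monotone pruning."""

    def tids(p: FrozenSet[int]) -> FrozenSet[int]:
        return frozenset(t for t, tr in enumerate(transactions) if p <= tr)

    universe = sorted({i for t in transactions for i in t})
    frequent: Dict[FrozenSet[int], FrozenSet[int]] = {}

    def grow(p: FrozenSet[int], start: int):
        for k in range(start, len(universe)):
            q = p | {universe[k]}
            tq = tids(q)
            if len(tq) >= min_support:
                frequent[q] = tq
                grow(q, k + 1)

    grow(frozenset(), 0)
    if representation == "simple":
        return frequent
    closed = {
        p: t for p, t in frequent.items()
        if not any(
            len(frequent.get(p | {i}, ())) == len(t)
            for i in universe if i not in p and (p | {i}) in frequent
        )
    }
    if representation == "closed":
        return closed
    if representation == "maximal":
        return {
            p: t for p, t in closed.items()
            if not any((p | {i}) in frequent for i in universe if i not in p)
        }
    raise ValueError(representation)


# ---------------------------------------------------------------------------
# brute-force sequence oracle
# ---------------------------------------------------------------------------

def oracle_seq_contains(
    pattern: Tuple[int, ...], groups: Sequence[Sequence[int]]
) -> bool:
    """Independent containment check: recursive search over all embeddings
    with non-decreasing group positions."""
    def match(k: int, g: int) -> bool:
        if k == len(pattern):
            return True
        for gg in range(g, len(groups)):
            if pattern[k] in groups[gg] and match(k + 1, gg):
                return True
        return False

    return match(0, 0)


def brute_sequences(
    sequences: Sequence[Sequence[Sequence[int]]],
    min_support: int,
    representation: str = "simple",
) -> Dict[Tuple[int, ...], FrozenSet[int]]:
    """All frequent (closed) flat subsequences by breadth-first extension
    with oracle containment."""
    universe = sorted({i for s in sequences for grp in s for i in grp})

    def support(p: Tuple[int, ...]) -> FrozenSet[int]:
        return frozenset(
            k for k, s in enumerate(sequences) if oracle_seq_contains(p, s)
        )

    frequent: Dict[Tuple[int, ...], FrozenSet[int]] = {}
    frontier = [()]
    while frontier:
        nxt = []
        for p in frontier:
            for i in universe:
                if i in p:
                    continue
                q = p + (i,)
                tq = support(q)
                if len(tq) >= min_support:
                    frequent[q] = tq
                    nxt.append(q)
        frontier = nxt
    if representation == "simple":
        return frequent

    def flat_subseq(a, b):
        it = iter(b)
        return all(x in it for x in a)

    return {
        p: t for p, t in frequent.items()
        if not any(
            len(q) > len(p) and tq == t and flat_subseq(p, q)
            for q, tq in frequent.items()
        )
    }


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """4x4 dense matrix with one missing cell."""
    grid = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [2.0, 3.0, 4.0, 5.0],
        [np.nan, 1.0, 1.0, 1.0],
        [5.0, 5.0, 5.0, 5.0],
    ])
    return NumericDataset(["g1", "g2", "g3", "g4"],
                          ["s1", "s2", "s3", "s4"], grid)


def random_transactions(rng, n_txn=8, n_items=6, density=0.45):
    out = []
    for _ in range(n_txn):
        t = frozenset(i for i in range(n_items) if rng.random() < density)
        out.append(t)
    return out


def random_sequences(rng, n_seq=8, n_items=5, max_len=6):
    out = []
    for _ in range(n_seq):
        items = list(rng.permutation(n_items))[: int(rng.integers(2, max_len + 1))]
        # group random adjacent ties
        groups, k = [], 0
        while k < len(items):
            width = 2 if (k + 1 < len(items) and rng.random() < 0.3) else 1
            groups.append(tuple(sorted(items[k:k + width])))
            k += width
        out.append(tuple(groups))
    return out
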
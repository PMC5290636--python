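"""Transaction construction and frequent-pattern mining backends.

Rows of a symbolic dataset become transactions whose items encode
(column, symbol) pairs; frequent itemsets over those transactions are
exactly the candidate bicluster patterns, and the supporting transactions
are the candidate rows.  Order-preserving search uses sequences of column
indexes instead, sorted by cell value with ties grouped.

Several classic mining engines are provided (level-wise with tid-lists,
vertical tidset/diffset search, FP-growth, prefix-projected sequence
search) and must produce identical results for a given representation;
the test suite holds them to brute-force enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .errors import ConfigError, ValidationError
from .mapping import SymbolicDataset

__all__ = [
    "TransactionDB",
    "SequenceDB",
    "FullPattern",
    "itemize",
    "itemize_sequences",
    "mine_itemsets",
    "mine_sequences",
    "ITEMSET_ALGORITHMS",
    "SEQUENCE_ALGORITHMS",
]

# algorithm -> representations it can serve
ITEMSET_ALGORITHMS: Dict[str, Tuple[str, ...]] = {
    "apriori_tid": ("simple", "closed"),
    "eclat": ("simple",),
    "fpgrowth": ("simple",),
    "charm_tid": ("closed",),
    "charm_diffsets": ("closed",),
    "charm_mfi": ("maximal",),
}
SEQUENCE_ALGORITHMS: Dict[str, Tuple[str, ...]] = {
    "prefixspan": ("simple",),
    "indexspan": ("simple",),
    "bide": ("closed",),
}


@dataclass
class TransactionDB:
    """Itemset transactions with provenance back to dataset rows.

    Item encoding: ``item = column_index * |L| + symbol_rank`` so columns
    and symbols decode without side tables.  One transaction may exist per
    (row, variant) pair when an assumption enumerates shifted / scaled /
    sign-flipped row variants; ``provenance[t]`` is ``(row_index, tag)``
    where the tag records the variant's adjustment (or None).
    """

    transactions: List[FrozenSet[int]]
    provenance: List[Tuple[int, object]]
    n_cols: int
    alphabet_size: int
    symbols: Tuple[int, ...]
    row_ids: List[str]
    col_ids: List[str]

    def encode(self, col: int, symbol: int) -> int:
        return col * self.alphabet_size + self.symbols.index(symbol)

    def decode(self, item: int) -> Tuple[int, int]:
        col, rank = divmod(item, self.alphabet_size)
        return col, self.symbols[rank]

    def __len__(self) -> int:
        return len(self.transactions)


@dataclass
class SequenceDB:
    """Sequences of tie groups (sets of column indexes) with provenance."""

    sequences: List[Tuple[Tuple[int, ...], ...]]
    provenance: List[Tuple[int, object]]
    n_cols: int
    row_ids: List[str]
    col_ids: List[str]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class FullPattern:
    """A mined pattern with its support set.

    ``pattern`` is a frozenset of items (itemset mining) or a tuple of items
    (sequence mining).  ``tids`` indexes the supporting transactions;
    ``rows`` is the deduplicated set of originating dataset rows.
    """

    pattern: object
    tids: FrozenSet[int]
    rows: FrozenSet[int]
    closed: bool = False
    maximal: bool = False

    @property
    def support(self) -> int:
        return len(self.tids)


# ---------------------------------------------------------------------------
# transaction construction
# ---------------------------------------------------------------------------

def itemize(symbolic: SymbolicDataset, orientation: str = "rows") -> TransactionDB:
    """One transaction per row; each symbol of each non-missing cell
    contributes one item.  ``orientation='columns'`` transposes first."""
    if orientation == "columns":
        symbolic = symbolic.transpose()
    elif orientation != "rows":
        raise ConfigError(f"unknown orientation {orientation!r}")
    if symbolic.n_rows == 0 or symbolic.n_cols == 0:
        raise ValidationError("cannot itemize an empty dataset")
    L = symbolic.alphabet.size
    symbols = symbolic.alphabet.symbols
    rank = {s: r for r, s in enumerate(symbols)}
    per_row: List[Set[int]] = [set() for _ in range(symbolic.n_rows)]
    for (i, j), cell in symbolic.cells.items():
        for s in cell:
            per_row[i].add(j * L + rank[s])
    return TransactionDB(
        transactions=[frozenset(t) for t in per_row],
        provenance=[(i, None) for i in range(symbolic.n_rows)],
        n_cols=symbolic.n_cols,
        alphabet_size=L,
        symbols=symbols,
        row_ids=list(symbolic.row_ids),
        col_ids=list(symbolic.col_ids),
    )


def itemize_sequences(symbolic: SymbolicDataset) -> SequenceDB:
    """Each row becomes its column indexes sorted by primary symbol
    ascending; equal-symbol columns form one tie group."""
    if symbolic.n_rows == 0 or symbolic.n_cols == 0:
        raise ValidationError("cannot itemize an empty dataset")
    rows: List[Tuple[Tuple[int, ...], ...]] = []
    for i in range(symbolic.n_rows):
        by_symbol: Dict[int, List[int]] = {}
        for j in range(symbolic.n_cols):
            cell = symbolic.cells.get((i, j))
            if not cell:
                continue
            p = symbolic._primaries.get((i, j), cell[0])
            by_symbol.setdefault(p, []).append(j)
        groups = tuple(
            tuple(sorted(by_symbol[s])) for s in sorted(by_symbol)
        )
        rows.append(groups)
    return SequenceDB(
        sequences=rows,
        provenance=[(i, None) for i in range(symbolic.n_rows)],
        n_cols=symbolic.n_cols,
        row_ids=list(symbolic.row_ids),
        col_ids=list(symbolic.col_ids),
    )


# ---------------------------------------------------------------------------
# itemset engines (all return {itemset: tidset})
# ---------------------------------------------------------------------------

def _vertical(transactions: Sequence[FrozenSet[int]]) -> Dict[int, Set[int]]:
    tid: Dict[int, Set[int]] = {}
    for t, items in enumerate(transactions):
        for it in items:
            tid.setdefault(it, set()).add(t)
    return tid


def _apriori_tid(transactions, min_support) -> Dict[FrozenSet[int], FrozenSet[int]]:
    """Level-wise candidate generation with tid-list intersection."""
    tid = _vertical(transactions)
    level = {
        frozenset([i]): frozenset(t) for i, t in tid.items() if len(t) >= min_support
    }
    out: Dict[FrozenSet[int], FrozenSet[int]] = dict(level)
    k = 1
    while level:
        items_sorted = sorted(level, key=sorted)
        nxt: Dict[FrozenSet[int], FrozenSet[int]] = {}
        for a in range(len(items_sorted)):
            for b in range(a + 1, len(items_sorted)):
                ia, ib = items_sorted[a], items_sorted[b]
                union = ia | ib
                if len(union) != k + 1 or union in nxt:
                    continue
                # classic prune: all k-subsets must be frequent
                if any(union - {x} not in level for x in union):
                    continue
                tids = level[ia] & level[ib]
                if len(tids) >= min_support:
                    nxt[union] = frozenset(tids)
        out.update(nxt)
        level = nxt
        k += 1
    return out


def _eclat(transactions, min_support) -> Dict[FrozenSet[int], FrozenSet[int]]:
    """Depth-first vertical search over tidsets."""
    tid = _vertical(transactions)
    items = sorted(i for i, t in tid.items() if len(t) >= min_support)
    out: Dict[FrozenSet[int], FrozenSet[int]] = {}

    def dfs(prefix: Tuple[int, ...], ptids: Set[int], candidates: List[int]):
        for idx, i in enumerate(candidates):
            tids = ptids & tid[i] if prefix else tid[i]
            if len(tids) < min_support:
                continue
            new = prefix + (i,)
            out[frozenset(new)] = frozenset(tids)
            dfs(new, tids, candidates[idx + 1:])

    dfs((), set(), items)
    return out


class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: Dict[int, "_FPNode"] = {}
        self.link: Optional["_FPNode"] = None


def _fpgrowth(transactions, min_support) -> Dict[FrozenSet[int], FrozenSet[int]]:
    """FP-growth over an annotated prefix tree; tidsets recovered by a
    final scan (the tree itself only tracks counts)."""
    counts: Dict[int, int] = {}
    for t in transactions:
        for i in t:
            counts[i] = counts.get(i, 0) + 1
    frequent = {i for i, c in counts.items() if c >= min_support}

    def build(weighted_transactions):
        root = _FPNode(None, None)
        headers: Dict[int, _FPNode] = {}
        for items, w in weighted_transactions:
            node = root
            for i in items:
                child = node.children.get(i)
                if child is None:
                    child = _FPNode(i, node)
                    node.children[i] = child
                    if i in headers:
                        last = headers[i]
                        while last.link is not None:
                            last = last.link
                        last.link = child
                    else:
                        headers[i] = child
                node = child
                node.count += w
        return root, headers

    def order_key(i):
        return (-counts[i], i)

    base = [
        (sorted((i for i in t if i in frequent), key=order_key), 1)
        for t in transactions
    ]
    supports: Dict[FrozenSet[int], int] = {}

    def mine(weighted, suffix: Tuple[int, ...]):
        root, headers = build(weighted)
        local: Dict[int, int] = {}
        for i, head in headers.items():
            c, node = 0, head
            while node is not None:
                c += node.count
                node = node.link
            local[i] = c
        for i in sorted(local, key=lambda x: (local[x], -x)):
            if local[i] < min_support:
                continue
            new_suffix = (i,) + suffix
            supports[frozenset(new_suffix)] = local[i]
            # conditional pattern base
            cond = []
            node = headers[i]
            while node is not None:
                path = []
                p = node.parent
                while p is not None and p.item is not None:
                    path.append(p.item)
                    p = p.parent
                if path:
                    cond.append((list(reversed(path)), node.count))
                node = node.link
            if cond:
                mine(cond, new_suffix)

    mine(base, ())
    # recover tidsets for the emitted patterns
    out: Dict[FrozenSet[int], FrozenSet[int]] = {}
    for pattern in supports:
        tids = frozenset(
            t for t, items in enumerate(transactions) if pattern <= items
        )
        out[pattern] = tids
    return out


def _declat(transactions, min_support) -> Dict[FrozenSet[int], int]:
    """Vertical search with diffsets: support(PX) = support(P) - |d(PX)|,
    d(PXY) = d(PY) - d(PX)."""
    tid = _vertical(transactions)
    all_tids = set(range(len(transactions)))
    items = sorted(i for i, t in tid.items() if len(t) >= min_support)
    out: Dict[FrozenSet[int], int] = {}

    def dfs(prefix, psupport, diffs: List[Tuple[int, Set[int], int]]):
        # diffs: (item, diffset vs prefix, support of prefix+item)
        for idx, (i, _, sup_i) in enumerate(diffs):
            new = prefix + (i,)
            out[frozenset(new)] = sup_i
            child: List[Tuple[int, Set[int], int]] = []
            for (j, dj, _) in diffs[idx + 1:]:
                d = dj - diffs[idx][1]
                sup = sup_i - len(d)
                if sup >= min_support:
                    child.append((j, d, sup))
            if child:
                dfs(new, sup_i, child)

    top = [
        (i, all_tids - tid[i], len(tid[i]))
        for i in items
    ]
    dfs((), len(transactions), top)
    return out


def _closed_filter(freq: Dict[FrozenSet[int], int]) -> Set[FrozenSet[int]]:
    """A frequent itemset is closed iff no single-item frequent extension
    preserves its support (closure argument)."""
    universe: Set[int] = set()
    for p in freq:
        universe |= p
    closed = set()
    for p, s in freq.items():
        if not any(
            (p | {i}) in freq and freq[p | {i}] == s
            for i in universe - p
        ):
            closed.add(p)
    return closed


def _lcm_closed(transactions, min_support) -> Dict[FrozenSet[int], FrozenSet[int]]:
    """Closed-set enumeration via prefix-preserving closure extension
    (tidset encoding)."""
    out: Dict[FrozenSet[int], FrozenSet[int]] = {}
    if len(transactions) < min_support:
        return out
    tid = _vertical(transactions)
    items = sorted(i for i, t in tid.items() if len(t) >= min_support)
    order = {i: k for k, i in enumerate(items)}

    def closure(tids: Set[int]) -> FrozenSet[int]:
        return frozenset(i for i in items if tids <= tid[i])

    root_tids = set(range(len(transactions)))
    root_clo = closure(root_tids)
    if root_clo:
        out[root_clo] = frozenset(root_tids)

    def dfs(clo: FrozenSet[int], tids: Set[int], core: int):
        for i in items:
            if i in clo or order[i] < core:
                continue
            new_tids = tids & tid[i]
            if len(new_tids) < min_support:
                continue
            new_clo = closure(new_tids)
            # prefix-preserving check: no item ordered before i may join
            if any(order[j] < order[i] and j not in clo for j in new_clo):
                continue
            out[new_clo] = frozenset(new_tids)
            dfs(new_clo, new_tids, order[i] + 1)

    dfs(root_clo, root_tids, 0)
    return out


def _tids_of(pattern: FrozenSet[int], transactions) -> FrozenSet[int]:
    return frozenset(t for t, items in enumerate(transactions) if pattern <= items)


def mine_itemsets(
    db: TransactionDB,
    min_support: int,
    representation: str = "closed",
    algorithm: str = "charm_diffsets",
) -> List[FullPattern]:
    """Mine frequent itemsets under the requested representation.

    simple = all frequent itemsets; closed = no superset with equal
    support; maximal = no frequent superset.  Results are identical across
    compatible algorithms; output is ordered by descending support then
    lexicographic pattern.
    """
    if min_support < 1:
        raise ConfigError(f"min_support must be >= 1, got {min_support}")
    if min_support > len(db):
        return []
    if algorithm not in ITEMSET_ALGORITHMS:
        raise ConfigError(f"unknown itemset algorithm {algorithm!r}")
    if representation not in ("simple", "closed", "maximal"):
        raise ConfigError(f"unknown representation {representation!r}")
    if representation not in ITEMSET_ALGORITHMS[algorithm]:
        raise ConfigError(
            f"algorithm {algorithm!r} does not serve representation "
            f"{representation!r} (serves {ITEMSET_ALGORITHMS[algorithm]})"
        )
    txns = db.transactions

    if algorithm == "apriori_tid":
        freq_tids = _apriori_tid(txns, min_support)
        if representation == "simple":
            result = freq_tids
        else:
            closed = _closed_filter({p: len(t) for p, t in freq_tids.items()})
            result = {p: freq_tids[p] for p in closed}
    elif algorithm == "eclat":
        result = _eclat(txns, min_support)
    elif algorithm == "fpgrowth":
        result = _fpgrowth(txns, min_support)
    elif algorithm == "charm_tid":
        result = _lcm_closed(txns, min_support)
    elif algorithm in ("charm_diffsets", "charm_mfi"):
        freq = _declat(txns, min_support)
        closed = _closed_filter(freq)
        if algorithm == "charm_mfi":
            universe: Set[int] = set()
            for p in freq:
                universe |= p
            closed = {
                p for p in closed
                if not any((p | {i}) in freq for i in universe - p)
            }
        result = {p: _tids_of(p, txns) for p in closed}

    is_closed = representation in ("closed", "maximal")
    patterns = []
    for p, tids in result.items():
        if not p:
            continue
        rows = frozenset(db.provenance[t][0] for t in tids)
        patterns.append(
            FullPattern(
                pattern=p,
                tids=tids,
                rows=rows,
                closed=is_closed,
                maximal=representation == "maximal",
            )
        )
    patterns.sort(key=lambda fp: (-fp.support, sorted(fp.pattern)))
    return patterns


# ---------------------------------------------------------------------------
# sequence engines
# ---------------------------------------------------------------------------

def seq_contains(pattern: Tuple[int, ...], groups: Tuple[Tuple[int, ...], ...]) -> bool:
    """Whether a flat pattern occurs in a tie-grouped sequence.

    Pattern items map to non-decreasing group positions (items tied in one
    group may appear in either order), greedily matched left to right.
    """
    g = 0
    for item in pattern:
        while g < len(groups) and item not in groups[g]:
            g += 1
        if g == len(groups):
            return False
        # stay on the same group: further items may share the tie group
    return True


def _prefixspan(db: SequenceDB, min_support: int, index_prune: bool) -> Dict[Tuple[int, ...], FrozenSet[int]]:
    sequences = db.sequences
    n = len(sequences)
    # global item frequencies for the item-indexable prune
    global_freq: Dict[int, int] = {}
    for s in sequences:
        seen = set()
        for grp in s:
            seen.update(grp)
        for i in seen:
            global_freq[i] = global_freq.get(i, 0) + 1

    out: Dict[Tuple[int, ...], FrozenSet[int]] = {}

    def project(pattern: Tuple[int, ...], occs: List[Tuple[int, int]]):
        # occs: (sequence index, group position where last item matched)
        candidates: Dict[int, List[Tuple[int, int]]] = {}
        for sid, g in occs:
            groups = sequences[sid]
            seen_here: Dict[int, int] = {}
            for gg in range(g, len(groups)):
                for item in groups[gg]:
                    if item in pattern:
                        continue
                    if item not in seen_here:
                        seen_here[item] = gg
            for item, gg in seen_here.items():
                candidates.setdefault(item, []).append((sid, gg))
        for item, occ in sorted(candidates.items()):
            if index_prune and global_freq.get(item, 0) < min_support:
                continue
            sids = {sid for sid, _ in occ}
            if len(sids) < min_support:
                continue
            new = pattern + (item,)
            out[new] = frozenset(sids)
            project(new, occ)

    project((), [(sid, 0) for sid in range(n)])
    return out


def _closed_seq_filter(freq: Dict[Tuple[int, ...], FrozenSet[int]]) -> Set[Tuple[int, ...]]:
    """Closed = no frequent proper supersequence with identical support set."""
    by_support: Dict[FrozenSet[int], List[Tuple[int, ...]]] = {}
    for p, tids in freq.items():
        by_support.setdefault(tids, []).append(p)

    def subseq(a: Tuple[int, ...], b: Tuple[int, ...]) -> bool:
        it = iter(b)
        return all(x in it for x in a)

    closed: Set[Tuple[int, ...]] = set()
    for tids, pats in by_support.items():
        for p in pats:
            if not any(len(q) > len(p) and subseq(p, q) for q in pats):
                closed.add(p)
    return closed


def mine_sequences(
    db: SequenceDB,
    min_support: int,
    representation: str = "closed",
    algorithm: str = "indexspan",
) -> List[FullPattern]:
    """Mine frequent (closed) subsequences of the tie-grouped sequences."""
    if min_support < 1:
        raise ConfigError(f"min_support must be >= 1, got {min_support}")
    if min_support > len(db):
        return []
    if algorithm not in SEQUENCE_ALGORITHMS:
        raise ConfigError(f"unknown sequence algorithm {algorithm!r}")
    if representation not in ("simple", "closed"):
        raise ConfigError(f"unknown sequence representation {representation!r}")
    if representation not in SEQUENCE_ALGORITHMS[algorithm]:
        raise ConfigError(
            f"algorithm {algorithm!r} does not serve representation "
            f"{representation!r} (serves {SEQUENCE_ALGORITHMS[algorithm]})"
        )
    freq = _prefixspan(db, min_support, index_prune=algorithm == "indexspan")
    if representation == "closed":
        keep = _closed_seq_filter(freq)
        freq = {p: t for p, t in freq.items() if p in keep}
    patterns = []
    for p, tids in freq.items():
        rows = frozenset(db.provenance[t][0] for t in tids)
        patterns.append(
            FullPattern(
                pattern=p,
                tids=tids,
                rows=rows,
                closed=representation == "closed",
            )
        )
    patterns.sort(key=lambda fp: (-fp.support, fp.pattern))
    return patterns
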
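"""Coherency-assumption mappings, bicluster derivation and the search loop.

Each coherency assumption is realized as a transaction mapping whose
frequent patterns correspond one-to-one to coherent submodules:

* constant        -- plain itemization; a pattern is the expected symbol k_j
                     per column.
* additive        -- every admissible whole-row shift gamma produces a
                     shifted transaction variant, so rows agreeing up to a
                     shift share a pattern.
* multiplicative  -- variants per admissible rational scale (the pattern is
                     the row divided by its scale).
* symmetric       -- each row also contributes its sign-flipped variant.
* order_preserving - rows become column sequences sorted by value; frequent
                     (closed) subsequences are shared orderings.

The iterative search relaxes the support threshold multiplicatively until a
stopping criterion is met, masks the most-covered cells between iterations
to expose secondary structure, and hands the accumulated biclusters to the
closing (merge / filter / significance) stage.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .datasets import NumericDataset, WeightedNetwork
from .errors import ConfigError
from .mapping import (
    SymbolicDataset,
    apply_noise_handler,
    discretize,
    handle_missings,
    normalize,
    remove_uninformative,
)
from .mining import (
    FullPattern,
    SequenceDB,
    TransactionDB,
    itemize,
    itemize_sequences,
    mine_itemsets,
    mine_sequences,
)
from .models import Bicluster, SearchConfig

logger = logging.getLogger("patbic")

__all__ = [
    "map_for_assumption",
    "derive_biclusters",
    "evaluate_quality",
    "run",
    "compute_coverage",
    "build_symbolic",
]


# ---------------------------------------------------------------------------
# assumption-specific transaction construction
# ---------------------------------------------------------------------------

def _row_cells(symbolic: SymbolicDataset, i: int) -> Dict[int, Tuple[int, ...]]:
    return {
        j: cell
        for (r, j), cell in symbolic.cells.items()
        if r == i and cell
    }


def _variant_db(symbolic, variants) -> TransactionDB:
    L = symbolic.alphabet.size
    symbols = symbolic.alphabet.symbols
    rank = {s: r for r, s in enumerate(symbols)}
    transactions, provenance = [], []
    for row, tag, cells in variants:
        items = set()
        for j, syms in cells.items():
            for s in syms:
                items.add(j * L + rank[s])
        transactions.append(frozenset(items))
        provenance.append((row, tag))
    return TransactionDB(
        transactions=transactions,
        provenance=provenance,
        n_cols=symbolic.n_cols,
        alphabet_size=L,
        symbols=symbols,
        row_ids=list(symbolic.row_ids),
        col_ids=list(symbolic.col_ids),
    )


def map_for_assumption(
    symbolic: SymbolicDataset, assumption: str, config: SearchConfig
):
    """Build the transaction (or sequence) database for an assumption."""
    alphabet = symbolic.alphabet
    if assumption == "constant":
        return itemize(symbolic)
    if assumption == "order_preserving":
        return itemize_sequences(symbolic)

    by_row = [
        _row_cells(symbolic, i) for i in range(symbolic.n_rows)
    ]
    symset = set(alphabet.symbols)
    variants = []

    if assumption == "additive":
        span = alphabet.size - 1
        for i, cells in enumerate(by_row):
            if not cells:
                continue
            for gamma in range(-span, span + 1):
                shifted = {}
                ok = True
                for j, syms in cells.items():
                    kept = tuple(s - gamma for s in syms if s - gamma in symset)
                    if not kept:
                        ok = False
                        break
                    shifted[j] = kept
                if ok:
                    variants.append((i, gamma, shifted))
        return _variant_db(symbolic, variants)

    if assumption == "multiplicative":
        for i, cells in enumerate(by_row):
            if not cells:
                continue
            nonzero = sorted(
                {s for syms in cells.values() for s in syms if s != 0}
            )
            candidates = {Fraction(1)}
            for v in nonzero[:1]:
                for k in alphabet.symbols:
                    if k != 0:
                        candidates.add(Fraction(v, k))
            for scale in sorted(candidates):
                if scale == 0:
                    continue
                scaled = {}
                ok = True
                for j, syms in cells.items():
                    kept = []
                    for s in syms:
                        q = Fraction(s) / scale
                        if q.denominator == 1 and int(q) in symset:
                            kept.append(int(q))
                    if not kept:
                        ok = False
                        break
                    scaled[j] = tuple(kept)
                if ok:
                    variants.append((i, scale, scaled))
        return _variant_db(symbolic, variants)

    if assumption == "symmetric":
        if not alphabet.symmetric:
            raise ConfigError(
                "the symmetric assumption requires a symmetric alphabet"
            )
        for i, cells in enumerate(by_row):
            if not cells:
                continue
            variants.append((i, 1, cells))
            flipped = {
                j: tuple(sorted(-s for s in syms)) for j, syms in cells.items()
            }
            variants.append((i, -1, flipped))
        return _variant_db(symbolic, variants)

    raise ConfigError(f"unknown assumption {assumption!r}")


# ---------------------------------------------------------------------------
# bicluster derivation
# ---------------------------------------------------------------------------

def _canonical_additive(pattern, tags, alphabet):
    """Shift the pattern so its minimum sits at the alphabet minimum; the
    per-row shifts absorb the difference (matches reporting gamma=(5,1)
    rather than (4,0) for rows (6,5,6,5)/(2,1,2,1))."""
    shift = min(pattern) - alphabet.min_symbol
    if shift == 0:
        return pattern, tags
    if any((k - shift) not in alphabet.symbols for k in pattern):
        return pattern, tags
    return (
        tuple(k - shift for k in pattern),
        {r: g + shift for r, g in tags.items()},
    )


def _canonical_multiplicative(pattern, tags, alphabet):
    """Divide the pattern by the gcd of its entries (primitive pattern);
    scales absorb the factor."""
    nonzero = [abs(int(k)) for k in pattern if k != 0]
    if not nonzero:
        return pattern, tags
    g = nonzero[0]
    for v in nonzero[1:]:
        g = math.gcd(g, v)
    if g <= 1:
        return pattern, tags
    reduced = tuple(int(k) // g for k in pattern)
    if any(k not in alphabet.symbols for k in reduced):
        return pattern, tags
    return reduced, {r: Fraction(s) * g for r, s in tags.items()}


def derive_biclusters(
    patterns: Sequence[FullPattern],
    db,
    assumption: str,
    config: SearchConfig,
    symbolic: Optional[SymbolicDataset] = None,
) -> List[Bicluster]:
    """Decode mined patterns into biclusters.

    Columns and expected symbols are decoded from the items; supporting
    rows are deduplicated over shift/scale/sign variants (a row supporting
    through two shifts keeps the smallest |gamma|).  Patterns spanning
    fewer than ``config.min_cols`` columns, or assigning two symbols to one
    column, are dropped; duplicate (rows, columns) pairs collapse onto
    their canonical pattern.
    """
    min_cols = int(config.min_cols) if config.min_cols != "auto" else 1
    out: Dict[Tuple[frozenset, frozenset], Bicluster] = {}

    if assumption == "order_preserving":
        for fp in patterns:
            cols = tuple(fp.pattern)
            if len(cols) < min_cols or len(set(cols)) != len(cols):
                continue
            rows = tuple(sorted(fp.rows))
            bic = Bicluster(
                rows=tuple(db.row_ids[r] for r in rows),
                cols=tuple(db.col_ids[c] for c in cols),
                pattern=tuple(range(len(cols))),
                assumption=assumption,
            )
            out.setdefault(bic.key(), bic)
        bics = list(out.values())
        if symbolic is not None:
            for b in bics:
                evaluate_quality(b, symbolic)
        return bics

    alphabet_symbols = db.symbols

    class _Alpha:  # minimal view for canonicalization helpers
        symbols = alphabet_symbols
        min_symbol = alphabet_symbols[0]

    for fp in patterns:
        decoded = sorted(db.decode(it) for it in fp.pattern)
        cols = [c for c, _ in decoded]
        if len(set(cols)) != len(cols):
            continue  # two symbols for one column (multi-item artifact)
        if len(cols) < min_cols:
            continue
        pattern = tuple(s for _, s in decoded)

        # deduplicate rows over variants
        tags: Dict[int, object] = {}
        for t in fp.tids:
            row, tag = db.provenance[t]
            if row in tags:
                prev = tags[row]
                if assumption == "additive" and abs(tag) < abs(prev):
                    tags[row] = tag
                elif assumption == "multiplicative" and abs(tag - 1) < abs(prev - 1):
                    tags[row] = tag
                elif assumption == "symmetric" and tag == 1:
                    tags[row] = tag
            else:
                tags[row] = tag

        if assumption == "additive":
            pattern, tags = _canonical_additive(pattern, tags, _Alpha)
        elif assumption == "multiplicative":
            pattern, tags = _canonical_multiplicative(pattern, tags, _Alpha)
        elif assumption == "symmetric":
            # phi with signs c equals -phi with signs -c; fix the
            # representative whose first nonzero symbol is positive
            first = next((k for k in pattern if k != 0), 0)
            if first < 0:
                pattern = tuple(-k for k in pattern)
                tags = {r: -c for r, c in tags.items()}

        rows_sorted = sorted(tags)
        row_ids = tuple(db.row_ids[r] for r in rows_sorted)
        if assumption == "constant":
            adjustments = {}
        else:
            adjustments = {db.row_ids[r]: tags[r] for r in rows_sorted}
        bic = Bicluster(
            rows=row_ids,
            cols=tuple(db.col_ids[c] for c in cols),
            pattern=pattern,
            assumption=assumption,
            adjustments=adjustments,
        )
        out.setdefault(bic.key(), bic)

    bics = list(out.values())
    if symbolic is not None:
        for b in bics:
            evaluate_quality(b, symbolic)
    return bics


# ---------------------------------------------------------------------------
# quality statistics
# ---------------------------------------------------------------------------

def _longest_nondecreasing(seq: List[int]) -> int:
    """Length of the longest non-decreasing subsequence (O(n log n))."""
    import bisect

    tails: List[int] = []
    for x in seq:
        k = bisect.bisect_right(tails, x)
        if k == len(tails):
            tails.append(x)
        else:
            tails[k] = x
    return len(tails)


def evaluate_quality(bic: Bicluster, symbolic: SymbolicDataset) -> Bicluster:
    """Recompute noisy_fraction / missing_fraction in place.

    A present cell is noisy when its symbol set misses the model's expected
    value.  For order-preserving biclusters, a row's noisy cells are the
    minimum number of cells whose removal makes the row's symbols
    non-decreasing along the pattern's column order.
    """
    ridx = {r: i for i, r in enumerate(symbolic.row_ids)}
    cidx = {c: j for j, c in enumerate(symbolic.col_ids)}
    total = bic.n_elements
    missing = 0
    noisy = 0
    if bic.assumption == "order_preserving":
        for r in bic.rows:
            i = ridx[r]
            present = []
            for c in bic.cols:
                cell = symbolic.cells.get((i, cidx[c]))
                if not cell:
                    missing += 1
                else:
                    present.append(symbolic._primaries.get((i, cidx[c]), cell[0]))
            noisy += len(present) - _longest_nondecreasing(present)
    else:
        for r in bic.rows:
            i = ridx[r]
            for pos, c in enumerate(bic.cols):
                cell = symbolic.cells.get((i, cidx[c]))
                if not cell:
                    missing += 1
                    continue
                expected = bic.expected_symbol(r, pos)
                if expected is None or expected not in cell:
                    noisy += 1
    bic.missing_fraction = missing / total
    bic.noisy_fraction = noisy / total
    return bic


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_symbolic(numeric: NumericDataset, config: SearchConfig) -> SymbolicDataset:
    """Mapping stage: normalize -> discretize -> noise handler ->
    uninformative removal (fixed order)."""
    symmetric = bool(config.symmetries) and config.symmetries != "dynamic"
    if config.symmetries == "dynamic":
        symmetric = numeric.has_negatives()
    data = normalize(numeric, config.normalization)
    symbolic = discretize(
        data, n_items=config.n_items, method=config.discretization,
        symmetric=symmetric,
    )
    if config.noise_handler:
        if config.discretization == "none":
            raise ConfigError(
                "the multi-item noise handler needs recorded discretization "
                "bins (discretization != 'none')"
            )
        symbolic = apply_noise_handler(data, symbolic, config.noise_boundary)
    symbolic = remove_uninformative(symbolic, config.uninformative)
    return symbolic


def _mine(db, config: SearchConfig, support: int) -> List[FullPattern]:
    if isinstance(db, SequenceDB):
        return mine_sequences(
            db, support,
            representation=config.representation,
            algorithm=config.miner,
        )
    return mine_itemsets(
        db, support,
        representation=config.representation,
        algorithm=config.miner,
    )


def _stopping_met(config, iteration_found, all_found, support, numeric) -> bool:
    # nbics counts the current iteration's discoveries (each iteration
    # searches the masked data afresh); coverage is a whole-solution
    # property and uses the accumulated set
    if config.stop == "nbics":
        return len(iteration_found) >= config.stop_value
    if config.stop == "coverage":
        return compute_coverage(all_found, numeric) >= config.stop_value
    # support criterion: relax until the requested fraction of rows
    target = max(2, math.ceil(config.stop_value * numeric.n_rows))
    return support <= target


def _mask_most_covered(
    numeric: NumericDataset,
    biclusters: Sequence[Bicluster],
    rng: np.random.Generator,
    fraction: float = 0.25,
) -> Tuple[NumericDataset, int]:
    """Mask ``fraction`` of the covered cells, most-covered first; ties are
    broken by a seeded uniform draw."""
    ridx = {r: i for i, r in enumerate(numeric.row_ids)}
    cidx = {c: j for j, c in enumerate(numeric.col_ids)}
    counts: Dict[Tuple[int, int], int] = {}
    for b in biclusters:
        for r in b.rows:
            for c in b.cols:
                key = (ridx[r], cidx[c])
                if not numeric.is_missing(*key):
                    counts[key] = counts.get(key, 0) + 1
    covered = list(counts)
    if not covered:
        return numeric, 0
    k = int(round(fraction * len(covered)))
    if k == 0:
        return numeric, 0
    jitter = rng.random(len(covered))
    order = sorted(
        range(len(covered)),
        key=lambda idx: (-counts[covered[idx]], jitter[idx]),
    )
    to_mask = [covered[idx] for idx in order[:k]]
    return numeric.with_masked(to_mask), len(to_mask)


def run(data, config: SearchConfig = None) -> List[Bicluster]:
    """Full biclustering search: mapping, iterative mining with support
    relaxation and inter-iteration masking, then closing.

    The support threshold starts at ceil(0.25 |X|) and shrinks by the
    factor 0.75 (floor: 2 rows) until the stopping criterion holds.  After
    each iteration but the last, 25% of the covered cells (most covered
    first) are masked to missing so later iterations focus on new regions.
    """
    from .closing import filter_biclusters, merge, significance
    from .network import network_to_dataset

    if config is None:
        config = SearchConfig()
    if isinstance(data, WeightedNetwork):
        data = network_to_dataset(data)
    config = config.resolve(data.has_negatives(), data.n_cols)

    transposed = config.orientation == "columns"
    if transposed:
        data = data.transpose()
    elif config.orientation != "rows":
        raise ConfigError(f"unknown orientation {config.orientation!r}")

    rng = np.random.default_rng(config.seed)
    numeric = handle_missings(data, config.missings)

    collected: Dict[Tuple[frozenset, frozenset], Bicluster] = {}
    working = numeric
    symbolic = None
    for iteration in range(config.n_iterations):
        symbolic = build_symbolic(working, config)
        db = map_for_assumption(symbolic, config.assumption, config)
        support = max(2, math.ceil(0.25 * numeric.n_rows))
        iteration_found: Dict[Tuple[frozenset, frozenset], Bicluster] = {}
        while True:
            patterns = _mine(db, config, support)
            for b in derive_biclusters(
                patterns, db, config.assumption, config, symbolic=symbolic
            ):
                iteration_found.setdefault(b.key(), b)
                collected.setdefault(b.key(), b)
            logger.info(
                "iteration %d: support %d -> %d biclusters (%d total)",
                iteration + 1, support, len(iteration_found), len(collected),
            )
            if _stopping_met(config, list(iteration_found.values()),
                             list(collected.values()), support, numeric):
                break
            if support <= 2:
                logger.warning(
                    "support floor reached before the stopping criterion; "
                    "returning the best-effort solution"
                )
                break
            support = max(2, min(support - 1, math.floor(support * 0.75)))
        if iteration < config.n_iterations - 1:
            working, n_masked = _mask_most_covered(
                working, list(collected.values()), rng
            )
            logger.info("iteration %d: masked %d cells", iteration + 1, n_masked)

    solution = list(collected.values())
    solution = merge(
        solution, overlap_threshold=config.quality, strategy=config.merging,
        symbolic=symbolic, quality=config.quality,
    )
    solution = filter_biclusters(
        solution, criterion=config.filter_criterion,
        min_dissimilar=config.filter_dissimilarity,
    )
    full_symbolic = build_symbolic(numeric, config)
    for b in solution:
        evaluate_quality(b, full_symbolic)
        b.p_value = significance(b, full_symbolic)

    if transposed:
        # swap back to the input orientation; the pattern stays aligned to
        # the mined axis (now the bicluster's rows)
        solution = [
            Bicluster(
                rows=b.cols, cols=b.rows, pattern=b.pattern,
                assumption=b.assumption, adjustments=b.adjustments,
                noisy_fraction=b.noisy_fraction,
                missing_fraction=b.missing_fraction,
                p_value=b.p_value, orientation="columns",
            )
            for b in solution
        ]
    solution.sort(key=lambda b: (-b.n_elements, b.rows, b.cols))
    return solution


def compute_coverage(solution: Sequence[Bicluster], data: NumericDataset) -> float:
    """Fraction of non-missing cells covered by at least one bicluster."""
    if data.n_nonmissing == 0:
        return 0.0
    ridx = {r: i for i, r in enumerate(data.row_ids)}
    cidx = {c: j for j, c in enumerate(data.col_ids)}
    covered: Set[Tuple[int, int]] = set()
    for b in solution:
        for r in b.rows:
            for c in b.cols:
                key = (ridx[r], cidx[c])
                if not data.is_missing(*key):
                    covered.add(key)
    return len(covered) / data.n_nonmissing
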
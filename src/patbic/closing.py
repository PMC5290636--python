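"""Post-processing: merging, dissimilarity filtering, extension/reduction
and statistical-significance annotation of bicluster solutions.

Merging tolerates noise and missing values by fusing biclusters whose
element overlap (relative to the smaller of the pair) reaches a threshold,
typically the quality level.  Filtering then removes biclusters that are
insufficiently dissimilar from a larger one, yielding a compact solution.

The significance annotation is a deliberately simple stand-in model: the
upper-tail binomial probability of observing at least |I| of |X| rows
matching the pattern, with a per-row occurrence probability estimated from
empirical column-wise symbol frequencies (independence across columns).
It is labeled as such in all output.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Optional, Sequence

from scipy import stats

from .errors import ConfigError
from .mapping import SymbolicDataset
from .models import Bicluster

__all__ = ["merge", "filter_biclusters", "extend_reduce", "significance"]


def _overlap(a: Bicluster, b: Bicluster) -> float:
    ea, eb = a.elements(), b.elements()
    denom = min(len(ea), len(eb))
    return len(ea & eb) / denom if denom else 0.0


def _merge_pair(a: Bicluster, b: Bicluster) -> Bicluster:
    """Union of rows and columns; the larger constituent's pattern wins on
    shared columns, the smaller fills the rest."""
    big, small = (a, b) if a.n_elements >= b.n_elements else (b, a)
    rows = tuple(sorted(set(big.rows) | set(small.rows)))
    pat: Dict[str, object] = dict(zip(small.cols, small.pattern))
    pat.update(zip(big.cols, big.pattern))
    cols = tuple(sorted(pat))
    adjustments = dict(small.adjustments)
    adjustments.update(big.adjustments)
    if big.assumption == "order_preserving":
        # preserve the larger bicluster's ordering; appended columns follow
        ordered = list(big.cols) + [c for c in small.cols if c not in big.cols]
        return Bicluster(
            rows=rows, cols=tuple(ordered),
            pattern=tuple(range(len(ordered))),
            assumption=big.assumption,
        )
    return Bicluster(
        rows=rows, cols=cols,
        pattern=tuple(pat[c] for c in cols),
        assumption=big.assumption,
        adjustments={r: adjustments.get(r, big.adjustments.get(r)) for r in rows
                     if r in adjustments},
    )


def merge(
    biclusters: Sequence[Bicluster],
    overlap_threshold: float = 0.8,
    strategy: str = "heuristic",
    symbolic: Optional[SymbolicDataset] = None,
    quality: Optional[float] = None,
) -> List[Bicluster]:
    """Merge pairs sharing >= ``overlap_threshold`` of the smaller pair
    member's elements.

    heuristic (default): size-descending greedy sweep repeated to fixpoint.
    combinatorial: exhaustive pairwise closure (every pair re-examined after
    each fusion).  When ``symbolic`` and ``quality`` are given, a fusion is
    vetoed if the merged bicluster's noisy or missing fraction would exceed
    1 - quality.
    """
    if overlap_threshold <= 0 or overlap_threshold > 1:
        raise ConfigError(
            f"overlap threshold must lie in (0, 1], got {overlap_threshold}"
        )
    if strategy not in ("heuristic", "combinatorial", "multi_support_fim"):
        raise ConfigError(f"unknown merging strategy {strategy!r}")
    from .core import evaluate_quality

    def admissible(m: Bicluster) -> bool:
        if symbolic is None or quality is None:
            return True
        evaluate_quality(m, symbolic)
        tol = 1 - quality
        return m.noisy_fraction <= tol + 1e-12 and m.missing_fraction <= tol + 1e-12

    work = list(biclusters)
    changed = True
    while changed:
        changed = False
        work.sort(key=lambda b: -b.n_elements)
        n = len(work)
        merged_pair = None
        for i in range(n):
            for j in range(i + 1, n):
                if _overlap(work[i], work[j]) >= overlap_threshold:
                    candidate = _merge_pair(work[i], work[j])
                    if admissible(candidate):
                        merged_pair = (i, j, candidate)
                        break
            if merged_pair and strategy == "heuristic":
                break
            if merged_pair:
                break
        if merged_pair:
            i, j, candidate = merged_pair
            work = [b for k, b in enumerate(work) if k not in (i, j)]
            work.append(candidate)
            changed = True
    # collapse exact duplicates
    seen, out = set(), []
    for b in sorted(work, key=lambda b: (-b.n_elements, b.rows, b.cols)):
        if b.key() not in seen:
            seen.add(b.key())
            out.append(b)
    return out


def _shared_fraction(b: Bicluster, larger: Bicluster, criterion: str) -> float:
    if criterion == "elements":
        own = b.elements()
        other = larger.elements()
    elif criterion == "rows":
        own, other = set(b.rows), set(larger.rows)
    elif criterion == "columns":
        own, other = set(b.cols), set(larger.cols)
    else:
        raise ConfigError(f"unknown filtering criterion {criterion!r}")
    return len(own & other) / len(own)


def filter_biclusters(
    biclusters: Sequence[Bicluster],
    criterion: str = "elements",
    min_dissimilar: float = 0.4,
) -> List[Bicluster]:
    """Remove biclusters lacking ``min_dissimilar`` dissimilar elements
    (or rows / columns) against a strictly larger retained bicluster.

    With 20% dissimilarity, a bicluster sharing more than 80% of its own
    elements with a larger one is removed; the default 40% removes above
    60% shared.
    """
    if not (0 < min_dissimilar < 1):
        raise ConfigError(
            f"min_dissimilar must lie in (0, 1), got {min_dissimilar}"
        )
    ordered = sorted(biclusters, key=lambda b: (-b.n_elements, b.rows, b.cols))
    retained: List[Bicluster] = []
    for b in ordered:
        removable = any(
            r.n_elements > b.n_elements
            and _shared_fraction(b, r, criterion) > 1 - min_dissimilar
            for r in retained
        )
        if not removable:
            retained.append(b)
    return retained


def extend_reduce(
    bic: Bicluster, symbolic: SymbolicDataset, quality: float = 0.8
) -> Bicluster:
    """Greedy extension then reduction against the homogeneity tolerance.

    Rows, then columns, are added while the bicluster's combined noisy +
    missing fraction stays within 1 - quality; afterwards rows/columns are
    removed while the fraction exceeds the tolerance, preferring removals
    that lower it most.  Terminates at a fixpoint.
    """
    from .core import evaluate_quality

    tol = 1 - quality + 1e-12
    ridx = {r: i for i, r in enumerate(symbolic.row_ids)}
    cidx = {c: j for j, c in enumerate(symbolic.col_ids)}

    def badness(rows, cols, adjustments) -> float:
        trial = Bicluster(
            rows=tuple(rows), cols=tuple(cols),
            pattern=bic.pattern if bic.assumption != "order_preserving"
            else tuple(range(len(cols))),
            assumption=bic.assumption, adjustments=adjustments,
        )
        evaluate_quality(trial, symbolic)
        return trial.noisy_fraction + trial.missing_fraction

    def best_adjustment(row_id: str, cols) -> object:
        """Adjustment minimizing mismatches of a candidate row."""
        if bic.assumption == "constant":
            return None
        i = ridx[row_id]
        alphabet = symbolic.alphabet
        if bic.assumption == "additive":
            candidates = range(
                alphabet.min_symbol - alphabet.max_symbol,
                alphabet.max_symbol - alphabet.min_symbol + 1,
            )
        elif bic.assumption == "symmetric":
            candidates = (1, -1)
        elif bic.assumption == "multiplicative":
            cand = {Fraction(1)}
            for s in alphabet.symbols:
                for k in alphabet.symbols:
                    if k != 0 and s != 0:
                        cand.add(Fraction(s, k))
            candidates = sorted(cand)
        else:
            return None
        best, best_miss = None, None
        pat = dict(zip(bic.cols, bic.pattern))
        for a in candidates:
            miss = 0
            for c in cols:
                cell = symbolic.cells.get((i, cidx[c]))
                k = pat.get(c)
                if cell is None or k is None:
                    continue
                if bic.assumption == "additive":
                    exp = int(k) + int(a)
                elif bic.assumption == "symmetric":
                    exp = int(k) * int(a)
                else:
                    v = Fraction(int(k)) * Fraction(a)
                    exp = int(v) if v.denominator == 1 else None
                if exp is None or exp not in cell:
                    miss += 1
            if best_miss is None or miss < best_miss:
                best, best_miss = a, miss
        return best

    rows = list(bic.rows)
    cols = list(bic.cols)
    adjustments = dict(bic.adjustments)

    # extension: rows first, then columns
    if bic.assumption != "order_preserving":
        improved = True
        while improved:
            improved = False
            for r in symbolic.row_ids:
                if r in rows:
                    continue
                adj = best_adjustment(r, cols)
                trial_adj = dict(adjustments)
                if adj is not None:
                    trial_adj[r] = adj
                if badness(rows + [r], cols, trial_adj) <= tol:
                    rows.append(r)
                    adjustments = trial_adj
                    improved = True
        pat = dict(zip(bic.cols, bic.pattern))
        improved = True
        while improved:
            improved = False
            for c in symbolic.col_ids:
                if c in pat:
                    continue
                # choose the majority expected base symbol for the column
                counts: Dict[int, int] = {}
                for r in rows:
                    cell = symbolic.cells.get((ridx[r], cidx[c]))
                    if not cell:
                        continue
                    for s in cell:
                        base = _invert(s, bic.assumption, adjustments.get(r))
                        if base is not None and base in symbolic.alphabet.symbols:
                            counts[base] = counts.get(base, 0) + 1
                if not counts:
                    continue
                k = max(sorted(counts), key=lambda s: counts[s])
                trial_pat = dict(pat)
                trial_pat[c] = k
                trial_cols = cols + [c]
                trial = Bicluster(
                    rows=tuple(rows), cols=tuple(trial_cols),
                    pattern=tuple(trial_pat[x] for x in trial_cols),
                    assumption=bic.assumption, adjustments=adjustments,
                )
                from .core import evaluate_quality as _eq
                _eq(trial, symbolic)
                if trial.noisy_fraction + trial.missing_fraction <= tol:
                    cols = trial_cols
                    pat = trial_pat
                    improved = True
        bic = Bicluster(
            rows=tuple(rows), cols=tuple(cols),
            pattern=tuple(pat[c] for c in cols),
            assumption=bic.assumption, adjustments=adjustments,
        )

    # reduction: drop the worst row/column while above tolerance
    from .core import evaluate_quality as _eq
    _eq(bic, symbolic)
    while bic.noisy_fraction + bic.missing_fraction > tol:
        best_trial = None
        best_bad = bic.noisy_fraction + bic.missing_fraction
        if bic.n_rows > 1:
            for r in bic.rows:
                rr = tuple(x for x in bic.rows if x != r)
                trial = Bicluster(
                    rows=rr, cols=bic.cols, pattern=bic.pattern,
                    assumption=bic.assumption,
                    adjustments={k: v for k, v in bic.adjustments.items() if k != r},
                )
                _eq(trial, symbolic)
                bad = trial.noisy_fraction + trial.missing_fraction
                if bad < best_bad:
                    best_bad, best_trial = bad, trial
        if bic.n_cols > 1:
            for pos, c in enumerate(bic.cols):
                cc = tuple(x for x in bic.cols if x != c)
                pp = tuple(p for k, p in enumerate(bic.pattern) if k != pos)
                if bic.assumption == "order_preserving":
                    pp = tuple(range(len(cc)))
                trial = Bicluster(
                    rows=bic.rows, cols=cc, pattern=pp,
                    assumption=bic.assumption, adjustments=dict(bic.adjustments),
                )
                _eq(trial, symbolic)
                bad = trial.noisy_fraction + trial.missing_fraction
                if bad < best_bad:
                    best_bad, best_trial = bad, trial
        if best_trial is None:
            break
        bic = best_trial
    return bic


def _invert(symbol: int, assumption: str, adjustment) -> Optional[int]:
    """Base pattern symbol implied by an observed symbol and an adjustment."""
    if assumption == "constant" or adjustment is None:
        return symbol
    if assumption == "additive":
        return symbol - int(adjustment)
    if assumption == "symmetric":
        return symbol * int(adjustment)
    if assumption == "multiplicative":
        v = Fraction(symbol) / Fraction(adjustment)
        return int(v) if v.denominator == 1 else None
    return symbol


def significance(bic: Bicluster, symbolic: SymbolicDataset) -> float:
    """Binomial upper-tail p-value of >= |I| of |X| rows matching the
    pattern (stand-in significance model; empirical column marginals).

    The per-row occurrence probability is the product over the bicluster's
    columns of the empirical frequency of the expected symbol in that
    column; order-preserving biclusters use a uniform-orderings null with
    per-row probability 1/|J|!.
    """
    n = symbolic.n_rows
    cidx = {c: j for j, c in enumerate(symbolic.col_ids)}
    if bic.assumption == "order_preserving":
        p_row = 1.0 / math.factorial(len(bic.cols))
    else:
        # column marginals ignore per-row adjustments: frequency of the
        # base pattern symbol (adjustment-free occurrence probability)
        p_row = 1.0
        for pos, c in enumerate(bic.cols):
            j = cidx[c]
            k = bic.pattern[pos]
            hits = sum(
                1 for i in range(n)
                if k in symbolic.cells.get((i, j), ())
            )
            p_row *= max(hits, 1) / n
    p = float(stats.binom.sf(bic.n_rows - 1, n, min(p_row, 1.0)))
    return min(max(p, 5e-324), 1.0)
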
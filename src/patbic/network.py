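"""Weighted-network adaptation of the matrix data model.

A weighted network becomes a (row = source node, column = target node)
dataset whose cells are edge weights; absent edges are missing — never
zero — so sparsity is handled by the same missing-aware searches used for
matrices, and storage stays proportional to the number of interactions.
"""

from __future__ import annotations

from typing import Optional

from .datasets import NumericDataset, WeightedNetwork
from .errors import ValidationError
from .models import Bicluster
from .mapping import SymbolicDataset

__all__ = ["network_to_dataset", "module_quality_check"]


def network_to_dataset(
    net: WeightedNetwork, bipartite: Optional[bool] = None
) -> NumericDataset:
    """Sparse dataset view of a network.

    Homogeneous networks (shared node set; the default whenever source and
    target node sets overlap) use one index for both axes.  Bipartite /
    heterogeneous networks keep disjoint row and column node sets.
    """
    if net.n_edges == 0:
        raise ValidationError("cannot map an empty network")
    sources = net.source_nodes()
    targets = net.target_nodes()
    if bipartite is None:
        bipartite = not (set(sources) & set(targets))
    if bipartite:
        row_ids, col_ids = sources, targets
    else:
        row_ids = col_ids = list(net.nodes)
    ridx = {r: i for i, r in enumerate(row_ids)}
    cidx = {c: j for j, c in enumerate(col_ids)}
    cells = {}
    for u, v, w in net.edges:
        if u in ridx and v in cidx:
            cells[(ridx[u], cidx[v])] = w
    return NumericDataset(row_ids, col_ids, cells)


def module_quality_check(
    bic: Bicluster, symbolic: SymbolicDataset, quality: float = 0.8
) -> bool:
    """True iff noisy and missing fractions within the module's block both
    stay within 1 - quality."""
    from .core import evaluate_quality

    evaluate_quality(bic, symbolic)
    tol = 1 - quality + 1e-12
    return bic.missing_fraction <= tol and bic.noisy_fraction <= tol
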
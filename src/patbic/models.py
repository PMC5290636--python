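"""Bicluster and search-configuration models."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Optional, Tuple

from .errors import ConfigError
from .mapping import Alphabet

__all__ = ["Bicluster", "SearchConfig", "ASSUMPTIONS"]

ASSUMPTIONS = ("constant", "additive", "multiplicative", "symmetric", "order_preserving")


@dataclass
class Bicluster:
    """A (rows, columns) submodule with its coherency model.

    ``pattern`` aligns with ``cols``: the expected symbol k_j per column
    (for order-preserving biclusters, ``cols`` is stored in pattern order
    and ``pattern`` holds the ranks 0..|J|-1).  ``adjustments`` maps each
    row id to its per-row term: shift gamma (additive), scale (multiplicative),
    sign +/-1 (symmetric); empty for constant and order-preserving models.
    """

    rows: Tuple[str, ...]
    cols: Tuple[str, ...]
    pattern: Tuple[object, ...]
    assumption: str
    adjustments: Dict[str, object] = field(default_factory=dict)
    noisy_fraction: float = 0.0
    missing_fraction: float = 0.0
    p_value: Optional[float] = None
    orientation: str = "rows"  # axis the pattern aligns with

    def __post_init__(self):
        if len(self.rows) < 1 or len(self.cols) < 1:
            raise ConfigError("a bicluster needs at least one row and one column")
        pattern_axis = self.cols if self.orientation == "rows" else self.rows
        if len(self.pattern) != len(pattern_axis):
            raise ConfigError("pattern must assign one expected value per column")
        if self.assumption not in ASSUMPTIONS:
            raise ConfigError(f"unknown assumption {self.assumption!r}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.cols)

    @property
    def n_elements(self) -> int:
        return len(self.rows) * len(self.cols)

    def elements(self) -> frozenset:
        return frozenset((r, c) for r in self.rows for c in self.cols)

    def key(self) -> Tuple[frozenset, frozenset]:
        return (frozenset(self.rows), frozenset(self.cols))

    def expected_symbol(self, row_id: str, col_pos: int) -> Optional[int]:
        """Model value for (row, J[col_pos]); None for order-preserving."""
        k = self.pattern[col_pos]
        if self.assumption == "constant":
            return int(k)
        if self.assumption == "additive":
            return int(k) + int(self.adjustments.get(row_id, 0))
        if self.assumption == "multiplicative":
            scale = self.adjustments.get(row_id, 1)
            v = Fraction(int(k)) * Fraction(scale)
            return int(v) if v.denominator == 1 else None
        if self.assumption == "symmetric":
            return int(k) * int(self.adjustments.get(row_id, 1))
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Bicluster({self.n_rows}x{self.n_cols}, {self.assumption}, "
            f"noisy={self.noisy_fraction:.2f}, missing={self.missing_fraction:.2f})"
        )


_STOPS = ("nbics", "coverage", "support")


@dataclass
class SearchConfig:
    """Full parameter bundle with the tool's default parameterization.

    Defaults: constant assumption, |L| = 5, quality 80%, row normalization,
    Gaussian discretization, multi-item noise handler off, symmetries chosen
    dynamically on negative values, missings removed, no uninformative-item
    removal, stop at 50 biclusters before merging, minimum 4 columns,
    2 iterations, closed patterns on rows with a dynamically selected miner,
    heuristic merging, filtering at 40% dissimilar elements.
    """

    assumption: str = "constant"
    n_items: int = 5
    quality: float = 0.8
    normalization: str = "row"
    discretization: str = "gaussian"
    noise_handler: bool = False
    noise_boundary: float = 0.25
    symmetries: object = "dynamic"  # True / False / "dynamic"
    missings: str = "remove"
    uninformative: str = "none"
    stop: str = "nbics"
    stop_value: float = 50
    min_cols: object = 4  # int or "auto" (ceil(sqrt(|Y|)))
    n_iterations: int = 2
    representation: str = "closed"
    orientation: str = "rows"
    miner: str = "dynamic"
    merging: str = "heuristic"
    filter_criterion: str = "elements"
    filter_dissimilarity: float = 0.4
    seed: int = 0

    def resolve(self, has_negatives: bool, n_cols: int) -> "SearchConfig":
        """Apply dynamic defaults and check parameter consistency."""
        from .mining import ITEMSET_ALGORITHMS, SEQUENCE_ALGORITHMS

        if self.assumption == "plaid":
            raise NotImplementedError(
                "the plaid assumption (cumulative overlap effects) is not "
                "implemented in this package"
            )
        if self.assumption not in ASSUMPTIONS:
            raise ConfigError(f"unknown assumption {self.assumption!r}")
        symmetric = self.symmetries
        if symmetric == "dynamic":
            symmetric = bool(has_negatives)
        symmetric = bool(symmetric)
        if self.n_items < 2:
            raise ConfigError(f"n_items must be >= 2, got {self.n_items}")
        if symmetric and self.assumption == "additive" and self.n_items % 2 == 0:
            raise ConfigError(
                "additive models with symmetries need an odd number of items "
                f"(got n_items={self.n_items}, symmetries=on)"
            )
        if symmetric and self.assumption == "multiplicative" and self.n_items % 2 == 1:
            raise ConfigError(
                "multiplicative models with symmetries need an even number of "
                f"items (got n_items={self.n_items}, symmetries=on)"
            )
        if self.assumption == "symmetric" and not symmetric:
            raise ConfigError(
                "the symmetric assumption requires a symmetric alphabet "
                "(symmetries=on or negative input values)"
            )
        if self.uninformative == "zero_entries":
            alpha = Alphabet(self.n_items, symmetric=symmetric)
            if 0 not in alpha.symbols:
                raise ConfigError(
                    "zero_entries removal needs 0 in the alphabet; a symmetric "
                    f"alphabet with even n_items={self.n_items} has none"
                )
        if not (0 < self.quality <= 1):
            raise ConfigError(f"quality must lie in (0, 1], got {self.quality}")
        if self.stop not in _STOPS:
            raise ConfigError(f"unknown stopping criterion {self.stop!r}")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")

        min_cols = self.min_cols
        if min_cols == "auto":
            min_cols = max(1, math.ceil(math.sqrt(n_cols)))
        min_cols = int(min_cols)

        representation = self.representation
        miner = self.miner
        if self.assumption == "order_preserving":
            if representation == "maximal":
                raise ConfigError(
                    "order-preserving searches support simple or closed "
                    "representations only"
                )
            if miner == "dynamic":
                miner = "indexspan" if representation == "simple" else "bide"
            if miner not in SEQUENCE_ALGORITHMS:
                raise ConfigError(
                    f"{miner!r} is not a sequential pattern miner "
                    f"(choose from {sorted(SEQUENCE_ALGORITHMS)})"
                )
            if representation not in SEQUENCE_ALGORITHMS[miner]:
                raise ConfigError(
                    f"miner {miner!r} does not serve representation "
                    f"{representation!r}"
                )
        else:
            if miner == "dynamic":
                miner = {
                    "closed": "charm_diffsets",
                    "maximal": "charm_mfi",
                    "simple": "fpgrowth",
                }[representation]
            if miner not in ITEMSET_ALGORITHMS:
                raise ConfigError(
                    f"{miner!r} is not a frequent itemset miner "
                    f"(choose from {sorted(ITEMSET_ALGORITHMS)})"
                )
            if representation not in ITEMSET_ALGORITHMS[miner]:
                raise ConfigError(
                    f"miner {miner!r} does not serve representation "
                    f"{representation!r}"
                )
        return replace(
            self,
            symmetries=symmetric,
            min_cols=min_cols,
            miner=miner,
        )
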
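"""Over-representation analysis of a gene list against gene-set
categories, with an exact hypergeometric upper tail and BH FDR across
the tested (post size-filter) categories.

The tail probability is computed as an exact rational sum of binomial
coefficients, not a distribution-function approximation, so tiny
categories give bit-exact answers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .diffexpr import fdr_adjust

log = logging.getLogger(__name__)

MIN_CATEGORY_SIZE = 5
ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """category_id -> (name, members) over an explicit gene universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    reference: frozenset[str]

    def __post_init__(self) -> None:
        for cat, (_, members) in self.sets.items():
            extra = members - self.reference
            if extra:
                raise ValueError(
                    f"category {cat!r} has members outside the reference "
                    f"universe, e.g. {sorted(extra)[:3]}"
                )

    @classmethod
    def from_gmt(cls, path, reference) -> "GeneSetCollection":
        """GMT: one tab-separated line per set (id, description, members...).
        Members outside the reference are dropped with a logged count."""
        reference = frozenset(reference)
        sets = {}
        dropped = 0
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                cat, name, *members = parts
                keep = frozenset(m for m in members if m in reference)
                dropped += len(set(members)) - len(keep)
                sets[cat] = (name, keep)
        if dropped:
            log.info("dropped %d gene-set members outside the universe", dropped)
        return cls(sets, reference)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for cat, (name, members) in self.sets.items():
                fh.write("\t".join([cat, name, *sorted(members)]) + "\n")


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError("invalid hypergeometric parameters")
    if k <= max(0, n + K - N):
        return 1.0
    if k > min(n, K):
        return 0.0
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return total / comb(N, n)


def ora_test(
    deg_list,
    collection: GeneSetCollection,
    min_size: int = MIN_CATEGORY_SIZE,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One-sided over-representation test per category.

    Categories smaller than ``min_size`` (within the universe) are
    excluded *before* testing, and BH FDR runs across the tested set
    only. Input genes outside the universe are dropped with a logged
    count; duplicates collapse with a warning. Results are sorted by
    (q, p, category).
    """
    degs = list(deg_list)
    if len(set(degs)) != len(degs):
        warnings.warn("duplicate gene ids in input list; collapsing")
    deg_set = set(degs)
    outside = deg_set - collection.reference
    if outside:
        log.info("dropped %d input genes outside the universe", len(outside))
        deg_set -= outside
    if not collection.reference:
        raise ValueError("empty reference universe")
    if not deg_set:
        raise ValueError("no input genes remain within the universe")

    N = len(collection.reference)
    n = len(deg_set)
    rows = []
    for cat, (name, members) in collection.sets.items():
        K = len(members)
        if K < min_size:
            continue
        k = len(members & deg_set)
        rows.append((cat, name, k, n, K, N, hypergeom_tail(k, N, K, n)))
    df = pd.DataFrame(
        rows, columns=["category_id", "name", "k", "n", "K", "N", "p"]
    )
    df["q"] = fdr_adjust(df["p"].to_numpy()) if len(df) else []
    df["significant"] = df["q"] < alpha
    df = df.sort_values(["q", "p", "category_id"], kind="stable")
    return df.reset_index(drop=True)
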
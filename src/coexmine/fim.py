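"""Frequent itemset mining over work-situation transactions.

The miner is a depth-first Eclat: every agent is mapped to the set of
transaction ids (tidset) of the WS it appears in, and candidate itemsets are
grown by prefix extension with tidset intersection.  Support is
anti-monotone — an itemset can never occur in more WS than any of its
subsets — so a branch whose tidset drops below the absolute threshold is
pruned without losing any frequent itemset.  This suits these data, where
the number of transactions (tens of thousands of WS) dwarfs the universe
(on the order of a hundred agents), and yields the exact WS count for every
reported itemset.

Two support denominators are in play throughout the analysis: all WS, used
in the pedagogical worked example, and the multi-agent universe (WS exposed
to at least two agents), used in the headline co-exposure tables.  The
``denominator_kind`` switch selects the counting universe; both numerator
and denominator are restricted, so supports remain proportions in a single
probability space (for itemsets of two or more agents the WS counts are
identical either way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import MiningParams
from .transactions import TransactionDB

__all__ = [
    "FrequentItemset",
    "support",
    "mine_frequent_itemsets",
    "top_k_itemsets",
    "effective_threshold",
    "write_itemsets",
    "itemsets_to_frame",
]


@dataclass(frozen=True)
class FrequentItemset:
    """An agent set with its exact WS count and support."""

    items: tuple[str, ...]  # sorted
    n_ws: int
    support: float
    denominator_kind: str


def effective_threshold(params: MiningParams, denominator: int) -> int:
    """Absolute WS threshold: max(ceil(min_support * denominator), min_ws).

    ceil keeps the relative floor conservative (0.1 % of 10,547 WS -> 11 WS);
    min_ws then applies as an absolute floor.
    """
    return max(math.ceil(params.min_support * denominator), params.min_ws)


def _counting_universe(db: TransactionDB, denominator_kind: str):
    """Transactions in scope for the chosen denominator, with their agent sets."""
    if denominator_kind == "all_ws":
        txs = db.transactions
    elif denominator_kind == "multi_agent_ws":
        txs = tuple(t for t in db.transactions if len(t.agents) >= 2)
    else:
        raise ValueError(f"unknown denominator_kind {denominator_kind!r}")
    return txs


def support(
    items: Iterable[str], db: TransactionDB, denominator_kind: str = "all_ws"
) -> tuple[int, float]:
    """Exact containment count and support of *items*.

    Returns ``(n_ws, support)``; agents absent from the database simply give
    a count of zero.  The empty itemset has no meaning here and is an error.
    """
    items = frozenset(items)
    if not items:
        raise ValueError("support of the empty itemset is undefined")
    txs = _counting_universe(db, denominator_kind)
    if not txs:
        raise ValueError("counting universe is empty")
    n = sum(1 for t in txs if items <= t.agents)
    return n, n / len(txs)


def mine_frequent_itemsets(
    db: TransactionDB, params: MiningParams
) -> list[FrequentItemset]:
    """All itemsets meeting the support threshold, with exact WS counts.

    Output is complete (every itemset at or above the effective absolute
    threshold, up to ``max_len`` items), duplicate-free, and sorted by
    (descending WS count, ascending length, lexicographic items).  Singleton
    itemsets are included: rule metrics and per-agent prevalence need them.
    """
    txs = _counting_universe(db, params.denominator_kind)
    denominator = len(txs)
    if denominator == 0:
        return []
    threshold = effective_threshold(params, denominator)
    max_len = params.max_len or float("inf")

    tidsets: dict[str, set[int]] = {}
    for tid, t in enumerate(txs):
        for a in t.agents:
            tidsets.setdefault(a, set()).add(tid)

    # frequent singletons, lexicographic order fixes the DFS prefix order
    items = sorted(a for a, tids in tidsets.items() if len(tids) >= threshold)

    out: list[FrequentItemset] = []

    def emit(prefix: tuple[str, ...], tids: set[int]) -> None:
        out.append(
            FrequentItemset(
                items=prefix,
                n_ws=len(tids),
                support=len(tids) / denominator,
                denominator_kind=params.denominator_kind,
            )
        )

    def grow(prefix: tuple[str, ...], siblings: list[tuple[str, set[int]]]) -> None:
        for i, (item, tids) in enumerate(siblings):
            candidate = prefix + (item,)
            emit(candidate, tids)
            if len(candidate) >= max_len:
                continue
            extensions = []
            for nxt, nxt_tids in siblings[i + 1:]:
                inter = tids & nxt_tids
                if len(inter) >= threshold:  # anti-monotone pruning
                    extensions.append((nxt, inter))
            if extensions:
                grow(candidate, extensions)

    grow((), [(a, tidsets[a]) for a in items])
    out.sort(key=lambda fi: (-fi.n_ws, len(fi.items), fi.items))
    return out


def top_k_itemsets(
    itemsets: Sequence[FrequentItemset],
    k: int,
    db: TransactionDB | None = None,
    min_items: int = 2,
) -> pd.DataFrame:
    """Top *k* itemsets by WS count, annotated with the modal sector.

    The annotation is the industrial sector with the largest number of WS
    exposed to the itemset, plus that count; it falls back to ``"n/a"`` when
    no transaction in scope carries a sector code (toy databases).  Ties are
    broken deterministically (count desc, length asc, lexicographic).
    """
    ranked = [fi for fi in itemsets if len(fi.items) >= min_items]
    ranked.sort(key=lambda fi: (-fi.n_ws, len(fi.items), fi.items))
    rows = []
    for fi in ranked[:k]:
        sector, sector_n = _modal_sector(fi.items, db)
        rows.append(
            {
                "items": "|".join(fi.items),
                "n_items": len(fi.items),
                "n_ws": fi.n_ws,
                "support": fi.support,
                "modal_sector": sector,
                "modal_sector_n": sector_n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["items", "n_items", "n_ws", "support",
                 "modal_sector", "modal_sector_n"],
    )


def _modal_sector(items: tuple[str, ...], db: TransactionDB | None):
    if db is None:
        return "n/a", 0
    itemset = frozenset(items)
    counts: dict[str, int] = {}
    for t in db.transactions:
        if itemset <= t.agents and t.key.sector_code:
            counts[t.key.sector_code] = counts.get(t.key.sector_code, 0) + 1
    if not counts:
        return "n/a", 0
    sector = min(counts, key=lambda s: (-counts[s], s))
    return sector, counts[sector]


def itemsets_to_frame(itemsets: Sequence[FrequentItemset]) -> pd.DataFrame:
    rows = [
        {
            "items": "|".join(fi.items),
            "n_items": len(fi.items),
            "n_ws": fi.n_ws,
            "support": fi.support,
            "denominator_kind": fi.denominator_kind,
        }
        for fi in itemsets
    ]
    return pd.DataFrame(
        rows, columns=["items", "n_items", "n_ws", "support", "denominator_kind"]
    )


def write_itemsets(itemsets: Sequence[FrequentItemset], path: str | Path) -> None:
    itemsets_to_frame(itemsets).to_csv(path, index=False)
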
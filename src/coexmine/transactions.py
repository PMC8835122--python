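"""Work situations and the transaction database.

A work situation (WS) is the unit of analysis: the group of measurements
sharing an industrial sector, an occupation, a task and a calendar year.
Reducing each WS to the set of agents detected at least once in it yields a
transaction database in the market-basket sense, over which frequent
itemsets and association rules are mined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .records import AgentCatalog, MeasurementRecord

__all__ = [
    "WorkSituationKey",
    "Transaction",
    "TransactionDB",
    "build_transactions",
    "merge_transaction_dbs",
    "summarize_coexposure",
    "export_long",
    "export_basket",
]


class WorkSituationKey(NamedTuple):
    """sector x occupation x task x calendar year; exact tuple equality."""

    sector_code: str
    occupation_code: str
    task_code: str
    year: int


@dataclass(frozen=True)
class Transaction:
    """One WS reduced to its set of detected agents."""

    key: WorkSituationKey
    agents: frozenset[str]
    n_records: int
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError(f"transaction {self.key} has an empty agent set")
        if self.n_records < len(self.agents):
            raise ValueError(
                f"transaction {self.key}: n_records ({self.n_records}) < "
                f"|agents| ({len(self.agents)})"
            )


@dataclass(frozen=True)
class TransactionDB:
    """Deterministically ordered list of WS transactions."""

    transactions: tuple[Transaction, ...]

    @property
    def n_total(self) -> int:
        return len(self.transactions)

    @property
    def n_multi(self) -> int:
        """Number of WS exposed to at least two distinct agents."""
        return sum(1 for t in self.transactions if len(t.agents) >= 2)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t.agents
        return frozenset(out)

    @classmethod
    def from_baskets(
        cls,
        baskets: Iterable[Iterable[str]],
        keys: Sequence[WorkSituationKey] | None = None,
    ) -> "TransactionDB":
        """Build a toy database straight from agent sets (one per WS).

        Used for worked examples and tests; generated keys carry no sector
        information (empty sector/occupation codes, task = running index).
        """
        baskets = [frozenset(b) for b in baskets]
        if keys is None:
            keys = [
                WorkSituationKey("", "", f"WS{i + 1}", 0)
                for i in range(len(baskets))
            ]
        txs = [
            Transaction(key=k, agents=b, n_records=len(b), sources=frozenset())
            for k, b in zip(keys, baskets)
        ]
        return cls(transactions=tuple(sorted(txs, key=lambda t: t.key)))


def build_transactions(records: Sequence[MeasurementRecord]) -> TransactionDB:
    """Group retained (detected-only) records into WS transactions.

    One transaction per distinct (sector, occupation, task, year) tuple;
    its agent set is the distinct agents among the group's records.  Output
    is sorted by key so downstream reports are byte-stable.
    """
    groups: dict[WorkSituationKey, list[MeasurementRecord]] = {}
    for r in records:
        key = WorkSituationKey(r.sector_code, r.occupation_code, r.task_code, r.year)
        groups.setdefault(key, []).append(r)
    txs = [
        Transaction(
            key=key,
            agents=frozenset(r.agent_id for r in recs),
            n_records=len(recs),
            sources=frozenset(r.source for r in recs),
        )
        for key, recs in groups.items()
    ]
    return TransactionDB(transactions=tuple(sorted(txs, key=lambda t: t.key)))


def merge_transaction_dbs(*dbs: TransactionDB) -> TransactionDB:
    """Merge databases, unioning transactions that share a WS key.

    Grouping is associative: building transactions from concatenated record
    files equals building per file and merging.
    """
    merged: dict[WorkSituationKey, tuple[set[str], int, set[str]]] = {}
    for db in dbs:
        for t in db.transactions:
            agents, n, sources = merged.setdefault(t.key, (set(), 0, set()))
            agents |= t.agents
            sources |= t.sources
            merged[t.key] = (agents, n + t.n_records, sources)
    txs = [
        Transaction(key=k, agents=frozenset(a), n_records=n, sources=frozenset(s))
        for k, (a, n, s) in merged.items()
    ]
    return TransactionDB(transactions=tuple(sorted(txs, key=lambda t: t.key)))


def summarize_coexposure(
    db: TransactionDB,
    catalog: AgentCatalog | None = None,
    records: Sequence[MeasurementRecord] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-agent exposure and co-exposure summary.

    Returns a table with, per agent: number of contributing records (exact
    when *records* is given, otherwise -1), number of WS exposed, and the
    proportion of those WS also exposed to at least one other agent; plus a
    dict summarising the agents-per-WS distribution (median, IQR, max) over
    the whole database.
    """
    if db.n_total == 0:
        raise ValueError("empty transaction database")
    n_ws: dict[str, int] = {}
    n_co: dict[str, int] = {}
    for t in db.transactions:
        multi = len(t.agents) >= 2
        for a in t.agents:
            n_ws[a] = n_ws.get(a, 0) + 1
            n_co[a] = n_co.get(a, 0) + (1 if multi else 0)
    rec_counts = record_counts_by_agent(records) if records is not None else None
    rows = []
    for a in sorted(n_ws):
        rows.append(
            {
                "agent_id": a,
                "name": catalog[a].name if catalog and a in catalog else a,
                "carcinogen": bool(catalog and a in catalog and catalog[a].carcinogen),
                "n_records": rec_counts.get(a, 0) if rec_counts is not None else -1,
                "n_ws": n_ws[a],
                "coexposure_proportion": n_co[a] / n_ws[a],
            }
        )
    sizes = np.array([len(t.agents) for t in db.transactions])
    dist = {
        "n_ws": db.n_total,
        "n_multi_agent_ws": db.n_multi,
        "median_agents_per_ws": float(np.median(sizes)),
        "iqr_agents_per_ws": (
            float(np.percentile(sizes, 25)),
            float(np.percentile(sizes, 75)),
        ),
        "max_agents_per_ws": int(sizes.max()),
    }
    return pd.DataFrame(rows), dist


def record_counts_by_agent(records: Sequence[MeasurementRecord]) -> dict[str, int]:
    """Exact per-agent record counts (preferred over the even split used when
    only transactions are available)."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.agent_id] = counts.get(r.agent_id, 0) + 1
    return counts


def export_long(db: TransactionDB, path: str | Path) -> None:
    """Long format: one (ws_id, agent_id) row per detected agent."""
    rows = []
    for i, t in enumerate(db.transactions):
        ws_id = f"WS{i + 1:06d}"
        for a in sorted(t.agents):
            rows.append(
                {
                    "ws_id": ws_id,
                    "sector_code": t.key.sector_code,
                    "occupation_code": t.key.occupation_code,
                    "task_code": t.key.task_code,
                    "year": t.key.year,
                    "agent_id": a,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def export_basket(db: TransactionDB, path: str | Path, delimiter: str = "|") -> None:
    """Basket format: one WS per line, agents joined by *delimiter*."""
    with open(path, "w") as fh:
        for t in db.transactions:
            fh.write(delimiter.join(sorted(t.agents)) + "\n")
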
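"""Carcinogen-restricted mining, sector/task strata, pairwise co-occurrence.

The carcinogen restriction intersects every WS's agent set with the set of
catalog-flagged carcinogens (IARC group 1 / 2A / 2B in the input catalog)
and drops WS left empty; supports are then computed over the restricted
multi-agent universe, recomputed from the data.

Stratified analyses split the transaction database by industrial sector or
by task.  A stratum qualifies only with at least ``min_stratum_ws``
(default 100) WS exposed to two or more agents; within a qualifying
stratum the support floor is the greater of 0.1 % of the stratum's WS and
10 WS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MiningParams, RuleParams, StrataParams
from .fim import mine_frequent_itemsets, top_k_itemsets
from .records import AgentCatalog
from .rules import mine_rules, rank_rules
from .transactions import Transaction, TransactionDB, summarize_coexposure

__all__ = [
    "restrict_to_carcinogens",
    "StratumReport",
    "stratified_mining",
    "CooccurrenceMatrix",
    "cooccurrence_matrix",
]


def restrict_to_carcinogens(db: TransactionDB, catalog: AgentCatalog) -> TransactionDB:
    """Project every transaction onto the catalog's carcinogen set.

    Transactions emptied by the restriction are dropped; counts (n_multi,
    universe) follow from the surviving transactions.  A catalog with no
    carcinogen flags is a configuration error.
    """
    carcinogens = catalog.carcinogens
    if not carcinogens:
        raise ValueError("catalog flags no carcinogens; cannot restrict")
    txs = []
    for t in db.transactions:
        agents = t.agents & carcinogens
        if agents:
            txs.append(
                Transaction(
                    key=t.key, agents=frozenset(agents),
                    n_records=max(t.n_records, len(agents)), sources=t.sources,
                )
            )
    return TransactionDB(transactions=tuple(txs))


@dataclass
class StratumReport:
    """The four per-stratum tables: agent prevalence, frequent itemsets,
    top rules by confidence, top rules by lift."""

    stratum_code: str
    strat_by: str
    n_ws: int
    n_multi: int
    threshold_ws: int
    prevalence: pd.DataFrame = field(repr=False, default=None)
    itemsets: pd.DataFrame = field(repr=False, default=None)
    rules_by_confidence: pd.DataFrame = field(repr=False, default=None)
    rules_by_lift: pd.DataFrame = field(repr=False, default=None)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.prevalence.to_csv(directory / "agent_prevalence.csv", index=False)
        self.itemsets.to_csv(directory / "frequent_itemsets.csv", index=False)
        self.rules_by_confidence.to_csv(
            directory / "rules_by_confidence.csv", index=False
        )
        self.rules_by_lift.to_csv(directory / "rules_by_lift.csv", index=False)


def stratum_support_floor(n_ws: int, params: StrataParams | None = None) -> int:
    """Effective absolute support floor for a stratum of *n_ws* WS:
    max(ceil(0.1% of n_ws), 10)."""
    params = params or StrataParams()
    return max(int(np.ceil(params.stratum_min_support * n_ws)), params.min_ws_floor)


def stratified_mining(
    db: TransactionDB,
    catalog: AgentCatalog,
    strat_by: str,
    params: StrataParams | None = None,
) -> tuple[dict[str, StratumReport], list[dict]]:
    """Mine each qualifying sector or task stratum separately.

    Returns ``(reports, skipped)``: one :class:`StratumReport` per stratum
    with at least ``min_stratum_ws`` multi-agent WS, and a log of strata
    skipped for falling below that floor.
    """
    if strat_by not in ("sector", "task"):
        raise ValueError("strat_by must be 'sector' or 'task'")
    params = params or StrataParams()
    attr = "sector_code" if strat_by == "sector" else "task_code"

    groups: dict[str, list[Transaction]] = {}
    for t in db.transactions:
        groups.setdefault(getattr(t.key, attr), []).append(t)

    reports: dict[str, StratumReport] = {}
    skipped: list[dict] = []
    for code in sorted(groups):
        sub = TransactionDB(transactions=tuple(groups[code]))
        if sub.n_multi < params.min_stratum_ws:
            skipped.append(
                {"stratum": code, "strat_by": strat_by, "n_multi_agent_ws": sub.n_multi,
                 "reason": f"fewer than {params.min_stratum_ws} multi-agent WS"}
            )
            continue
        threshold = stratum_support_floor(sub.n_multi, params)
        mp = MiningParams(
            min_support=params.stratum_min_support,
            min_ws=params.min_ws_floor,
            denominator_kind="multi_agent_ws",
        )
        itemsets = mine_frequent_itemsets(sub, mp)
        rp = RuleParams(
            min_support=params.stratum_min_support,
            min_ws=params.min_ws_floor,
            min_confidence=params.min_confidence,
            denominator_kind="multi_agent_ws",
        )
        rules = mine_rules(sub, rp, itemsets=itemsets)
        prevalence, _ = summarize_coexposure(sub, catalog)
        reports[code] = StratumReport(
            stratum_code=code,
            strat_by=strat_by,
            n_ws=sub.n_total,
            n_multi=sub.n_multi,
            threshold_ws=threshold,
            prevalence=prevalence,
            itemsets=top_k_itemsets(itemsets, params.top_k, sub),
            rules_by_confidence=rank_rules(rules, "confidence", k=params.top_k),
            rules_by_lift=rank_rules(rules, "lift", k=params.top_k),
        )
    return reports, skipped


@dataclass
class CooccurrenceMatrix:
    """Symmetric pairwise WS-count matrix over a subset of agents.

    Diagonal entries are per-agent WS counts; entry (i, j) is the number of
    WS with both agents detected.  Off-diagonal entries below ``floor`` are
    masked (not zeroed) in exports, mirroring the display rule of the
    published co-occurrence chart.
    """

    agents: tuple[str, ...]
    counts: np.ndarray  # square, int
    floor: int
    excluded: tuple[str, ...]

    def to_frame(self, masked: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.agents, columns=self.agents)
        if masked:
            df = df.astype("Int64")
            mask = (self.counts < self.floor) & ~np.eye(len(self.agents), dtype=bool)
            df = df.mask(mask)
        return df

    def write(self, path: str | Path, masked: bool = True) -> None:
        self.to_frame(masked=masked).to_csv(path, index_label="agent_id")

    def plot(self, path: str | Path) -> None:
        """Heatmap with darker shades for more frequent co-occurrences."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.agents)
        data = self.counts.astype(float)
        mask = (self.counts < self.floor) & ~np.eye(n, dtype=bool)
        data[mask] = np.nan
        np.fill_diagonal(data, np.nan)  # diagonal would dominate the scale
        fig, ax = plt.subplots(figsize=(max(4, n * 0.3),) * 2)
        im = ax.imshow(data, cmap="Blues")
        ax.set_xticks(range(n), self.agents, rotation=90, fontsize=6)
        ax.set_yticks(range(n), self.agents, fontsize=6)
        fig.colorbar(im, ax=ax, label="WS with co-occurrence")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def cooccurrence_matrix(
    db: TransactionDB,
    agent_subset: Sequence[str] | None = None,
    floor: int = 10,
    exclude: Sequence[str] = (),
) -> CooccurrenceMatrix:
    """Exact pairwise WS counts over *agent_subset* (default: the universe),
    minus *exclude*; pairs below *floor* are masked on export."""
    agents = set(agent_subset) if agent_subset is not None else set(db.universe)
    agents -= set(exclude)
    if not agents:
        raise ValueError("no agents left after exclusions")
    order = tuple(sorted(agents))
    index = {a: i for i, a in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t in db.transactions:
        present = sorted(a for a in t.agents if a in index)
        for i, a in enumerate(present):
            ia = index[a]
            counts[ia, ia] += 1
            for b in present[i + 1:]:
                ib = index[b]
                counts[ia, ib] += 1
                counts[ib, ia] += 1
    return CooccurrenceMatrix(
        agents=order, counts=counts, floor=floor, excluded=tuple(sorted(exclude))
    )
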
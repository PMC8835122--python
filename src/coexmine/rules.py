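"""Association rules over co-exposure itemsets.

A rule A -> C splits an itemset into a non-empty antecedent A and a
disjoint non-empty consequent C.  Three interestingness measures are used:

* support — proportion of WS (in the chosen denominator universe)
  containing A ∪ C; identical for a rule and its complement C -> A;
* confidence — proportion of WS containing A that also contain C, i.e.
  n_ws(A ∪ C) / n_ws(A); NOT symmetric between complements;
* lift — observed rule support over its expectation were A and C
  independent, support(A ∪ C) / (support(A) · support(C)), equivalently
  confidence(A -> C) / support(C); 1 means independence, >1 positive
  dependence; symmetric between complements.

Every emitted rule also carries the confidence of its complementary rule,
whether or not the complement itself clears the confidence floor — the
report tables print both.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import RuleParams
from .fim import FrequentItemset, mine_frequent_itemsets, support
from .transactions import TransactionDB

__all__ = [
    "AssociationRule",
    "confidence",
    "lift",
    "mine_rules",
    "rank_rules",
    "rules_to_frame",
    "write_rules",
]


@dataclass(frozen=True)
class AssociationRule:
    antecedent: tuple[str, ...]  # sorted, non-empty
    consequent: tuple[str, ...]  # sorted, non-empty, disjoint from antecedent
    n_ws: int                    # WS containing antecedent ∪ consequent
    support: float
    confidence: float
    lift: float
    confidence_complement: float
    denominator_kind: str


def confidence(
    antecedent, consequent, db: TransactionDB, denominator_kind: str = "all_ws"
) -> float:
    """n_ws(A ∪ C) / n_ws(A); a ratio of counts, so independent of the
    denominator choice. Undefined (error) when A never occurs."""
    a = frozenset(antecedent)
    c = frozenset(consequent)
    _check_rule_sets(a, c)
    n_a, _ = support(a, db, denominator_kind)
    if n_a == 0:
        raise ValueError("confidence undefined: antecedent never occurs")
    n_ac, _ = support(a | c, db, denominator_kind)
    return n_ac / n_a


def lift(
    antecedent, consequent, db: TransactionDB, denominator_kind: str = "all_ws"
) -> float:
    """support(A ∪ C) / (support(A) · support(C)) in the chosen universe."""
    a = frozenset(antecedent)
    c = frozenset(consequent)
    _check_rule_sets(a, c)
    _, s_a = support(a, db, denominator_kind)
    _, s_c = support(c, db, denominator_kind)
    if s_a == 0 or s_c == 0:
        raise ValueError("lift undefined: zero marginal support")
    _, s_ac = support(a | c, db, denominator_kind)
    return s_ac / (s_a * s_c)


def _check_rule_sets(a: frozenset, c: frozenset) -> None:
    if not a or not c:
        raise ValueError("antecedent and consequent must be non-empty")
    if a & c:
        raise ValueError("antecedent and consequent must be disjoint")


def mine_rules(
    db: TransactionDB,
    params: RuleParams | None = None,
    itemsets: Sequence[FrequentItemset] | None = None,
) -> list[AssociationRule]:
    """All rules from frequent itemsets passing support and confidence floors.

    Every ordered bipartition (A, C) of every frequent itemset of size >= 2
    is a candidate; antecedents and consequents of any size are allowed.
    Because support is anti-monotone, A and C are themselves frequent at the
    same threshold, so their counts come from the mining pass — no rescan.
    Rules whose antecedent or consequent has zero support cannot arise from
    a frequent parent and are thus never emitted.
    """
    params = params or RuleParams()
    if itemsets is None:
        itemsets = mine_frequent_itemsets(db, params.mining_params())
    counts = {fs.items: fs.n_ws for fs in itemsets}
    supports = {fs.items: fs.support for fs in itemsets}

    out: list[AssociationRule] = []
    for fs in itemsets:
        if len(fs.items) < 2:
            continue
        items = fs.items
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                cons = tuple(x for x in items if x not in ante)
                conf = fs.n_ws / counts[ante]
                if conf < params.min_confidence:
                    continue
                out.append(
                    AssociationRule(
                        antecedent=ante,
                        consequent=cons,
                        n_ws=fs.n_ws,
                        support=fs.support,
                        confidence=conf,
                        lift=conf / supports[cons],
                        confidence_complement=fs.n_ws / counts[cons],
                        denominator_kind=fs.denominator_kind,
                    )
                )
    out.sort(
        key=lambda r: (-r.n_ws, len(r.antecedent) + len(r.consequent),
                       r.antecedent, r.consequent)
    )
    return out


def rank_rules(
    rules: Sequence[AssociationRule],
    by: str = "confidence",
    min_support_report: float = 0.0,
    k: int = 10,
    max_consequent_items: int | None = 1,
) -> pd.DataFrame:
    """Top *k* rules by confidence or lift above a report-level support floor.

    Ties are broken deterministically: metric desc, support desc, then
    lexicographic antecedent and consequent.  ``max_consequent_items``
    restricts consequent size in the printed table (default: single-item
    consequents, the convention of the published rule tables); ``None``
    lifts the restriction.
    """
    if by not in ("confidence", "lift"):
        raise ValueError("by must be 'confidence' or 'lift'")
    pool = [
        r
        for r in rules
        if r.support >= min_support_report
        and (max_consequent_items is None or len(r.consequent) <= max_consequent_items)
    ]
    pool.sort(
        key=lambda r: (
            -getattr(r, by), -r.support, r.antecedent, r.consequent,
        )
    )
    return rules_to_frame(pool[:k])


def rules_to_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    rows = [
        {
            "antecedent": "|".join(r.antecedent),
            "consequent": "|".join(r.consequent),
            "n_ws": r.n_ws,
            "support": r.support,
            "confidence": r.confidence,
            "lift": r.lift,
            "confidence_complement": r.confidence_complement,
        }
        for r in rules
    ]
    return pd.DataFrame(
        rows,
        columns=["antecedent", "consequent", "n_ws", "support",
                 "confidence", "lift", "confidence_complement"],
    )


def write_rules(rules: Sequence[AssociationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)
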
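"""Independent brute-force oracles for the miners.

These deliberately share no code with the package's Eclat/rule machinery:
frequent itemsets come from enumerating the full powerset of the universe
with a direct containment scan, rules from enumerating every ordered
bipartition of every observed itemset.  Feasible only on small universes,
which is the point.
"""

from __future__ import annotations

from itertools import chain, combinations


def brute_force_itemsets(
    baskets: list[frozenset[str]], threshold: int, max_len: int | None = None
) -> dict[tuple[str, ...], int]:
    """All itemsets with containment count >= threshold, by powerset scan."""
    universe = sorted(set(chain.from_iterable(baskets)))
    top = max_len or len(universe)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, min(top, len(universe)) + 1):
        for items in combinations(universe, r):
            s = frozenset(items)
            n = sum(1 for b in baskets if s <= b)
            if n >= threshold:
                out[items] = n
    return out


def brute_force_rules(
    baskets: list[frozenset[str]],
    threshold: int,
    min_confidence: float,
) -> dict[tuple[tuple[str, ...], tuple[str, ...]], dict]:
    """Every rule A -> C over every ordered bipartition of every itemset
    meeting the support threshold, filtered by the confidence floor."""
    n_total = len(baskets)
    freq = brute_force_itemsets(baskets, threshold)
    out = {}
    for items, n_ws in freq.items():
        if len(items) < 2:
            continue
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                cons = tuple(x for x in items if x not in ante)
                n_a = sum(1 for b in baskets if frozenset(ante) <= b)
                n_c = sum(1 for b in baskets if frozenset(cons) <= b)
                conf = n_ws / n_a
                if conf < min_confidence:
                    continue
                out[(ante, cons)] = {
                    "n_ws": n_ws,
                    "support": n_ws / n_total,
                    "confidence": conf,
                    "lift": (n_ws / n_total) / ((n_a / n_total) * (n_c / n_total)),
                    "confidence_complement": n_ws / n_c,
                }
    return out


def random_baskets(rng, n_agents: int, n_transactions: int) -> list[frozenset[str]]:
    """Random non-empty agent sets over a small universe (test workload)."""
    agents = [f"a{i:02d}" for i in range(n_agents)]
    baskets = []
    for _ in range(n_transactions):
        probs = rng.uniform(0.05, 0.6)
        mask = rng.random(n_agents) < probs
        basket = frozenset(a for a, m in zip(agents, mask) if m)
        if not basket:
            basket = frozenset({agents[int(rng.integers(n_agents))]})
        baskets.append(basket)
    return baskets
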
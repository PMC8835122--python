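"""Carcinogen restriction, sector/task strata, pairwise co-occurrence."""

from __future__ import annotations

import numpy as np
import pytest

from coexmine import (
    AgentCatalog,
    CatalogEntry,
    MiningParams,
    TransactionDB,
    WorkSituationKey,
    cooccurrence_matrix,
    mine_frequent_itemsets,
    restrict_to_carcinogens,
    stratified_mining,
    support,
)
from coexmine.config import StrataParams
from coexmine.subanalyses import stratum_support_floor

from oracles import random_baskets


def _catalog(agents, carcinogens):
    return AgentCatalog(
        CatalogEntry(agent_id=a, name=a, carcinogen=a in carcinogens)
        for a in agents
    )


class TestCarcinogenRestriction:
    def test_table1_restriction_drops_unflagged_only_ws(self, table1_db,
                                                        table1_catalog):
        # wood dust and ethanol are unflagged; WS2 (wood dust alone) vanishes
        cdb = restrict_to_carcinogens(table1_db, table1_catalog)
        assert cdb.n_total == 3
        assert [set(t.agents) for t in cdb.transactions] == [
            {"asbestos", "lead"},
            {"benzene", "lead"},
            {"asbestos", "chromium", "lead"},
        ]

    def test_partial_restriction_keeps_carcinogen_subset(self):
        db = TransactionDB.from_baskets([{"a", "b", "c", "d", "e"}])
        cdb = restrict_to_carcinogens(db, _catalog("abcde", {"b", "d"}))
        assert [set(t.agents) for t in cdb.transactions] == [{"b", "d"}]

    def test_no_flagged_carcinogens_is_an_error(self, table1_db):
        catalog = _catalog(sorted(table1_db.universe), set())
        with pytest.raises(ValueError, match="no carcinogens"):
            restrict_to_carcinogens(table1_db, catalog)

    def test_multi_carcinogen_count_matches_recount(self, rng):
        baskets = random_baskets(rng, n_agents=10, n_transactions=150)
        agents = sorted({a for b in baskets for a in b})
        carcinogens = set(agents[::2])
        db = TransactionDB.from_baskets(baskets)
        cdb = restrict_to_carcinogens(db, _catalog(agents, carcinogens))
        expected = sum(1 for b in baskets if len(b & carcinogens) >= 2)
        assert cdb.n_multi == expected

    def test_restriction_commutes_with_counting(self, rng):
        """Supports of all-carcinogen itemsets are unchanged by projecting
        the database onto the carcinogen set (same WS counts)."""
        baskets = random_baskets(rng, n_agents=10, n_transactions=200)
        agents = sorted({a for b in baskets for a in b})
        carcinogens = set(agents[:5])
        db = TransactionDB.from_baskets(baskets)
        cdb = restrict_to_carcinogens(db, _catalog(agents, carcinogens))
        for pair in [(agents[0], agents[2]), (agents[1], agents[3])]:
            n_full, _ = support(pair, db, "all_ws")
            n_restricted = sum(1 for t in cdb.transactions
                               if frozenset(pair) <= t.agents)
            assert n_full == n_restricted


def _stratified_db(sizes: dict[str, int], strat="sector"):
    baskets, keys = [], []
    for code, n in sizes.items():
        for i in range(n):
            sector = code if strat == "sector" else "S0"
            task = code if strat == "task" else "T0"
            keys.append(WorkSituationKey(sector, "O1", f"{task}_{i}", 2015))
            baskets.append({"a", "b"} if i % 2 == 0 else {"a", "c"})
    return TransactionDB.from_baskets(baskets, keys=keys)


class TestStratifiedMining:
    def test_qualification_boundary_99_vs_100(self):
        db = _stratified_db({"S_small": 99, "S_big": 100})
        catalog = _catalog("abc", {"a"})
        reports, skipped = stratified_mining(db, catalog, "sector")
        assert set(reports) == {"S_big"}
        assert [s["stratum"] for s in skipped] == ["S_small"]

    def test_qualification_counts_multi_agent_ws_only(self):
        # 120 WS but only 60 with >= 2 agents -> skipped
        baskets = [{"a", "b"}] * 60 + [{"a"}] * 60
        keys = [WorkSituationKey("S1", "O1", f"T{i}", 2015) for i in range(120)]
        db = TransactionDB.from_baskets(baskets, keys=keys)
        reports, skipped = stratified_mining(db, _catalog("ab", {"a"}), "sector")
        assert not reports and len(skipped) == 1

    def test_support_floor_rule(self):
        # 0.1% of 500 -> ceil(0.5) = 1, floored at 10; 0.1% of 20,000 -> 20
        assert stratum_support_floor(500) == 10
        assert stratum_support_floor(20000) == 20
        assert stratum_support_floor(9999) == 10
        assert stratum_support_floor(10001) == 11

    def test_task_strata_and_planted_pair_ranks_first(self, rng):
        baskets, keys = [], []
        for i in range(150):  # stratum T_weld: planted pair (w1, w2)
            basket = {"w1", "w2"} if rng.random() < 0.8 else {"w1", "x"}
            keys.append(WorkSituationKey(f"S{i % 3}", "O1", "T_weld", 2015))
            baskets.append(basket)
        for i in range(150):  # background stratum with a different mixture
            keys.append(WorkSituationKey("S9", "O1", "T_paint", 2015))
            baskets.append({"p1", "p2"})
        db = TransactionDB.from_baskets(baskets, keys=keys)
        catalog = _catalog(["w1", "w2", "x", "p1", "p2"], {"w1"})
        reports, _ = stratified_mining(db, catalog, "task")
        assert set(reports) == {"T_weld", "T_paint"}
        top = reports["T_weld"].itemsets.iloc[0]
        assert top["items"] == "w1|w2"
        # four per-stratum tables are all populated
        rep = reports["T_weld"]
        assert not rep.prevalence.empty
        assert not rep.rules_by_confidence.empty
        assert not rep.rules_by_lift.empty

    def test_stratified_counts_partition_full_db(self, rng):
        """Summing an itemset's WS count over sector strata recovers its
        full-database count (every WS carries exactly one sector code)."""
        baskets, keys = [], []
        for i in range(300):
            sector = f"S{int(rng.integers(3))}"
            keys.append(WorkSituationKey(sector, "O1", f"T{i}", 2015))
            mask = rng.random(4) < 0.5
            basket = {f"a{j}" for j, m in enumerate(mask) if m} or {"a0"}
            baskets.append(basket)
        db = TransactionDB.from_baskets(baskets, keys=keys)
        params = StrataParams(min_stratum_ws=1, min_ws_floor=1)
        catalog = _catalog([f"a{j}" for j in range(4)], {"a0"})
        reports, _ = stratified_mining(db, catalog, "sector", params)
        pair = ("a0", "a1")
        total = sum(
            sum(1 for t in TransactionDB.from_baskets(
                [b for k, b in zip(keys, baskets) if k.sector_code == code]
            ).transactions if frozenset(pair) <= t.agents)
            for code in reports
        )
        n_full, _ = support(pair, db, "all_ws")
        assert total == n_full


class TestCooccurrence:
    def test_table1_pairwise_counts(self, table1_db):
        m = cooccurrence_matrix(table1_db, floor=1)
        df = m.to_frame(masked=False)
        assert df.loc["asbestos", "lead"] == 2
        assert df.loc["asbestos", "chromium"] == 1
        assert df.loc["lead", "lead"] == 3  # diagonal: per-agent WS count

    def test_floor_masks_toy_db_off_diagonal(self, table1_db):
        m = cooccurrence_matrix(table1_db, floor=10)
        df = m.to_frame(masked=True)
        off = ~np.eye(len(df), dtype=bool)
        assert df.where(off).isna().all(axis=None)
        # masked, not zeroed: unmasked counts are still there
        assert m.to_frame(masked=False).loc["asbestos", "lead"] == 2

    def test_exclusions_drop_agents(self, table1_db):
        m = cooccurrence_matrix(table1_db, floor=1,
                                exclude=["wood dust", "ethanol"])
        assert "wood dust" not in m.agents and "ethanol" not in m.agents
        with pytest.raises(ValueError, match="no agents left"):
            cooccurrence_matrix(table1_db, exclude=sorted(table1_db.universe))

    def test_matrix_equals_pairwise_itemset_supports(self, rng):
        """Cross-module consistency: entry (i, j) equals the miner's WS count
        for the 2-itemset {i, j}."""
        baskets = random_baskets(rng, n_agents=8, n_transactions=120)
        db = TransactionDB.from_baskets(baskets)
        m = cooccurrence_matrix(db, floor=1)
        df = m.to_frame(masked=False)
        mined = {
            fi.items: fi.n_ws
            for fi in mine_frequent_itemsets(
                db, MiningParams(min_support=1e-12, min_ws=1, max_len=2,
                                 denominator_kind="all_ws")
            )
        }
        for i, a in enumerate(m.agents):
            for b in m.agents[i + 1:]:
                assert df.loc[a, b] == mined.get((a, b), 0)
        # symmetry and dominance by diagonals
        arr = m.counts
        assert (arr == arr.T).all()
        diag = np.diag(arr)
        assert (arr <= np.minimum.outer(diag, diag) + 0).all()

    def test_heatmap_renders(self, table1_db, tmp_path):
        m = cooccurrence_matrix(table1_db, floor=1)
        out = tmp_path / "heat.png"
        m.plot(out)
        assert out.stat().st_size > 0
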
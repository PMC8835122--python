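"""End-to-end orchestration: records -> transactions -> itemsets -> rules ->
subanalyses, with a run manifest for provenance.

The analysis path holds no randomness (only the synthetic generator does),
so a rerun on the same inputs and config produces a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .fim import (
    effective_threshold,
    itemsets_to_frame,
    mine_frequent_itemsets,
    top_k_itemsets,
)
from .records import apply_inclusion_filters, read_catalog, read_records
from .rules import mine_rules, rank_rules, rules_to_frame
from .report import format_rule_table
from .subanalyses import (
    cooccurrence_matrix,
    restrict_to_carcinogens,
    stratified_mining,
)
from .transactions import build_transactions, export_basket, export_long, summarize_coexposure

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``; any stage failure aborts with a stage-tagged error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "coexmine",
        "version": __version__,
        "input_hashes": {
            "records": _sha256(Path(config.records_path)),
            "catalog": _sha256(Path(config.catalog_path)),
        },
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # tag failures with the stage
                (out / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # --- records ---
    @stage("records")
    def _records():
        catalog = read_catalog(config.catalog_path)
        recs, rejects = read_records(config.records_path, config.schema)
        retained, audit = apply_inclusion_filters(recs, catalog, config.filters)
        rejects.to_csv(out / "rejects.csv", index=False)
        audit.to_frame().to_csv(out / "filter_audit.csv", index=False)
        return catalog, recs, retained

    catalog, raw_records, retained = _records

    # --- transactions ---
    @stage("transactions")
    def _transactions():
        db = build_transactions(retained)
        export_long(db, out / "transactions_long.csv")
        export_basket(db, out / "transactions_basket.txt")
        per_agent, dist = summarize_coexposure(db, catalog, retained)
        per_agent.to_csv(out / "coexposure_by_agent.csv", index=False)
        return db, dist

    db, dist = _transactions

    manifest.update(
        {
            "n_records_input": len(raw_records),
            "n_records_retained": len(retained),
            "n_agents_retained": len(db.universe),
            "n_ws": db.n_total,
            "n_multi_agent_ws": db.n_multi,
            "median_agents_per_ws": dist["median_agents_per_ws"],
            "iqr_agents_per_ws": list(dist["iqr_agents_per_ws"]),
            "max_agents_per_ws": dist["max_agents_per_ws"],
        }
    )

    # --- frequent itemsets ---
    @stage("itemsets")
    def _itemsets():
        itemsets = mine_frequent_itemsets(db, config.mining)
        itemsets_to_frame(itemsets).to_csv(out / "frequent_itemsets.csv", index=False)
        top_k_itemsets(itemsets, config.report_top_k, db).to_csv(
            out / "itemsets_top.csv", index=False
        )
        by_len = []
        for n_items in (3, 4, 5):
            sub = [fi for fi in itemsets if len(fi.items) == n_items]
            t = top_k_itemsets(sub, 5, db, min_items=n_items)
            t.insert(0, "n_items_group", n_items)
            by_len.append(t)
        pd.concat(by_len, ignore_index=True).to_csv(
            out / "itemsets_by_length.csv", index=False
        )
        return itemsets

    itemsets = _itemsets
    manifest["n_frequent_itemsets"] = len(itemsets)
    denom = db.n_multi if config.mining.denominator_kind == "multi_agent_ws" else db.n_total
    manifest["itemset_threshold_ws"] = effective_threshold(config.mining, denom)

    # --- association rules ---
    @stage("rules")
    def _rules():
        rules = mine_rules(db, config.rules, itemsets=itemsets)
        rules_to_frame(rules).to_csv(out / "rules.csv", index=False)
        by_conf = rank_rules(
            rules, "confidence", config.report_min_support_confidence,
            config.report_top_k,
        )
        by_lift = rank_rules(
            rules, "lift", config.report_min_support_lift, config.report_top_k
        )
        by_conf.to_csv(out / "rules_by_confidence.csv", index=False)
        by_lift.to_csv(out / "rules_by_lift.csv", index=False)
        format_rule_table(by_conf).to_csv(
            out / "rules_by_confidence_display.csv", index=False
        )
        format_rule_table(by_lift).to_csv(
            out / "rules_by_lift_display.csv", index=False
        )
        return rules

    rules = _rules
    manifest["n_rules"] = len(rules)

    # --- carcinogen restriction ---
    @stage("carcinogens")
    def _carcinogens():
        if not catalog.carcinogens:
            return None
        cdb = restrict_to_carcinogens(db, catalog)
        c_itemsets = mine_frequent_itemsets(cdb, config.mining)
        top_k_itemsets(c_itemsets, config.report_top_k, cdb).to_csv(
            out / "carcinogen_itemsets_top.csv", index=False
        )
        matrix = cooccurrence_matrix(
            cdb,
            floor=config.cooccurrence.floor,
            exclude=config.cooccurrence.exclude,
        )
        matrix.write(out / "cooccurrence.csv")
        try:
            matrix.plot(out / "cooccurrence.png")
        except Exception:
            pass  # headless rendering issues never fail the run
        return cdb

    cdb = _carcinogens
    manifest["n_ws_carcinogen"] = cdb.n_total if cdb is not None else 0
    manifest["n_multi_carcinogen_ws"] = cdb.n_multi if cdb is not None else 0

    # --- strata ---
    @stage("strata")
    def _strata():
        skipped_all = []
        for strat_by in ("sector", "task"):
            reports, skipped = stratified_mining(db, catalog, strat_by, config.strata)
            for code, rep in reports.items():
                rep.write(out / "strata" / strat_by / code)
            skipped_all.extend(skipped)
            manifest[f"n_{strat_by}_strata"] = len(reports)
        pd.DataFrame(
            skipped_all, columns=["stratum", "strat_by", "n_multi_agent_ws", "reason"]
        ).to_csv(out / "strata_skipped.csv", index=False)

    _strata

    dump_config(config, out / "resolved_config.yaml")
    manifest["config_hash"] = _sha256(out / "resolved_config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    incomplete = out / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return PipelineResult(out_dir=out, manifest=manifest)
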
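"""Record reading, validation, the detection predicate, and inclusion filters."""

from __future__ import annotations


import pytest

from coexmine import (
    AgentCatalog,
    CatalogEntry,
    FilterConfig,
    SchemaConfig,
    apply_inclusion_filters,
    flag_detected,
    read_catalog,
    read_records,
)
from coexmine.records import write_records

from conftest import make_record

HEADER = (
    "agent_id,sector_code,occupation_code,task_code,year,concentration,loq,source"
)


def _write(tmp_path, rows, name="records.csv", header=HEADER):
    path = tmp_path / name
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestReadRecords:
    def test_well_formed_file_yields_all_records_and_no_rejects(self, tmp_path):
        rows = [
            f"ag0{i},S1,O1,T1,2015,{i}.5,1.0,SRC_A" for i in range(1, 5)
        ]
        records, rejects = read_records(_write(tmp_path, rows))
        assert len(records) == 4
        assert rejects.empty
        assert records[0].concentration == 1.5
        assert records[0].loq == 1.0

    def test_unparseable_concentration_rejected_with_reason(self, tmp_path):
        rows = [
            "ag01,S1,O1,T1,2015,1.5,1.0,SRC_A",
            "ag02,S1,O1,T1,2015,abc,1.0,SRC_A",
            "ag03,S1,O1,T1,2015,2.5,1.0,SRC_A",
            "ag04,S1,O1,T1,2015,3.5,1.0,SRC_A",
        ]
        records, rejects = read_records(_write(tmp_path, rows))
        assert len(records) == 3
        assert rejects.to_dict("records") == [{"row": 2, "reason": "bad_numeric"}]

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("ag01,,O1,T1,2015,1.5,1.0,SRC_A", "missing_descriptor"),
            ("ag01,S1,O1,T1,late,1.5,1.0,SRC_A", "bad_year"),
            ("ag01,S1,O1,T1,2015,-1.0,1.0,SRC_A", "negative_concentration"),
            ("ag01,S1,O1,T1,2015,1.5,0.0,SRC_A", "nonpositive_loq"),
            (",S1,O1,T1,2015,1.5,1.0,SRC_A", "missing_agent"),
            ("ag01,S1,O1,T1,2015,1.5,1.0,", "missing_source"),
        ],
    )
    def test_malformed_rows_collected_not_dropped(self, tmp_path, row, reason):
        _, rejects = read_records(_write(tmp_path, [row]))
        assert list(rejects["reason"]) == [reason]

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("agent_id,year\na,2015\n")
        with pytest.raises(ValueError, match="missing mandatory columns"):
            read_records(path)

    def test_detected_flag_dialect(self, tmp_path):
        header = (
            "agent_id,sector_code,occupation_code,task_code,year,"
            "concentration,detected,source"
        )
        rows = ["ag01,S1,O1,T1,2015,1.5,true,SRC_A",
                "ag02,S1,O1,T1,2015,0.0,false,SRC_A"]
        schema = SchemaConfig(mode="flag")
        records, rejects = read_records(_write(tmp_path, rows, header=header), schema)
        assert rejects.empty
        assert [flag_detected(r) for r in records] == [True, False]

    def test_write_read_round_trip(self, tmp_path, rng):
        records = [
            make_record(
                agent=f"ag{rng.integers(9)}",
                year=int(rng.integers(2010, 2020)),
                concentration=float(rng.uniform(0, 10)),
                loq=float(rng.uniform(0.1, 2.0)),
                task=f"T{i}",
            )
            for i in range(1000)
        ]
        path = tmp_path / "round.csv"
        write_records(records, path)
        back, rejects = read_records(path)
        assert rejects.empty
        assert back == records


class TestFlagDetected:
    def test_above_loq_is_detected(self):
        assert flag_detected(make_record(concentration=5.0, loq=1.0))

    def test_exactly_at_loq_is_censored_by_default(self):
        # boundary is strict: "above the LOQ" means strictly above
        assert not flag_detected(make_record(concentration=1.0, loq=1.0))
        assert flag_detected(
            make_record(concentration=1.0, loq=1.0), detect_at_loq=True
        )

    def test_neither_loq_nor_flag_is_an_error(self):
        rec = make_record(loq=None, detected=None)
        with pytest.raises(ValueError, match="neither LOQ nor detected flag"):
            flag_detected(rec)


def _catalog(agents, excluded=(), reason="generic_dust"):
    return AgentCatalog(
        CatalogEntry(
            agent_id=a, name=a,
            excluded=a in excluded,
            exclusion_reason=reason if a in excluded else None,
        )
        for a in agents
    )


class TestInclusionFilters:
    def test_min_count_boundary_99_removed_100_kept(self):
        records = [make_record(agent="X", task=f"T{i}") for i in range(99)]
        records += [make_record(agent="Y", task=f"T{i}") for i in range(100)]
        retained, audit = apply_inclusion_filters(
            records, _catalog({"X", "Y"}), FilterConfig()
        )
        assert {r.agent_id for r in retained} == {"Y"}
        stage = audit.to_frame().set_index("stage").loc["min_count_per_agent"]
        assert stage["agents_removed"] == "X"

    def test_catalog_excluded_agent_removed(self):
        records = [make_record(agent="inhalable dust"), make_record(agent="lead")]
        catalog = _catalog({"inhalable dust", "lead"}, excluded={"inhalable dust"})
        cfg = FilterConfig(min_detected_per_agent=1)
        retained, audit = apply_inclusion_filters(records, catalog, cfg)
        assert {r.agent_id for r in retained} == {"lead"}
        stage = audit.to_frame().set_index("stage").loc["agent_exclusions"]
        assert stage["agents_removed"] == "inhalable dust"

    def test_per_source_exclusion(self):
        records = [
            make_record(agent="asbestos", source="SRC_B"),
            make_record(agent="asbestos", source="SRC_A2", task="T2"),
        ]
        cfg = FilterConfig(
            min_detected_per_agent=1,
            agent_source_exclusions=[("asbestos", "SRC_B")],
        )
        retained, _ = apply_inclusion_filters(records, _catalog({"asbestos"}), cfg)
        assert len(retained) == 1
        assert retained[0].source == "SRC_A2"

    def test_year_window(self):
        records = [make_record(year=y, task=f"T{y}") for y in (2009, 2010, 2019, 2020)]
        cfg = FilterConfig(min_detected_per_agent=1)
        retained, _ = apply_inclusion_filters(records, _catalog({"ag01"}), cfg)
        assert sorted(r.year for r in retained) == [2010, 2019]

    def test_uncatalogued_agent_is_hard_error(self):
        with pytest.raises(ValueError, match="missing from the catalog"):
            apply_inclusion_filters([make_record(agent="mystery")], _catalog({"ag01"}))

    def test_retained_set_matches_brute_force_recount(self, rng):
        # independent recount: an agent survives iff its detected, in-window,
        # non-excluded record count reaches the floor
        agents = [f"ag{i}" for i in range(12)]
        records = []
        for i in range(2000):
            records.append(
                make_record(
                    agent=agents[int(rng.integers(12))],
                    year=int(rng.integers(2008, 2022)),
                    concentration=float(rng.uniform(0, 2.0)),
                    loq=1.0,
                    task=f"T{i}",
                )
            )
        cfg = FilterConfig(min_detected_per_agent=40)
        retained, audit = apply_inclusion_filters(records, _catalog(agents), cfg)

        counts: dict[str, int] = {}
        for r in records:
            if 2010 <= r.year <= 2019 and r.concentration > r.loq:
                counts[r.agent_id] = counts.get(r.agent_id, 0) + 1
        expected_agents = {a for a, n in counts.items() if n >= 40}
        assert {r.agent_id for r in retained} == expected_agents
        assert all(flag_detected(r) for r in retained)
        # audit counts sum per stage
        for stage in audit.stages:
            assert stage["n_in"] == stage["n_removed"] + stage["n_out"]

    def test_filtering_is_idempotent(self, rng):
        records = [
            make_record(
                agent=f"ag{int(rng.integers(5))}",
                concentration=float(rng.uniform(0, 3)),
                task=f"T{i}",
            )
            for i in range(500)
        ]
        cfg = FilterConfig(min_detected_per_agent=30)
        catalog = _catalog({f"ag{i}" for i in range(5)})
        once, _ = apply_inclusion_filters(records, catalog, cfg)
        twice, _ = apply_inclusion_filters(once, catalog, cfg)
        assert once == twice


def test_catalog_round_trip_and_reason_vocabulary(tmp_path):
    path = tmp_path / "catalog.csv"
    path.write_text(
        "agent_id,name,carcinogen,excluded,exclusion_reason\n"
        "lead,Lead,1,0,\n"
        "inh_dust,Inhalable dust,0,1,generic_dust\n"
    )
    catalog = read_catalog(path)
    assert catalog.carcinogens == {"lead"}
    assert catalog.excluded_agents == {"inh_dust": "generic_dust"}
    with pytest.raises(ValueError, match="exclusion reason"):
        CatalogEntry(agent_id="x", name="x", excluded=True, exclusion_reason="typo")
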
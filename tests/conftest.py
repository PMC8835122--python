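from __future__ import annotations

import numpy as np
import pytest

from coexmine import (
    AgentCatalog,
    CatalogEntry,
    MeasurementRecord,
    TransactionDB,
)

TABLE1_BASKETS = [
    {"asbestos", "lead"},
    {"wood dust"},
    {"benzene", "ethanol", "lead"},
    {"asbestos", "chromium", "lead"},
]


@pytest.fixture
def table1_db() -> TransactionDB:
    """The four-WS pedagogical transaction database."""
    return TransactionDB.from_baskets(TABLE1_BASKETS)


@pytest.fixture
def table1_catalog() -> AgentCatalog:
    carcinogens = {"asbestos", "benzene", "lead", "chromium"}
    agents = {"asbestos", "lead", "wood dust", "benzene", "ethanol", "chromium"}
    return AgentCatalog(
        CatalogEntry(agent_id=a, name=a, carcinogen=a in carcinogens)
        for a in sorted(agents)
    )


def make_record(
    agent="ag01",
    sector="S1",
    occupation="O1",
    task="T1",
    year=2015,
    concentration=5.0,
    loq=1.0,
    detected=None,
    source="SRC_A",
) -> MeasurementRecord:
    return MeasurementRecord(
        agent_id=agent,
        sector_code=sector,
        occupation_code=occupation,
        task_code=task,
        year=year,
        concentration=concentration,
        loq=loq,
        detected=detected,
        source=source,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210131)
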
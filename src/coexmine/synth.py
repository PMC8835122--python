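"""Synthetic occupational-exposure corpora with known ground truth.

The real exposure databases this pipeline targets are not public, so the
generator emulates their record structure with a planted mixture process:

* A small set of *process profiles* (think "aromatic solvent degreasing",
  "arc welding fume", "stone cutting") each carries a set of agents with
  per-agent emission probabilities, pools of sector/occupation/task codes,
  and a relative weight.
* Each work situation (WS) draws a profile by weight and a distinct
  (sector, occupation, task, year) key from the profile's pools.
* Each agent of the profile is emitted in that WS independently with its
  emission probability; an emitted (WS, agent) pair yields a small number
  of measurement records (geometric, mean ``mean_records``).
* Each record is censored independently with probability ``censor_prob``:
  concentration and LOQ are constructed so that the below-LOQ probability
  equals ``censor_prob`` exactly, keeping the pipeline's detection
  predicate (concentration strictly above LOQ) the single source of truth.

Everything is deterministic given the config seed.  Because emissions and
censoring are independent across agents within a profile, the WS-level
probability that an itemset is fully detected has a closed form
(:func:`expected_support`), which the mining tests use as their recovery
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import AgentCatalog, CatalogEntry, MeasurementRecord, write_records
from .transactions import Transaction, TransactionDB, WorkSituationKey

__all__ = [
    "ProcessProfile",
    "SynthConfig",
    "SyntheticTruth",
    "default_config",
    "generate",
    "generate_transactions",
    "make_catalog",
    "detection_prob",
    "expected_support",
    "planted_itemsets",
]


@dataclass(frozen=True)
class ProcessProfile:
    """A recurring workplace process emitting a characteristic agent mixture."""

    profile_id: str
    emissions: dict[str, float]  # agent_id -> emission probability in (0, 1]
    sectors: tuple[str, ...]
    occupations: tuple[str, ...]
    tasks: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if not self.emissions:
            raise ValueError(f"profile {self.profile_id}: empty emission set")
        for a, p in self.emissions.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(
                    f"profile {self.profile_id}: emission probability for {a} "
                    f"must lie in (0, 1], got {p}"
                )
        if self.weight <= 0:
            raise ValueError(f"profile {self.profile_id}: weight must be positive")


@dataclass
class SynthConfig:
    """Generator parameters; fully deterministic given ``seed``."""

    n_ws: int = 5000
    profiles: tuple[ProcessProfile, ...] = ()
    censor_prob: float = 0.48      # record-level below-LOQ probability
    mean_records: float = 3.0      # mean records per emitted (WS, agent)
    year_min: int = 2010
    year_max: int = 2019
    sources: tuple[str, ...] = ("SYNTH_A", "SYNTH_B")
    source_probs: tuple[float, ...] = (0.7, 0.3)
    seed: int = 1
    carcinogen_agents: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_ws < 1:
            raise ValueError("n_ws must be >= 1")
        if not self.profiles:
            raise ValueError("at least one process profile is required")
        if not (0.0 <= self.censor_prob <= 1.0):
            raise ValueError("censor_prob must lie in [0, 1]")
        if self.mean_records < 1.0:
            raise ValueError("mean_records must be >= 1")
        total = sum(p.weight for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile weights must sum to 1, got {total}")

    @property
    def agents(self) -> tuple[str, ...]:
        out: set[str] = set()
        for p in self.profiles:
            out |= set(p.emissions)
        return tuple(sorted(out))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated corpus: the WS -> profile assignment and
    the analytic detection/support probabilities."""

    seed: int
    assignments: pd.DataFrame  # ws_index, profile_id, sector, occupation, task, year
    agent_detection: dict[str, float]   # WS-level marginal detection prob
    itemset_expectation: dict[tuple[str, ...], float]

    def write(self, path: str | Path) -> None:
        self.assignments.to_csv(path, index=False)


def detection_prob(config: SynthConfig) -> float:
    """WS-level probability that an emitted agent is detected at least once.

    Records per emitted (WS, agent) are geometric on {1, 2, ...} with mean
    m (success probability 1/m); each record clears the LOQ independently
    with probability 1 - c.  Marginalizing the record count K:

        P(detected) = 1 - E[c^K] = 1 - c(1/m) / (1 - c(1 - 1/m)).
    """
    c = config.censor_prob
    q = 1.0 / config.mean_records
    if c == 0.0:
        return 1.0
    return 1.0 - (c * q) / (1.0 - c * (1.0 - q))


def expected_support(itemset: Iterable[str], config: SynthConfig) -> float:
    """Closed-form WS-level probability that all agents of *itemset* are
    detected in a random WS: the profile-weight mixture of per-profile
    products of emission x detection probabilities."""
    items = tuple(sorted(set(itemset)))
    if not items:
        raise ValueError("empty itemset")
    d = detection_prob(config)
    total = 0.0
    for p in config.profiles:
        prob = 1.0
        for a in items:
            if a not in p.emissions:
                prob = 0.0
                break
            prob *= p.emissions[a] * d
        total += p.weight * prob
    return total


def planted_itemsets(
    config: SynthConfig, min_size: int = 2, max_size: int | None = None
) -> list[tuple[str, ...]]:
    """All size->=2 subsets of every profile's emission set (deduplicated):
    the itemsets the generator deliberately plants."""
    from itertools import combinations

    out: set[tuple[str, ...]] = set()
    for p in config.profiles:
        agents = sorted(p.emissions)
        top = max_size or len(agents)
        for r in range(min_size, min(top, len(agents)) + 1):
            out.update(combinations(agents, r))
    return sorted(out)


def _draw_key(
    rng: np.random.Generator,
    profile: ProcessProfile,
    config: SynthConfig,
    used: set[WorkSituationKey],
) -> WorkSituationKey:
    # WS keys must be distinct or grouping would merge them; rejection-sample
    # within the profile's code pools
    for _ in range(10_000):
        key = WorkSituationKey(
            sector_code=profile.sectors[rng.integers(len(profile.sectors))],
            occupation_code=profile.occupations[rng.integers(len(profile.occupations))],
            task_code=profile.tasks[rng.integers(len(profile.tasks))],
            year=int(rng.integers(config.year_min, config.year_max + 1)),
        )
        if key not in used:
            used.add(key)
            return key
    raise RuntimeError(
        f"profile {profile.profile_id}: key pools too small for the requested "
        f"number of distinct WS"
    )


def generate(
    config: SynthConfig,
    records_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[MeasurementRecord], SyntheticTruth]:
    """Generate a full record-level corpus (and optionally write it).

    The records file is in the exact input dialect of the reader; rerunning
    with the same config (incl. seed) reproduces byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([p.weight for p in config.profiles])
    q = 1.0 / config.mean_records
    c = config.censor_prob
    # fixed per-agent LOQ scales, drawn once (units are opaque to the pipeline)
    agents = config.agents
    loq_scale = {a: float(10.0 ** rng.uniform(-2, 1)) for a in agents}

    used_keys: set[WorkSituationKey] = set()
    records: list[MeasurementRecord] = []
    assign_rows = []
    for ws_index in range(config.n_ws):
        profile = config.profiles[rng.choice(len(config.profiles), p=weights)]
        key = _draw_key(rng, profile, config, used_keys)
        assign_rows.append(
            {
                "ws_index": ws_index,
                "profile_id": profile.profile_id,
                "sector_code": key.sector_code,
                "occupation_code": key.occupation_code,
                "task_code": key.task_code,
                "year": key.year,
            }
        )
        for agent in sorted(profile.emissions):
            if rng.random() >= profile.emissions[agent]:
                continue
            k = int(rng.geometric(q))
            loq = loq_scale[agent]
            for _ in range(k):
                u = rng.random()
                if u < c:  # censored: concentration strictly below loq
                    conc = loq * (u / c if c > 0 else 0.0)
                else:      # detected: concentration strictly above loq
                    conc = loq * (1.0 + 1e-6 + 9.0 * (u - c) / (1.0 - c))
                source = config.sources[
                    rng.choice(len(config.sources), p=np.array(config.source_probs))
                ]
                records.append(
                    MeasurementRecord(
                        agent_id=agent,
                        sector_code=key.sector_code,
                        occupation_code=key.occupation_code,
                        task_code=key.task_code,
                        year=key.year,
                        concentration=conc,
                        loq=loq,
                        detected=None,
                        source=source,
                    )
                )

    truth = SyntheticTruth(
        seed=config.seed,
        assignments=pd.DataFrame(assign_rows),
        agent_detection={
            a: detection_prob(config) for a in agents
        },
        itemset_expectation={
            its: expected_support(its, config) for its in planted_itemsets(config)
        },
    )
    if records_path is not None:
        write_records(records, records_path)
    if truth_path is not None:
        truth.write(truth_path)
    return records, truth


def generate_transactions(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> TransactionDB:
    """WS-level fast path: draw detected agent sets directly.

    Each agent of the drawn profile enters the WS's transaction with
    probability emission x detection_prob — the same WS-level law as the
    record-level generator, without materializing individual records.
    Intended for Monte-Carlo studies with many replicates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    weights = np.array([p.weight for p in config.profiles])
    d = detection_prob(config)
    used: set[WorkSituationKey] = set()
    txs = []
    for _ in range(config.n_ws):
        profile = config.profiles[rng.choice(len(config.profiles), p=weights)]
        key = _draw_key(rng, profile, config, used)
        agents = frozenset(
            a for a, p in sorted(profile.emissions.items()) if rng.random() < p * d
        )
        if agents:
            txs.append(
                Transaction(
                    key=key, agents=agents, n_records=len(agents),
                    sources=frozenset({config.sources[0]}),
                )
            )
    return TransactionDB(transactions=tuple(sorted(txs, key=lambda t: t.key)))


def make_catalog(config: SynthConfig) -> AgentCatalog:
    """Catalog matching the generated corpus, with carcinogen flags from
    ``config.carcinogen_agents`` and no excluded agents."""
    return AgentCatalog(
        CatalogEntry(
            agent_id=a,
            name=a.replace("_", " "),
            carcinogen=a in config.carcinogen_agents,
        )
        for a in config.agents
    )


def _profile(
    pid: str, agents: Sequence[str], probs: Sequence[float], weight: float,
    sector_base: int, n_sectors: int = 4,
) -> ProcessProfile:
    sectors = tuple(f"S{sector_base + i:02d}" for i in range(n_sectors))
    occupations = tuple(f"O{sector_base * 10 + i:03d}" for i in range(30))
    tasks = tuple(f"T{sector_base * 10 + i:03d}" for i in range(12))
    return ProcessProfile(
        profile_id=pid,
        emissions=dict(zip(agents, probs)),
        sectors=sectors,
        occupations=occupations,
        tasks=tasks,
        weight=weight,
    )


def default_config(seed: int = 1, n_ws: int = 5000) -> SynthConfig:
    """Default study conditions: 5,000 WS, 30 agents, 8 process profiles,
    48 % record-level censoring, years 2010-2019.

    Profiles mimic recurring industrial mixtures (solvent blends, welding
    metals, silica dusts, aldehydes...); one deliberately rare profile
    (weight 1 %) plants a mixture whose expected support falls below the
    usual mining thresholds.  Agents of the metal, silica and aldehyde
    profiles are flagged as carcinogens in the generated catalog.
    """
    profiles = (
        _profile("aromatic_solvents", ["ag01", "ag02", "ag03", "ag04"],
                 [0.90, 0.85, 0.80, 0.60], 0.18, 1),
        _profile("welding_metals", ["ag05", "ag06", "ag07", "ag08", "ag09"],
                 [0.90, 0.85, 0.80, 0.70, 0.50], 0.17, 2),
        _profile("silica_dusts", ["ag10", "ag11"],
                 [0.95, 0.90], 0.15, 3),
        _profile("ketone_blend", ["ag01", "ag12", "ag13", "ag14"],
                 [0.55, 0.90, 0.80, 0.70], 0.14, 4),
        _profile("degreasing", ["ag15", "ag16", "ag17", "ag18"],
                 [0.85, 0.80, 0.70, 0.55], 0.13, 5),
        _profile("plating_bath", ["ag19", "ag20", "ag21", "ag22"],
                 [0.90, 0.75, 0.65, 0.50], 0.12, 6),
        _profile("spray_coating", ["ag23", "ag24", "ag25", "ag26"],
                 [0.85, 0.75, 0.60, 0.45], 0.10, 7),
        _profile("rare_sterilant", ["ag27", "ag28", "ag29", "ag30"],
                 [0.30, 0.30, 0.25, 0.20], 0.01, 8),
    )
    carcinogens = frozenset(
        {"ag05", "ag06", "ag07", "ag08", "ag09", "ag10", "ag11", "ag27", "ag28"}
    )
    return SynthConfig(
        n_ws=n_ws, profiles=profiles, censor_prob=0.48, mean_records=3.0,
        seed=seed, carcinogen_agents=carcinogens,
    )
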
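"""Run configuration: schema mapping, filter/mining/rule/stratum parameters.

One YAML file drives a whole pipeline run.  Every block has defaults that
reproduce the headline parameterization of the analysis (minimum support
0.1 %, minimum confidence 10 %, stratum floor max(0.1 % of stratum, 10 WS),
stratum qualification at 100 multi-agent WS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Closed vocabulary for agent-catalog exclusion reasons.
EXCLUSION_REASONS = frozenset(
    {"generic_dust", "duplicate_indicator", "source_specific", "other"}
)

DENOMINATOR_KINDS = ("all_ws", "multi_agent_ws")


@dataclass
class SchemaConfig:
    """Column mapping for a delimited records file.

    ``mode`` declares how quantification status is encoded: ``"loq"`` means a
    numeric limit-of-quantification column is present, ``"flag"`` means a
    boolean detected column.  Exactly one of the two forms per file.
    """

    agent_id: str = "agent_id"
    sector_code: str = "sector_code"
    occupation_code: str = "occupation_code"
    task_code: str = "task_code"
    year: str = "year"
    concentration: str = "concentration"
    loq: str = "loq"
    detected: str = "detected"
    source: str = "source"
    mode: str = "loq"  # "loq" | "flag"

    def __post_init__(self) -> None:
        if self.mode not in ("loq", "flag"):
            raise ValueError(f"schema mode must be 'loq' or 'flag', got {self.mode!r}")


@dataclass
class FilterConfig:
    """Inclusion/exclusion rules applied to validated records.

    Filter order is fixed: year window -> agent/source exclusions ->
    detected-only -> minimum detected-sample count per agent.
    """

    year_min: int = 2010
    year_max: int = 2019
    min_detected_per_agent: int = 100
    #: (agent_id, source) pairs excluded, e.g. asbestos measurements from one
    #: source whose task descriptor is unreliable.
    agent_source_exclusions: list[tuple[str, str]] = field(default_factory=list)
    #: Whether a concentration exactly equal to the LOQ counts as detected.
    #: Default False: only strictly-above-LOQ measurements are "detected".
    detect_at_loq: bool = False


@dataclass
class MiningParams:
    """Frequent-itemset mining thresholds.

    The effective absolute threshold is ``max(ceil(min_support * denominator),
    min_ws)`` work situations.
    """

    min_support: float = 0.001
    min_ws: int = 1
    max_len: int | None = None
    denominator_kind: str = "multi_agent_ws"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError("min_support must lie in (0, 1]")
        if self.min_ws < 1:
            raise ValueError("min_ws must be >= 1")
        if self.denominator_kind not in DENOMINATOR_KINDS:
            raise ValueError(f"unknown denominator_kind {self.denominator_kind!r}")


@dataclass
class RuleParams:
    """Association-rule mining thresholds (support floor as MiningParams,
    plus a confidence floor applied to confidence(A -> C) only)."""

    min_support: float = 0.001
    min_ws: int = 1
    min_confidence: float = 0.10
    max_len: int | None = None
    denominator_kind: str = "multi_agent_ws"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must lie in [0, 1]")

    def mining_params(self) -> MiningParams:
        return MiningParams(
            min_support=self.min_support,
            min_ws=self.min_ws,
            max_len=self.max_len,
            denominator_kind=self.denominator_kind,
        )


@dataclass
class StrataParams:
    """Sector/task stratification rules: a stratum qualifies with at least
    ``min_stratum_ws`` multi-agent WS; its support floor is
    ``max(ceil(stratum_min_support * n_ws), min_ws_floor)``."""

    min_stratum_ws: int = 100
    stratum_min_support: float = 0.001
    min_ws_floor: int = 10
    min_confidence: float = 0.10
    top_k: int = 10


@dataclass
class CooccurParams:
    floor: int = 10
    exclude: list[str] = field(default_factory=list)
    carcinogens_only: bool = True


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    records_path: str = ""
    catalog_path: str = ""
    out_dir: str = "coexmine_out"
    seed: int = 1
    schema: SchemaConfig = field(default_factory=SchemaConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    mining: MiningParams = field(default_factory=MiningParams)
    rules: RuleParams = field(default_factory=RuleParams)
    strata: StrataParams = field(default_factory=StrataParams)
    cooccurrence: CooccurParams = field(default_factory=CooccurParams)
    report_top_k: int = 10
    report_min_support_confidence: float = 0.05
    report_min_support_lift: float = 0.01

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["filters"]["agent_source_exclusions"] = [
            list(t) for t in self.filters.agent_source_exclusions
        ]
        return d


def _build(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data)
    kwargs: dict[str, Any] = {}
    for key, cls in (
        ("schema", SchemaConfig),
        ("filters", FilterConfig),
        ("mining", MiningParams),
        ("rules", RuleParams),
        ("strata", StrataParams),
        ("cooccurrence", CooccurParams),
    ):
        if key in data:
            kwargs[key] = _build(cls, data.pop(key))
    if "filters" in kwargs:
        kwargs["filters"].agent_source_exclusions = [
            tuple(t) for t in kwargs["filters"].agent_source_exclusions
        ]
    kwargs.update(data)
    return _build(RunConfig, {**{k: v for k, v in kwargs.items()}})


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
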
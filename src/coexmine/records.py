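"""Reading, validation and filtering of personal air-measurement records.

A record is one personal air sample: which agent was measured, where
(industrial sector / occupation / task codes, treated as opaque tokens),
when (calendar year), the measured concentration and either a limit of
quantification (LOQ) or a pre-computed detected flag, and a source tag for
the originating database.

Censoring is decided in exactly one place, :func:`flag_detected`: a
measurement counts as detected only if its concentration is strictly above
the LOQ (a value exactly at the LOQ is censored; configurable).

Filtering follows a fixed, audited order:

1. calendar-year window (study period),
2. catalog-level agent exclusions and per-(agent, source) exclusions,
3. detected-only restriction,
4. minimum number of detected samples per agent over the pooled corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import EXCLUSION_REASONS, FilterConfig, SchemaConfig

__all__ = [
    "MeasurementRecord",
    "CatalogEntry",
    "AgentCatalog",
    "FilterAudit",
    "read_records",
    "read_catalog",
    "flag_detected",
    "apply_inclusion_filters",
]


@dataclass(frozen=True, slots=True)
class MeasurementRecord:
    """One personal air sample with its descriptive codes."""

    agent_id: str
    sector_code: str
    occupation_code: str
    task_code: str
    year: int
    concentration: float
    loq: float | None
    detected: bool | None
    source: str


@dataclass(frozen=True)
class CatalogEntry:
    agent_id: str
    name: str
    carcinogen: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.excluded:
            if self.exclusion_reason not in EXCLUSION_REASONS:
                raise ValueError(
                    f"agent {self.agent_id!r}: exclusion reason "
                    f"{self.exclusion_reason!r} not in {sorted(EXCLUSION_REASONS)}"
                )


class AgentCatalog:
    """Lookup table of agents: display name, carcinogen flag, exclusions."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.agent_id in self._entries:
                raise ValueError(f"duplicate catalog entry for {e.agent_id!r}")
            self._entries[e.agent_id] = e

    def __contains__(self, agent_id: str) -> bool:
        return agent_id in self._entries

    def __getitem__(self, agent_id: str) -> CatalogEntry:
        return self._entries[agent_id]

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def agent_ids(self) -> list[str]:
        return sorted(self._entries)

    @property
    def carcinogens(self) -> frozenset[str]:
        return frozenset(a for a, e in self._entries.items() if e.carcinogen)

    @property
    def excluded_agents(self) -> dict[str, str]:
        """agent_id -> exclusion reason, for catalog-excluded agents."""
        return {
            a: e.exclusion_reason or "other"
            for a, e in self._entries.items()
            if e.excluded
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "agent_id": e.agent_id,
                "name": e.name,
                "carcinogen": e.carcinogen,
                "excluded": e.excluded,
                "exclusion_reason": e.exclusion_reason or "",
            }
            for e in sorted(self._entries.values(), key=lambda e: e.agent_id)
        ]
        return pd.DataFrame(rows)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_catalog(path: str | Path) -> AgentCatalog:
    """Read an agent catalog from a delimited file.

    Required columns: agent_id, name, carcinogen, excluded; optional
    exclusion_reason (required for excluded agents).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    needed = {"agent_id", "name", "carcinogen", "excluded"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
    entries = []
    for values in df.itertuples(index=False, name=None):
        row = dict(zip(df.columns, values))
        entries.append(
            CatalogEntry(
                agent_id=str(row["agent_id"]).strip(),
                name=str(row["name"]).strip(),
                carcinogen=_parse_bool(row["carcinogen"]),
                excluded=_parse_bool(row["excluded"]),
                exclusion_reason=(
                    str(row.get("exclusion_reason", "")).strip() or None
                ),
            )
        )
    return AgentCatalog(entries)


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def read_records(
    path: str | Path, schema: SchemaConfig | None = None
) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Read and validate measurement records from a delimited file.

    Returns ``(records, rejects)`` where *rejects* is a table of malformed
    rows with 1-based data row numbers and a reason tag; malformed rows are
    never silently dropped.  A missing mandatory column is a hard error.
    """
    schema = schema or SchemaConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)

    needed = [schema.agent_id, schema.sector_code, schema.occupation_code,
              schema.task_code, schema.year, schema.concentration, schema.source]
    needed.append(schema.loq if schema.mode == "loq" else schema.detected)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} missing mandatory columns: {missing}")

    records: list[MeasurementRecord] = []
    rejects: list[dict] = []

    def reject(i: int, reason: str) -> None:
        rejects.append({"row": i + 1, "reason": reason})

    for i, values in enumerate(df.itertuples(index=False, name=None)):
        row = dict(zip(df.columns, values))
        agent = str(row[schema.agent_id]).strip()
        sector = str(row[schema.sector_code]).strip()
        occupation = str(row[schema.occupation_code]).strip()
        task = str(row[schema.task_code]).strip()
        if not agent:
            reject(i, "missing_agent")
            continue
        # a WS is defined by the full descriptor 4-tuple; rows missing any
        # descriptor cannot be assigned to a WS and are rejected outright
        if not (sector and occupation and task and str(row[schema.year]).strip()):
            reject(i, "missing_descriptor")
            continue
        try:
            year = int(str(row[schema.year]).strip())
        except ValueError:
            reject(i, "bad_year")
            continue
        try:
            conc = float(str(row[schema.concentration]).strip())
        except ValueError:
            reject(i, "bad_numeric")
            continue
        if not math.isfinite(conc) or conc < 0:
            reject(i, "negative_concentration")
            continue
        loq: float | None = None
        det: bool | None = None
        if schema.mode == "loq":
            try:
                loq = float(str(row[schema.loq]).strip())
            except ValueError:
                reject(i, "bad_numeric")
                continue
            if not math.isfinite(loq) or loq <= 0:
                reject(i, "nonpositive_loq")
                continue
        else:
            try:
                det = _parse_bool(row[schema.detected])
            except ValueError:
                reject(i, "bad_flag")
                continue
        source = str(row[schema.source]).strip()
        if not source:
            reject(i, "missing_source")
            continue
        records.append(
            MeasurementRecord(
                agent_id=agent, sector_code=sector, occupation_code=occupation,
                task_code=task, year=year, concentration=conc, loq=loq,
                detected=det, source=source,
            )
        )

    reject_df = pd.DataFrame(rejects, columns=["row", "reason"])
    return records, reject_df


def write_records(
    records: Sequence[MeasurementRecord],
    path: str | Path,
    schema: SchemaConfig | None = None,
) -> None:
    """Write records in the same dialect :func:`read_records` reads."""
    schema = schema or SchemaConfig()
    path = Path(path)
    rows = []
    for r in records:
        row = {
            schema.agent_id: r.agent_id,
            schema.sector_code: r.sector_code,
            schema.occupation_code: r.occupation_code,
            schema.task_code: r.task_code,
            schema.year: r.year,
            schema.concentration: repr(r.concentration),
            schema.source: r.source,
        }
        if schema.mode == "loq":
            row[schema.loq] = repr(r.loq)
        else:
            row[schema.detected] = str(bool(r.detected)).lower()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def flag_detected(record: MeasurementRecord, *, detect_at_loq: bool = False) -> bool:
    """Single source of truth for quantification status.

    True iff the concentration is strictly above the LOQ (>= when
    ``detect_at_loq``), or the record carries an explicit detected flag.
    """
    if record.loq is not None:
        if detect_at_loq:
            return record.concentration >= record.loq
        return record.concentration > record.loq
    if record.detected is not None:
        return bool(record.detected)
    raise ValueError(
        f"record for agent {record.agent_id!r} has neither LOQ nor detected flag"
    )


@dataclass
class FilterAudit:
    """Per-stage record/agent removal counts; rejected + retained = input at
    every stage."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, agents_removed: set[str]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "n_in": n_in,
                "n_removed": n_in - n_out,
                "n_out": n_out,
                "n_agents_removed": len(agents_removed),
                "agents_removed": ";".join(sorted(agents_removed)),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages,
            columns=["stage", "n_in", "n_removed", "n_out",
                     "n_agents_removed", "agents_removed"],
        )


def apply_inclusion_filters(
    records: Sequence[MeasurementRecord],
    catalog: AgentCatalog,
    filters: FilterConfig | None = None,
) -> tuple[list[MeasurementRecord], FilterAudit]:
    """Apply the study's inclusion rules in fixed order and audit each stage.

    Returns the retained (detected-only) records and a :class:`FilterAudit`.
    Every agent appearing in the input must have a catalog entry.
    """
    filters = filters or FilterConfig()
    audit = FilterAudit()

    uncatalogued = {r.agent_id for r in records} - set(catalog.agent_ids)
    if uncatalogued:
        raise ValueError(
            f"records reference agents missing from the catalog: "
            f"{sorted(uncatalogued)[:10]}"
        )

    # 1. study-period year window
    stage_in = list(records)
    kept = [r for r in stage_in if filters.year_min <= r.year <= filters.year_max]
    audit.add(
        "year_window", len(stage_in), len(kept),
        {r.agent_id for r in stage_in} - {r.agent_id for r in kept},
    )

    # 2. catalog exclusions + per-(agent, source) exclusions
    stage_in = kept
    excluded = catalog.excluded_agents
    pair_excl = set(filters.agent_source_exclusions)
    kept = [
        r
        for r in stage_in
        if r.agent_id not in excluded and (r.agent_id, r.source) not in pair_excl
    ]
    audit.add(
        "agent_exclusions", len(stage_in), len(kept),
        {r.agent_id for r in stage_in} - {r.agent_id for r in kept},
    )

    # 3. detected-only (strictly above LOQ)
    stage_in = kept
    kept = [
        r for r in stage_in
        if flag_detected(r, detect_at_loq=filters.detect_at_loq)
    ]
    audit.add(
        "detected_only", len(stage_in), len(kept),
        {r.agent_id for r in stage_in} - {r.agent_id for r in kept},
    )

    # 4. minimum detected-sample count per agent (pooled over sources)
    stage_in = kept
    counts: dict[str, int] = {}
    for r in stage_in:
        counts[r.agent_id] = counts.get(r.agent_id, 0) + 1
    rare = {a for a, n in counts.items() if n < filters.min_detected_per_agent}
    kept = [r for r in stage_in if r.agent_id not in rare]
    audit.add("min_count_per_agent", len(stage_in), len(kept), rare)

    return kept, audit
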
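"""Domain types for biomedical records, users and valuation configuration.

A biomedical record is reduced to the triplet ``(type, time, quality)``:
``type`` is a categorical key into a registry of record-type specifications,
``time`` is the patient's age at sampling in years, and ``quality`` is a
nonnegative scalar.  The registry attaches to each type a base value and a
half-life — the time scale over which the record retains half of its
relevance (a genome never decays; a cholesterol panel decays on a
five-year scale).  Everything here is metadata: record payloads are opaque
and never enter the valuation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .exceptions import ConfigError, RecordParseError

__all__ = [
    "BiomedicalRecord",
    "RecordTypeSpec",
    "UserProfile",
    "Dataset",
    "ValuationConfig",
    "MarketplaceParams",
    "load_valuation_config",
    "read_records",
    "write_records",
]

KERNELS = ("half_life_exp", "one_sided_exp", "rectangular")
QUALITY_AGGREGATORS = ("reciprocal_sum", "min")
GROUP_GROWTH_FORMS = ("k_log_k", "k_pow_3_2")

RECORD_COLUMNS = ["record_id", "owner_id", "type", "time", "quality"]


@dataclass(frozen=True)
class BiomedicalRecord:
    """One record: an opaque payload summarised by (type, time, quality).

    ``time`` is the sampling age of the patient in years (sampling date
    minus date of birth); ``quality`` is a dimensionless nonnegative
    scalar.  Records with quality 0 are valid but worthless.
    """

    record_id: str
    owner_id: str
    type: str
    time: float
    quality: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"record {self.record_id}: time must be >= 0, got {self.time}")
        if self.quality < 0:
            raise ValueError(
                f"record {self.record_id}: quality must be >= 0, got {self.quality}"
            )


@dataclass(frozen=True)
class RecordTypeSpec:
    """Valuation parameters of one record type.

    ``base_value`` is the type's base worth in LifePounds; ``half_life``
    (years) sets the decay scale of its time value, with ``math.inf``
    meaning static data whose time value is identically 1.
    ``kernel_offset`` shifts the decay kernel along the time axis.
    """

    type_key: str
    base_value: float
    half_life: float = math.inf
    kernel_offset: float = 0.0
    kernel: str = "half_life_exp"
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.base_value > 0:
            raise ConfigError(f"type {self.type_key}: base_value must be > 0")
        if not self.half_life > 0:
            raise ConfigError(f"type {self.type_key}: half_life must be > 0")
        if self.kernel not in KERNELS:
            raise ConfigError(f"type {self.type_key}: unknown kernel {self.kernel!r}")

    @property
    def is_static(self) -> bool:
        return math.isinf(self.half_life)


@dataclass
class UserProfile:
    """Platform user; ``base_value_modifier`` scales all of their base values."""

    user_id: str
    current_age: float = 0.0
    sex: str = "unknown"
    ethnicity: str = "unknown"
    blood_type: str = "unknown"
    attributes: dict = field(default_factory=dict)
    base_value_modifier: float = 1.0

    def __post_init__(self) -> None:
        if not self.base_value_modifier > 0:
            raise ValueError(f"user {self.user_id}: base_value_modifier must be > 0")


class Dataset:
    """A collection of records with unique record ids, indexed by owner."""

    def __init__(self, records: Iterable[BiomedicalRecord] = ()) -> None:
        self._records: dict[str, BiomedicalRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: BiomedicalRecord) -> None:
        if rec.record_id in self._records:
            raise RecordParseError(f"duplicate record_id {rec.record_id!r}")
        self._records[rec.record_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[BiomedicalRecord]:
        return iter(self._records.values())

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __getitem__(self, record_id: str) -> BiomedicalRecord:
        return self._records[record_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self._records == other._records

    @property
    def record_ids(self) -> set[str]:
        return set(self._records)

    @property
    def owner_ids(self) -> set[str]:
        return {r.owner_id for r in self}

    def by_owner(self) -> dict[str, list[BiomedicalRecord]]:
        out: dict[str, list[BiomedicalRecord]] = {}
        for rec in self:
            out.setdefault(rec.owner_id, []).append(rec)
        return out

    def subset(self, record_ids: Iterable[str]) -> "Dataset":
        return Dataset(self._records[rid] for rid in record_ids)

    def union(self, other: "Dataset") -> "Dataset":
        """Union by record_id; conflicting duplicate ids raise."""
        merged = Dataset(self)
        for rec in other:
            if rec.record_id in merged:
                if merged[rec.record_id] != rec:
                    raise RecordParseError(
                        f"record_id {rec.record_id!r} present in both datasets "
                        "with conflicting fields"
                    )
            else:
                merged.add(rec)
        return merged

    def max_time(self) -> float:
        return max((r.time for r in self), default=0.0)


@dataclass
class MarketplaceParams:
    """Blockchain-wide marketplace parameters carried inside the config file."""

    dv_share: float = 0.1
    validation_timeout: int = 10
    mint_on_upload: bool = False
    mint_amount: float = 0.0
    n_keepers: int = 4
    threshold: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.dv_share < 1:
            raise ConfigError(f"dv_share must be in [0, 1), got {self.dv_share}")


@dataclass
class ValuationConfig:
    """Everything the cost model needs beyond the records themselves.

    The synergy table maps type multisets (size >= 2) to the interaction
    base value of that combination; multisets absent from the table carry
    zero interaction value, which keeps the subset enumeration sparse.
    """

    type_registry: dict[str, RecordTypeSpec]
    synergy_table: dict[tuple[str, ...], float] = field(default_factory=dict)
    quality_aggregator: str = "reciprocal_sum"
    group_growth_form: str = "k_log_k"
    group_growth_c: float = 1.0
    max_combination_order: int = 4
    enumeration_cap: int = 64
    relationship_regularization: bool = True
    critical_representative_level: float = 0.0
    marketplace: MarketplaceParams = field(default_factory=MarketplaceParams)

    def __post_init__(self) -> None:
        if self.max_combination_order < 1:
            raise ConfigError("max_combination_order must be >= 1")
        if not self.group_growth_c > 0:
            raise ConfigError("group growth constant C must be > 0")
        if self.quality_aggregator not in QUALITY_AGGREGATORS:
            raise ConfigError(f"unknown quality_aggregator {self.quality_aggregator!r}")
        if self.group_growth_form not in GROUP_GROWTH_FORMS:
            raise ConfigError(f"unknown group_growth form {self.group_growth_form!r}")
        normalized: dict[tuple[str, ...], float] = {}
        for key, value in self.synergy_table.items():
            key = tuple(sorted(key))
            if len(key) < 2:
                raise ConfigError(f"synergy key {key} must contain >= 2 types")
            if not value > 0:
                raise ConfigError(f"synergy value for {key} must be > 0, got {value}")
            for t in key:
                if t not in self.type_registry:
                    raise ConfigError(f"synergy table references unknown type {t!r}")
            normalized[key] = float(value)
        self.synergy_table = normalized

    def spec_for(self, type_key: str) -> RecordTypeSpec:
        from .exceptions import UnregisteredTypeError

        try:
            return self.type_registry[type_key]
        except KeyError:
            raise UnregisteredTypeError(f"record type {type_key!r} not in registry") from None

    def synergy_value(self, types: Iterable[str]) -> float:
        """Interaction base value of a type multiset; 0 when undeclared."""
        return self.synergy_table.get(tuple(sorted(types)), 0.0)


def _parse_half_life(raw) -> float:
    if raw is None:
        return math.inf
    if isinstance(raw, str) and raw.lower() in ("inf", "infinity", ".inf"):
        return math.inf
    return float(raw)


def load_valuation_config(path: str | Path) -> ValuationConfig:
    """Load and validate a valuation config from YAML (JSON is valid YAML).

    Schema: top-level mappings ``types`` (type_key -> spec fields),
    ``synergy`` (list of {types: [..], value: x}), ``group_growth``
    ({form, C}), optional scalars, and ``marketplace``.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "types" not in raw or not isinstance(raw["types"], dict) or not raw["types"]:
        raise ConfigError(f"{path}: missing or empty 'types' section")

    registry: dict[str, RecordTypeSpec] = {}
    for key, body in raw["types"].items():
        body = dict(body or {})
        if "base_value" not in body:
            raise ConfigError(f"{path}: type {key!r} lacks base_value")
        try:
            registry[key] = RecordTypeSpec(
                type_key=key,
                base_value=float(body["base_value"]),
                half_life=_parse_half_life(body.get("half_life")),
                kernel_offset=float(body.get("kernel_offset", 0.0)),
                kernel=body.get("kernel", "half_life_exp"),
                display_name=body.get("display_name", key),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: type {key!r}: {exc}") from exc

    synergy: dict[tuple[str, ...], float] = {}
    for entry in raw.get("synergy", []) or []:
        if "types" not in entry or "value" not in entry:
            raise ConfigError(f"{path}: synergy entries need 'types' and 'value'")
        synergy[tuple(sorted(entry["types"]))] = float(entry["value"])

    growth = raw.get("group_growth", {}) or {}
    mp = MarketplaceParams(**(raw.get("marketplace", {}) or {}))

    return ValuationConfig(
        type_registry=registry,
        synergy_table=synergy,
        quality_aggregator=raw.get("quality_aggregator", "reciprocal_sum"),
        group_growth_form=growth.get("form", "k_log_k"),
        group_growth_c=float(growth.get("C", 1.0)),
        max_combination_order=int(raw.get("max_combination_order", 4)),
        enumeration_cap=int(raw.get("enumeration_cap", 64)),
        relationship_regularization=bool(raw.get("relationship_regularization", True)),
        critical_representative_level=float(raw.get("critical_representative_level", 0.0)),
        marketplace=mp,
    )


def read_records(path: str | Path, format: str | None = None) -> Dataset:
    """Read a record table from CSV (header row) or JSON (array of objects)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        frame = pd.read_csv(path, dtype={c: str for c in ("record_id", "owner_id", "type")},
                            float_precision="round_trip")
    elif format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
        frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    else:
        raise ValueError(f"unknown format {format!r}")

    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordParseError(f"{path}: missing columns {missing}")

    ds = Dataset()
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            rec = BiomedicalRecord(
                record_id=str(row.record_id),
                owner_id=str(row.owner_id),
                type=str(row.type),
                time=float(row.time),
                quality=float(row.quality),
            )
        except ValueError as exc:
            raise RecordParseError(f"{path}: row {i + 1}: {exc}") from exc
        try:
            ds.add(rec)
        except RecordParseError as exc:
            raise RecordParseError(f"{path}: row {i + 1}: {exc}") from exc
    return ds


def write_records(dataset: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a record table; inverse of :func:`read_records`.

    Rows are emitted in record_id order so output is bit-stable.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    rows = [
        {
            "record_id": r.record_id,
            "owner_id": r.owner_id,
            "type": r.type,
            "time": r.time,
            "quality": r.quality,
        }
        for r in sorted(dataset, key=lambda r: r.record_id)
    ]
    if format == "csv":
        frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
        # shortest round-trip float text, so read_records is an exact inverse
        for col in ("time", "quality"):
            frame[col] = frame[col].map(repr)
        frame.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
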
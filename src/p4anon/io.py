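"""Readers and writers: CSV data, hierarchy files, run config, JSON report.

Cell values are never coerced — everything stays text, including empty
strings.  All file errors carry the path and, where applicable, the line
number and field, so they are actionable.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .core import (
    AttributeConfig,
    Dataset,
    Hierarchy,
    HierarchyError,
    build_hierarchy,
)
from .models import SENSITIVE_DEPENDENT, PrivacyModel

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run configuration violates the documented schema."""


@dataclass
class RunConfig:
    """Validated run configuration (defaults filled in)."""

    attributes: list[AttributeConfig]
    models: list[PrivacyModel]
    transformation: str = "global"
    suppression_limit: float = 1.0
    partitions: int = 1
    workers: int | None = None
    harmonization: str = "average"
    local_iterations: int = 10
    seed: int = 0
    delimiter: str = ","
    quotechar: str = '"'
    hierarchy_delimiter: str = ";"
    lattice_node_cap: int = 10**6
    prune: bool = True
    #: directory hierarchy paths are resolved against (set by load_config)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ConfigError("attributes: names are not unique")
        if self.transformation not in ("global", "local"):
            raise ConfigError(
                f"transformation: expected 'global' or 'local', "
                f"got {self.transformation!r}"
            )
        if self.harmonization not in ("average", "minimum", "median"):
            raise ConfigError(
                f"harmonization: unknown strategy {self.harmonization!r}"
            )
        if not 0 <= self.suppression_limit <= 1:
            raise ConfigError("suppression_limit: must be in [0, 1]")
        if self.partitions < 1:
            raise ConfigError("partitions: must be >= 1")
        if self.workers is not None and self.workers < 1:
            raise ConfigError("workers: must be >= 1")
        if self.local_iterations < 1:
            raise ConfigError("local_iterations: must be >= 1")
        roles = {a.name: a.role for a in self.attributes}
        for a in self.attributes:
            if a.role == "quasi_identifier" and not a.hierarchy_ref:
                raise ConfigError(
                    f"attributes.{a.name}: quasi-identifier needs a hierarchy"
                )
        for m in self.models:
            if m.kind in SENSITIVE_DEPENDENT:
                if roles.get(m.sensitive) != "sensitive":
                    raise ConfigError(
                        f"models.{m.kind}: sensitive attribute "
                        f"{m.sensitive!r} is not declared with role sensitive"
                    )

    @property
    def qi_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "quasi_identifier"]

    @property
    def sensitive_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.role == "sensitive"]

    def to_dict(self) -> dict[str, Any]:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "role": a.role,
                    **(
                        {"hierarchy": a.hierarchy_ref}
                        if a.hierarchy_ref
                        else {}
                    ),
                }
                for a in self.attributes
            ],
            "models": [m.describe() for m in self.models],
            "transformation": self.transformation,
            "suppression_limit": self.suppression_limit,
            "partitions": self.partitions,
            "workers": self.workers,
            "harmonization": self.harmonization,
            "local_iterations": self.local_iterations,
            "seed": self.seed,
        }


_MODEL_PARAM_KEYS = {
    "k": int,
    "l": int,
    "c": float,
    "t": float,
    "delta": float,
    "beta": float,
    "threshold": float,
}


def _parse_model(block: Mapping[str, Any], idx: int) -> PrivacyModel:
    if not isinstance(block, Mapping) or "type" not in block:
        raise ConfigError(f"models[{idx}]: expected a mapping with a 'type'")
    kwargs: dict[str, Any] = {"kind": str(block["type"])}
    for key, val in block.items():
        if key == "type":
            continue
        elif key in _MODEL_PARAM_KEYS:
            kwargs[key] = _MODEL_PARAM_KEYS[key](val)
        elif key == "sensitive":
            kwargs["sensitive"] = str(val)
        elif key == "estimator":
            kwargs["estimator"] = str(val)
        elif key == "order":
            kwargs["order"] = tuple(str(v) for v in val)
        else:
            raise ConfigError(f"models[{idx}]: unknown key {key!r}")
    try:
        return PrivacyModel(**kwargs)
    except ValueError as e:
        raise ConfigError(f"models[{idx}]: {e}") from None


def _parse_attribute(block: Mapping[str, Any], idx: int) -> AttributeConfig:
    if not isinstance(block, Mapping) or "name" not in block:
        raise ConfigError(f"attributes[{idx}]: expected a mapping with a 'name'")
    try:
        return AttributeConfig(
            name=str(block["name"]),
            role=str(block.get("role", "insensitive")),
            hierarchy_ref=(
                str(block["hierarchy"]) if "hierarchy" in block else None
            ),
        )
    except ValueError as e:
        raise ConfigError(f"attributes[{idx}]: {e}") from None


def config_from_dict(raw: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    known = {
        "attributes",
        "models",
        "transformation",
        "suppression_limit",
        "partitions",
        "workers",
        "harmonization",
        "local_iterations",
        "seed",
        "csv_dialect",
        "hierarchy_delimiter",
        "lattice_node_cap",
        "prune",
    }
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
    if "attributes" not in raw:
        raise ConfigError("attributes: required")
    attrs = [
        _parse_attribute(b, i) for i, b in enumerate(raw["attributes"])
    ]
    models = [_parse_model(b, i) for i, b in enumerate(raw.get("models", []))]
    dialect = raw.get("csv_dialect", {}) or {}
    try:
        return RunConfig(
            attributes=attrs,
            models=models,
            transformation=str(raw.get("transformation", "global")),
            suppression_limit=float(raw.get("suppression_limit", 1.0)),
            partitions=int(raw.get("partitions", 1)),
            workers=(
                int(raw["workers"]) if raw.get("workers") is not None else None
            ),
            harmonization=str(raw.get("harmonization", "average")),
            local_iterations=int(raw.get("local_iterations", 10)),
            seed=int(raw.get("seed", 0)),
            delimiter=str(dialect.get("delimiter", ",")),
            quotechar=str(dialect.get("quote", '"')),
            hierarchy_delimiter=str(raw.get("hierarchy_delimiter", ";")),
            lattice_node_cap=int(raw.get("lattice_node_cap", 10**6)),
            prune=bool(raw.get("prune", True)),
            base_dir=base_dir or Path(),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    try:
        cfg = config_from_dict(raw, base_dir=path.parent)
    except ConfigError as e:
        raise ConfigError(f"{path}: {e}") from None
    logging.getLogger("p4anon").debug("loaded config: %s", cfg.to_dict())
    return cfg


def load_hierarchy(path: str | Path, delimiter: str = ";") -> Hierarchy:
    """Load a semicolon-delimited hierarchy file (one row per leaf, no header)."""
    path = Path(path)
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for row in reader:
            if row:
                rows.append(tuple(row))
    if rows:
        width = len(rows[0])
        for i, r in enumerate(rows, start=1):
            if len(r) != width:
                raise HierarchyError(
                    f"{path}: line {i}: {len(r)} columns, expected {width}"
                )
    try:
        return build_hierarchy(rows)
    except HierarchyError as e:
        raise type(e)(f"{path}: {e}") from None


def load_hierarchies(cfg: RunConfig) -> dict[str, Hierarchy]:
    out = {}
    for a in cfg.attributes:
        if a.role != "quasi_identifier":
            continue
        hpath = Path(a.hierarchy_ref)
        if not hpath.is_absolute():
            hpath = cfg.base_dir / hpath
        if not hpath.exists():
            raise ConfigError(
                f"attributes.{a.name}: hierarchy file {hpath} does not exist"
            )
        out[a.name] = load_hierarchy(hpath, cfg.hierarchy_delimiter)
    return out


def load_dataset(path: str | Path, cfg: RunConfig) -> Dataset:
    """Load a CSV with header; all cells read as text, row ids by input order."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=cfg.delimiter, quotechar=cfg.quotechar)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigError(f"{path}: empty file") from None
        names = [a.name for a in cfg.attributes]
        missing = [n for n in names if n not in header]
        if missing:
            raise ConfigError(
                f"{path}: header is missing configured attribute(s) "
                f"{missing}"
            )
        col_pos = [header.index(n) for n in names]
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ConfigError(
                    f"{path}: line {lineno}: {len(row)} fields, "
                    f"expected {len(header)}"
                )
            records.append(tuple(row[p] for p in col_pos))
    hierarchies = load_hierarchies(cfg)
    df = pd.DataFrame(records, columns=names, dtype=object)
    return Dataset(df, list(cfg.attributes), hierarchies)


def write_dataset(
    d: Dataset,
    path: str | Path,
    *,
    delimiter: str = ",",
    quotechar: str = '"',
    row_id_column: str | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, quotechar=quotechar)
        names = [a.name for a in d.attributes]
        header = ([row_id_column] if row_id_column else []) + names
        writer.writerow(header)
        for rid, row in zip(d.df.index, d.df.itertuples(index=False, name=None)):
            writer.writerow(([rid] if row_id_column else []) + list(row))


def write_report(
    report: Mapping[str, Any] | Any, cfg: RunConfig, path: str | Path
) -> None:
    """Serialize a run report (plus config echo and schema version) as JSON."""
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": cfg.to_dict(),
        "report": report if isinstance(report, Mapping) else report.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
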
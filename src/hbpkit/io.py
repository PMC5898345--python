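"""Reading and writing intervention tables, configuration and reports.

The canonical intervention table is comma-separated with a header row::

    id,name,icer_usd_per_daly,cost_saving,cases_per_year,cost_full_usd,
    dalys_full,implementation_level,flags

An optional first line ``# units: thousands`` declares that cases, costs and
DALYs are printed in thousands (the convention of published league tables);
they are converted to raw units on load. Source tables that mix raw and
thousand-scale columns are a classic source of silent errors, so everything
downstream of the loader works in raw USD and raw DALYs only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .core_metrics import DomainError, EconomyParams, Intervention

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_interventions",
    "write_interventions",
    "load_config",
    "economy_from_config",
    "write_table",
    "write_json",
]

logger = logging.getLogger("hbpkit")

REQUIRED_COLUMNS = (
    "id",
    "name",
    "icer_usd_per_daly",
    "cost_saving",
    "cases_per_year",
    "cost_full_usd",
    "dalys_full",
)
OPTIONAL_COLUMNS = ("implementation_level", "flags", "icer_rank", "low_confidence")

_COST_SAVING_STRINGS = {"cost saving", "cost-saving", "cost_saving", "cs"}
_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}
_FALSE_STRINGS = {"false", "0", "no", "n", "f", ""}


class SchemaError(ValueError):
    """The input table does not match the canonical schema."""


@dataclass(frozen=True)
class RunConfig:
    """Plumbing options shared by the command-line entry points."""

    input_path: Path | None = None
    config_path: Path | None = None
    output_dir: Path = Path(".")
    rounding_decimals: int = 0
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise DomainError("seed must be a non-negative integer")
        if self.rounding_decimals < 0:
            raise DomainError("rounding precision must be >= 0")


def _units_multiplier(path: Path) -> float:
    with open(path) as fh:
        first = fh.readline().strip().lower()
    if first.startswith("#") and "units" in first:
        if "thousand" in first:
            return 1000.0
        if "raw" in first or "usd" in first:
            return 1.0
        raise SchemaError(f"unrecognised units declaration: {first!r}")
    return 1.0


def _parse_bool(value: Any, column: str) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    if isinstance(value, (int, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise SchemaError(f"cannot parse {column}={value!r} as a boolean")


def load_interventions(path: str | Path) -> list[Intervention]:
    """Load and validate an intervention table.

    Applies the declared unit conversion, fills a missing implementation
    level with 1.0 (warning), deduplicates repeated names keeping the first
    occurrence (warning per drop) and validates every record's invariants.

    Raises
    ------
    SchemaError
        On a missing required column, an unparsable cell or an invariant
        violation such as an implementation level outside [0, 1].
    """
    path = Path(path)
    mult = _units_multiplier(path)
    df = pd.read_csv(path, comment="#", dtype={"id": str, "name": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    if "implementation_level" not in df.columns:
        logger.warning(
            "%s: no implementation_level column; defaulting every row to 1.0", path
        )
        df["implementation_level"] = 1.0

    records: list[Intervention] = []
    seen_names: set[str] = set()
    for idx, row in df.iterrows():
        name = str(row["name"]).strip()
        if name in seen_names:
            logger.warning("%s: dropping duplicate row for %r (row %d)", path, name, idx)
            continue
        seen_names.add(name)

        cost_saving = _parse_bool(row["cost_saving"], "cost_saving")
        raw_icer = row["icer_usd_per_daly"]
        if isinstance(raw_icer, str) and raw_icer.strip().lower() in _COST_SAVING_STRINGS:
            cost_saving = True
            icer: float | None = None
        elif pd.isna(raw_icer):
            icer = None
        else:
            icer = float(raw_icer)
        if cost_saving:
            icer = None

        level = row["implementation_level"]
        if pd.isna(level):
            logger.warning(
                "%s: %r has no implementation_level; defaulting to 1.0", path, name
            )
            level = 1.0

        flags: frozenset[str] = frozenset()
        if "flags" in df.columns and not pd.isna(row["flags"]):
            flags = frozenset(
                f.strip() for f in str(row["flags"]).split(";") if f.strip()
            )

        rank = None
        if "icer_rank" in df.columns and not pd.isna(row["icer_rank"]):
            rank = int(row["icer_rank"])
        low_conf = "low_confidence" in df.columns and _parse_bool(
            row["low_confidence"], "low_confidence"
        )

        try:
            records.append(
                Intervention(
                    id=str(row["id"]).strip(),
                    name=name,
                    icer_usd_per_daly=icer,
                    cost_saving=cost_saving,
                    cases_per_year=float(row["cases_per_year"]) * mult,
                    cost_full_usd=float(row["cost_full_usd"]) * mult,
                    dalys_full=float(row["dalys_full"]) * mult,
                    implementation_level=float(level),
                    flags=flags,
                    icer_rank=rank,
                    low_confidence=low_conf,
                )
            )
        except DomainError as err:
            raise SchemaError(f"{path} row {idx} ({name!r}): {err}") from err
    logger.info("%s: loaded %d intervention(s)", path, len(records))
    return records


def write_interventions(
    interventions: list[Intervention], path: str | Path
) -> None:
    """Write interventions in the canonical schema (raw USD/DALY units)."""
    rows = []
    for iv in interventions:
        rows.append(
            {
                "id": iv.id,
                "name": iv.name,
                "icer_usd_per_daly": "" if iv.cost_saving else iv.icer_usd_per_daly,
                "cost_saving": iv.cost_saving,
                "cases_per_year": iv.cases_per_year,
                "cost_full_usd": iv.cost_full_usd,
                "dalys_full": iv.dalys_full,
                "implementation_level": iv.implementation_level,
                "flags": ";".join(sorted(iv.flags)),
                "icer_rank": "" if iv.icer_rank is None else iv.icer_rank,
                "low_confidence": iv.low_confidence,
            }
        )
    pd.DataFrame(
        rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return cfg


def economy_from_config(cfg: dict[str, Any]) -> EconomyParams:
    """Build :class:`EconomyParams` from a configuration mapping."""
    return EconomyParams(
        k_usd_per_daly=float(cfg.get("k_usd_per_daly", 61.0)),
        threshold_scenarios={
            str(k): float(v) for k, v in (cfg.get("threshold_scenarios") or {}).items()
        },
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular report as comma-separated text."""
    table.to_csv(path, index=False)


def write_json(obj: Any, path: str | Path) -> None:
    """Write a report object (dataclass, mapping or sequence) as JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")
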
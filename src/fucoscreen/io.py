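"""CSV/TSV/JSON plumbing: schema-validated readers, writers, provenance.

All tables are plain UTF-8 CSV/TSV with explicit headers; lines starting
with ``#`` are comments. NA policy: an NA fluorescence cell is retained
and excluded from replicate means (with a warning at screening time); an
NA OD625 invalidates the row at screening time. Every pipeline run can
write a provenance JSON (config + seed + package version) so outputs are
reproducible from config and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

PLATE_COLUMNS = ["strain_id", "well", "replicate", "phase", "od625", "rfu_chla", "rfu_nilered"]
EXTRACT_COLUMNS = ["strain_id", "a665", "a652", "a470", "extract_ml", "biomass_mg", "dilution"]
GROWTH_COLUMNS = ["time_days", "od625", "dpa_uM"]

__all__ = [
    "PLATE_COLUMNS",
    "EXTRACT_COLUMNS",
    "GROWTH_COLUMNS",
    "read_plate_csv",
    "write_plate_csv",
    "read_extract_csv",
    "read_growth_csv",
    "write_growth_csv",
    "write_population_tsv",
    "write_provenance",
    "write_report",
]


class SchemaError(ValueError):
    """A table file does not match its expected header or column types."""


def _read_table(path: str | Path, columns: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}; found {list(df.columns)}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise SchemaError(f"{path.name}: non-numeric value in column {col!r} near line {row}")
        df[col] = coerced
    return df


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a plate-reader table (``strain_id,well,replicate,phase,od625,
    rfu_chla,rfu_nilered``), validating header and numeric columns."""
    return _read_table(path, PLATE_COLUMNS, ["od625", "rfu_chla", "rfu_nilered"])


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate.to_csv(path, index=False, columns=[c for c in PLATE_COLUMNS if c in plate.columns])


def read_extract_csv(path: str | Path) -> pd.DataFrame:
    """Read extract absorbances (``strain_id,a665,a652,a470,extract_ml,
    biomass_mg,dilution``)."""
    return _read_table(
        path, EXTRACT_COLUMNS, ["a665", "a652", "a470", "extract_ml", "biomass_mg", "dilution"]
    )


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    """Read growth curves (``time_days,od625,dpa_uM``)."""
    return _read_table(path, GROWTH_COLUMNS, GROWTH_COLUMNS)


def write_growth_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in GROWTH_COLUMNS if c in df.columns])


def write_population_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def write_provenance(path: str | Path, config: Any, seed: int | None = None, **extra: Any) -> None:
    """Write a provenance JSON sidecar: config, seed, versions."""
    from . import __version__

    payload = {
        "config": _jsonable(config),
        "seed": seed,
        "fucoscreen_version": __version__,
        "python_version": platform.python_version(),
        **{k: _jsonable(v) for k, v in extra.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_report(report, out_dir: str | Path) -> dict[str, Path]:
    """Write a ScreeningReport as JSON plus human-readable TSVs.

    Produces ``report.json`` (full audit trail), ``stages.tsv`` (counts)
    and ``selected.tsv`` (final strain list); returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_dir / "report.json",
        "stages": out_dir / "stages.tsv",
        "selected": out_dir / "selected.tsv",
    }
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    pd.DataFrame(
        [{"stage": n, "n_in": i, "n_out": o} for n, i, o in report.stage_counts()]
    ).to_csv(paths["stages"], sep="\t", index=False)
    pd.DataFrame({"strain_id": report.selected}).to_csv(paths["selected"], sep="\t", index=False)
    return paths
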
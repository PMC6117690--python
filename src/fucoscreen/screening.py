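"""Three-step high-throughput mutant screen with stability assessment.

The screen reproduces the campaign workflow as an auditable pipeline:

1. **Colony selection** — keep agar-plate colonies in the top quantiles
   of both size and colour intensity (the "deep colour, large size" rule
   made reproducible as a double-quantile filter).
2. **Fluorescence filter** — on triplicate-averaged 96-well reads, keep
   strains satisfying both regression-derived thresholds::

       RFU_chla >= 2309 * OD625 - 24.3
       RFU_nr   >= 167.1 * OD625 - 0.21

   Both inequalities are inclusive and both must hold; the decision trace
   records each rule's margin separately.
3. **Carotenoid filter** — after methanol extraction, keep strains whose
   total carotenoids are at least 15% above the wild type.
4. **Stability assessment** — after ~16 generations of repeated batch
   cultivation, a strain is stable iff its carotenoid content changed by
   less than 10%; a final value within 10% of the WT level additionally
   flags reversion to wild type.

Every exclusion carries the stage and rule that triggered it, and stage
survivor sets are nested by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CHL_THRESHOLD_SLOPE",
    "CHL_THRESHOLD_INTERCEPT",
    "NR_THRESHOLD_SLOPE",
    "NR_THRESHOLD_INTERCEPT",
    "ScreenConfig",
    "StageResult",
    "ScreeningReport",
    "chla_threshold",
    "nilered_threshold",
    "colony_select",
    "fluorescence_filter",
    "carotenoid_filter",
    "stability_assess",
    "run_screen",
]

# Regression-derived screening thresholds (RFU as a function of OD625).
CHL_THRESHOLD_SLOPE = 2309.0
CHL_THRESHOLD_INTERCEPT = -24.3
NR_THRESHOLD_SLOPE = 167.1
NR_THRESHOLD_INTERCEPT = -0.21


def chla_threshold(od625: float) -> float:
    """Minimum chlorophyll-a RFU for a strain to pass at a given OD625."""
    return CHL_THRESHOLD_SLOPE * od625 + CHL_THRESHOLD_INTERCEPT


def nilered_threshold(od625: float) -> float:
    """Minimum Nile-red RFU for a strain to pass at a given OD625."""
    return NR_THRESHOLD_SLOPE * od625 + NR_THRESHOLD_INTERCEPT


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable screen parameters (defaults are the standard campaign rules)."""

    size_quantile: float = 0.8  # keep top 20% by colony size ...
    color_quantile: float = 0.8  # ... and top 20% by colour intensity
    min_increase_pct: float = 15.0  # carotenoid gain over WT, percent
    stability_tolerance_pct: float = 10.0
    reversion_tolerance_pct: float = 10.0

    def __post_init__(self) -> None:
        for name in ("size_quantile", "color_quantile"):
            q = getattr(self, name)
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_increase_pct < 0:
            raise ValueError("min_increase_pct must be >= 0")
        if self.stability_tolerance_pct <= 0:
            raise ValueError("stability_tolerance_pct must be > 0")


@dataclass
class StageResult:
    """Outcome of one screening stage."""

    name: str
    n_in: int
    n_out: int
    survivors: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # strain_id -> reason

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "survivors": list(self.survivors),
            "dropped": dict(self.dropped),
        }


@dataclass
class ScreeningReport:
    """Full audit trail of a screening campaign."""

    stages: list[StageResult]
    selected: list[str]
    trace: pd.DataFrame  # per-strain decision details across stages

    def stage_counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def to_dict(self) -> dict[str, Any]:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "selected": list(self.selected),
            "trace": self.trace.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# stage 1: colony selection


def colony_select(
    colonies: pd.DataFrame,
    size_quantile: float = 0.8,
    color_quantile: float = 0.8,
) -> list[str]:
    """Keep colonies at or above both score quantiles.

    ``colonies`` needs columns ``strain_id, size, color_intensity``.
    Thresholding is inclusive (ties pass), which makes the selection
    deterministic; the survivor list is sorted by strain_id.
    """
    if colonies.empty:
        raise ValueError("colony table is empty")
    for col in ("strain_id", "size", "color_intensity"):
        if col not in colonies.columns:
            raise ValueError(f"colony table missing column {col!r}")
    size_thr = colonies["size"].quantile(size_quantile)
    color_thr = colonies["color_intensity"].quantile(color_quantile)
    keep = colonies[
        (colonies["size"] >= size_thr) & (colonies["color_intensity"] >= color_thr)
    ]
    return sorted(keep["strain_id"].tolist())


# ---------------------------------------------------------------------------
# stage 2: fluorescence filter


def fluorescence_filter(plate: pd.DataFrame) -> pd.DataFrame:
    """Evaluate both fluorescence thresholds on replicate-averaged reads.

    ``plate`` needs columns ``strain_id, od625, rfu_chla, rfu_nilered``
    (replicate rows). Rows with non-positive OD are rejected with a
    warning; NA fluorescence cells are excluded from the replicate mean
    with a warning; an NA OD invalidates the row.

    Returns one row per strain with the means, both thresholds, both
    margins (``rfu - threshold``), per-rule booleans and the combined
    ``passed`` flag (AND of the two inclusive inequalities).
    """
    required = {"strain_id", "od625", "rfu_chla", "rfu_nilered"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    plate = plate.copy()
    bad_od = plate["od625"].isna() | (plate["od625"] <= 0)
    if bad_od.any():
        warnings.warn(
            f"rejecting {int(bad_od.sum())} plate rows with missing/non-positive OD625",
            stacklevel=2,
        )
        plate = plate[~bad_od]
    if plate.empty:
        raise ValueError("no valid plate rows to screen")
    na_rfu = plate[["rfu_chla", "rfu_nilered"]].isna().any(axis=1)
    if na_rfu.any():
        warnings.warn(
            f"{int(na_rfu.sum())} rows have NA fluorescence cells; "
            "those cells are excluded from replicate means",
            stacklevel=2,
        )
    means = plate.groupby("strain_id")[["od625", "rfu_chla", "rfu_nilered"]].mean()

    out = means.reset_index()
    out["chla_threshold"] = CHL_THRESHOLD_SLOPE * out["od625"] + CHL_THRESHOLD_INTERCEPT
    out["nr_threshold"] = NR_THRESHOLD_SLOPE * out["od625"] + NR_THRESHOLD_INTERCEPT
    out["chla_margin"] = out["rfu_chla"] - out["chla_threshold"]
    out["nr_margin"] = out["rfu_nilered"] - out["nr_threshold"]
    out["chla_pass"] = out["chla_margin"] >= 0
    out["nr_pass"] = out["nr_margin"] >= 0
    out["passed"] = out["chla_pass"] & out["nr_pass"]
    return out.sort_values("strain_id", ignore_index=True)


# ---------------------------------------------------------------------------
# stage 3: carotenoid filter


def carotenoid_filter(
    profiles: Mapping[str, float] | pd.DataFrame,
    wt_car: float,
    min_increase_pct: float = 15.0,
) -> list[str]:
    """Strains whose carotenoid content is >= (1 + pct/100) x WT.

    ``profiles`` maps strain_id -> total carotenoids (mg/g DW), or is a
    DataFrame with columns ``strain_id, xcar_per_dw``.
    """
    if wt_car is None or wt_car <= 0:
        raise ValueError("a positive WT carotenoid content is required")
    if isinstance(profiles, pd.DataFrame):
        profiles = dict(zip(profiles["strain_id"], profiles["xcar_per_dw"]))
    threshold = wt_car * (1.0 + min_increase_pct / 100.0)
    return sorted(sid for sid, xcar in profiles.items() if xcar >= threshold)


# ---------------------------------------------------------------------------
# stage 4: stability


def stability_assess(
    initial_car: float,
    final_car: float,
    tolerance_pct: float = 10.0,
    wt_car: float | None = None,
    reversion_tolerance_pct: float = 10.0,
) -> tuple[str, bool]:
    """Classify a before/after carotenoid pair as stable or unstable.

    Stable iff ``|final - initial| / initial < tolerance_pct/100``. When
    ``wt_car`` is given, the reversion flag is set if the final content
    lies within ``reversion_tolerance_pct`` of the WT level — the
    signature of a heterozygous phenotype resolving back to wild type.
    """
    if initial_car <= 0:
        raise ValueError("initial_car must be > 0")
    change = abs(final_car - initial_car) / initial_car
    status = "stable" if change < tolerance_pct / 100.0 else "unstable"
    reverted = False
    if wt_car is not None and wt_car > 0:
        reverted = abs(final_car - wt_car) / wt_car < reversion_tolerance_pct / 100.0
    return status, reverted


# ---------------------------------------------------------------------------
# full pipeline


def _check_ids(stage: str, have: set[str], need: Sequence[str]) -> None:
    orphans = [sid for sid in need if sid not in have]
    if orphans:
        raise ValueError(
            f"{stage}: {len(orphans)} strain id(s) missing from input table: "
            f"{orphans[:10]}{'...' if len(orphans) > 10 else ''}"
        )


def run_screen(
    population: Sequence[str] | pd.DataFrame,
    plates: pd.DataFrame,
    profiles: Mapping[str, float] | pd.DataFrame,
    config: ScreenConfig | None = None,
    colonies: pd.DataFrame | None = None,
    stability: pd.DataFrame | None = None,
    wt_car: float | None = None,
) -> ScreeningReport:
    """Run the full screen and return the audit report.

    Parameters
    ----------
    population
        Strain ids in the campaign (or a manifest DataFrame with a
        ``strain_id`` column). The WT reference id ``"WT"`` provides the
        carotenoid baseline unless ``wt_car`` is given explicitly.
    plates
        Replicate-level plate reads (stage 2 input).
    profiles
        strain_id -> total carotenoids mg/g DW (stage 3 input).
    colonies
        Optional colony score table (stage 1); stage skipped when absent.
    stability
        Optional DataFrame ``strain_id, initial_car, final_car`` (stage
        4); stage skipped when absent.
    """
    config = config or ScreenConfig()
    if isinstance(population, pd.DataFrame):
        ids = population["strain_id"].tolist()
    else:
        ids = list(population)
    candidates = sorted(sid for sid in ids if sid != "WT")

    if isinstance(profiles, pd.DataFrame):
        profiles = dict(zip(profiles["strain_id"], profiles["xcar_per_dw"]))
    if wt_car is None:
        if "WT" not in profiles:
            raise ValueError("no WT reference: supply wt_car or a 'WT' profile")
        wt_car = profiles["WT"]

    stages: list[StageResult] = []
    trace_frames: list[pd.DataFrame] = []
    current = candidates

    if not candidates:
        return ScreeningReport(
            stages=[StageResult("empty", 0, 0, [])],
            selected=[],
            trace=pd.DataFrame(columns=["strain_id"]),
        )

    # stage 1: colonies
    if colonies is not None:
        _check_ids("colony_select", set(colonies["strain_id"]), current)
        sub = colonies[colonies["strain_id"].isin(current)]
        kept = colony_select(sub, config.size_quantile, config.color_quantile)
        dropped = {sid: "below size/colour quantile" for sid in current if sid not in kept}
        stages.append(StageResult("colony_select", len(current), len(kept), kept, dropped))
        logger.info("colony_select: %d -> %d strains", len(current), len(kept))
        current = kept

    # stage 2: fluorescence thresholds
    _check_ids("fluorescence_filter", set(plates["strain_id"]), current)
    decisions = fluorescence_filter(plates[plates["strain_id"].isin(current)])
    trace_frames.append(decisions.assign(stage="fluorescence_filter"))
    kept = sorted(decisions.loc[decisions["passed"], "strain_id"].tolist())
    dropped = {}
    for _, row in decisions[~decisions["passed"]].iterrows():
        rules = []
        if not row["chla_pass"]:
            rules.append("chlorophyll-a threshold")
        if not row["nr_pass"]:
            rules.append("Nile-red threshold")
        dropped[row["strain_id"]] = " and ".join(rules)
    stages.append(StageResult("fluorescence_filter", len(current), len(kept), kept, dropped))
    logger.info("fluorescence_filter: %d -> %d strains", len(current), len(kept))
    current = kept

    # stage 3: carotenoid content
    _check_ids("carotenoid_filter", set(profiles), current)
    sub_profiles = {sid: profiles[sid] for sid in current}
    kept = carotenoid_filter(sub_profiles, wt_car, config.min_increase_pct)
    threshold = wt_car * (1 + config.min_increase_pct / 100.0)
    dropped = {
        sid: f"carotenoids {sub_profiles[sid]:.3g} < {threshold:.3g} mg/g DW"
        for sid in current
        if sid not in kept
    }
    stages.append(StageResult("carotenoid_filter", len(current), len(kept), kept, dropped))
    logger.info("carotenoid_filter: %d -> %d strains", len(current), len(kept))
    current = kept

    # stage 4: stability (recorded even when nothing reaches it)
    if stability is not None:
        _check_ids("stability_assess", set(stability["strain_id"]), current)
        sub = stability.set_index("strain_id")
        kept, dropped, rows = [], {}, []
        for sid in current:
            status, reverted = stability_assess(
                float(sub.loc[sid, "initial_car"]),
                float(sub.loc[sid, "final_car"]),
                config.stability_tolerance_pct,
                wt_car,
                config.reversion_tolerance_pct,
            )
            rows.append(
                {
                    "strain_id": sid,
                    "stage": "stability_assess",
                    "status": status,
                    "reverted_to_wt": reverted,
                }
            )
            if status == "stable":
                kept.append(sid)
            else:
                dropped[sid] = "unstable" + (" (reverted to WT)" if reverted else "")
        trace_frames.append(pd.DataFrame(rows))
        stages.append(StageResult("stability_assess", len(current), len(kept), kept, dropped))
        logger.info("stability_assess: %d -> %d strains", len(current), len(kept))
        current = kept

    trace = (
        pd.concat(trace_frames, ignore_index=True)
        if trace_frames
        else pd.DataFrame(columns=["strain_id"])
    )
    return ScreeningReport(stages=stages, selected=current, trace=trace)
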
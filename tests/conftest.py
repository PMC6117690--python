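"""Shared fixtures: small synthetic campaigns with planted positives."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fucoscreen as fs
from fucoscreen.screening import chla_threshold, nilered_threshold

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gen_config() -> fs.GeneratorConfig:
    return fs.GeneratorConfig(n_strains=200, seed=42)


@pytest.fixture(scope="session")
def population(gen_config) -> list[fs.StrainRecord]:
    return fs.generate_population(gen_config)


@pytest.fixture(scope="session")
def toy_model():
    return fs.build_toy_network()


def make_campaign(
    n_strains: int = 200,
    seed: int = 42,
    n_planted: int = 5,
) -> dict:
    """A full synthetic screening campaign with planted true positives.

    Planted strains are constructed strictly above every stage's
    threshold: colony scores above the population maximum, fluorescence
    at twice both thresholds (noise-free, identical replicates),
    carotenoids at 1.4x WT, and perfectly stable trajectories — so a
    correct screen must select all of them.
    """
    config = fs.GeneratorConfig(n_strains=n_strains, seed=seed)
    strains = fs.generate_population(config)
    plate = fs.simulate_plate_reads(strains, "exponential", config, 3, seed=seed + 1)
    colonies = fs.simulate_colonies(strains, seed=seed + 2)
    stability = fs.simulate_stability_series(strains, seed=seed + 3, wt_car=config.wt_car)
    profiles = {s.strain_id: s.true_car for s in strains}

    od = 0.15
    planted_ids = [f"POS{i:02d}" for i in range(1, n_planted + 1)]
    plate_rows, colony_rows, stab_rows = [], [], []
    for sid in planted_ids:
        for rep in range(1, 4):
            plate_rows.append(
                {
                    "strain_id": sid,
                    "well": "Z01",
                    "replicate": rep,
                    "phase": "exponential",
                    "od625": od,
                    "rfu_chla": 2.0 * chla_threshold(od),
                    "rfu_nilered": 2.0 * nilered_threshold(od),
                }
            )
        colony_rows.append(
            {
                "strain_id": sid,
                "size": 2.0 * colonies["size"].max(),
                "color_intensity": 2.0 * colonies["color_intensity"].max(),
            }
        )
        profiles[sid] = config.wt_car * 1.4
        stab_rows.append(
            {
                "strain_id": sid,
                "stable": True,
                "initial_car": config.wt_car * 1.4,
                "final_car": config.wt_car * 1.4,
            }
        )

    return {
        "config": config,
        "strains": strains,
        "planted": planted_ids,
        "population": [s.strain_id for s in strains] + planted_ids,
        "plates": pd.concat([plate, pd.DataFrame(plate_rows)], ignore_index=True),
        "colonies": pd.concat([colonies, pd.DataFrame(colony_rows)], ignore_index=True),
        "stability": pd.concat([stability, pd.DataFrame(stab_rows)], ignore_index=True),
        "profiles": profiles,
        "wt_car": config.wt_car,
    }


@pytest.fixture(scope="session")
def campaign() -> dict:
    return make_campaign()


def brute_force_stage2(plate: pd.DataFrame) -> set[str]:
    """Independent row-by-row oracle for the fluorescence thresholds."""
    passed = set()
    for sid, g in plate.groupby("strain_id"):
        g = g[g["od625"] > 0]
        if g.empty:
            continue
        od = g["od625"].mean()
        chla = g["rfu_chla"].mean()
        nr = g["rfu_nilered"].mean()
        if chla >= 2309.0 * od - 24.3 and nr >= 167.1 * od - 0.21:
            passed.add(sid)
    return passed
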
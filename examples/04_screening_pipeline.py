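"""Run the full three-step screen (plus stability) on a synthetic campaign.

Stages: colony size/colour quantiles -> fluorescence thresholds on
triplicate-mean reads -> >= 15% carotenoid gain over WT -> < 10%
stability over ~16 generations. The report records every exclusion with
the rule that triggered it.
"""

from fucoscreen import (
    GeneratorConfig,
    generate_population,
    run_screen,
    simulate_colonies,
    simulate_plate_reads,
    simulate_stability_series,
)

config = GeneratorConfig(n_strains=1000, seed=7)
strains = generate_population(config)
plates = simulate_plate_reads(strains, "exponential", config, n_replicates=3, seed=8)
colonies = simulate_colonies(strains, seed=9)
stability = simulate_stability_series(strains, seed=10, wt_car=config.wt_car)
profiles = {s.strain_id: s.true_car for s in strains}  # extraction-stage contents

report = run_screen(
    population=[s.strain_id for s in strains],
    plates=plates,
    profiles=profiles,
    colonies=colonies,
    stability=stability,
)

for name, n_in, n_out in report.stage_counts():
    print(f"{name:20s} {n_in:4d} -> {n_out:4d}")
print(f"selected: {report.selected or 'none'}")
print()
print(
    "Counts shrink monotonically: each stage only removes strains. Under\n"
    "0.1 M EMS conditions mutant carotenoids top out near +8% over WT, so\n"
    "the +15% extraction filter usually empties the list — matching the\n"
    "observation that single-dose campaigns rarely yield strong gainers\n"
    "and motivating the fluorescence pre-screen's cheap triage."
)
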
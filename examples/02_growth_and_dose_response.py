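"""Fit specific growth rates and summarise the DPA dose-response.

Simulated OD625 time courses at several diphenylamine (DPA) doses are
fit by log-linear regression; the summary classifies each dose as
growing or declining and reports the largest dose still compatible with
growth — the working concentration for inhibitor-pressure screening.
"""

import numpy as np

from fucoscreen import dpa_dose_response, lethality, simulate_growth_curve

t = np.linspace(0.0, 4.0, 9)  # days, twice-daily reads
doses = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)  # uM DPA
curves = [simulate_growth_curve(mu0=0.645, dpa_dose_uM=d, t_grid=t, noise_sd=0.02, seed=1)
          for d in doses]

table = dpa_dose_response(curves)
print(table.table.to_string(index=False))
print(f"\nlargest dose with growth: {table.max_growth_dose_uM:.0f} uM")
print(f"EMS lethality example: 577 survivors vs 1000 controls -> "
      f"{lethality(577, 1000):.1f}% killed")
print()
print(
    "mu falls from ~0.645/day untreated to ~0.431/day at 10 uM and crosses\n"
    "zero at 40 uM. The 40 uM dose sits exactly on the zero-growth boundary,\n"
    "so under measurement noise its classification is a coin flip, while\n"
    "doses above it decline decisively — that boundary dose is the selective\n"
    "pressure applied on the mutagenesis plates."
)
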
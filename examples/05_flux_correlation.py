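"""Sample the toy metabolic network and classify flux correlations with
fucoxanthin synthesis.

The packaged network shares a fixed geranylgeranyl-pyrophosphate (GGPP)
pool between the fucoxanthin and chlorophyll-a branches, with a lipid
branch drawing on pyruvate independently. Uniform sampling of the
steady-state polytope followed by Pearson correlation against the
FUCO_SYN flux recovers the expected pathway-level structure.
"""

from fucoscreen import build_toy_network, classify_correlations, correlate_with_target, sample_fluxes

model = build_toy_network()
samples = sample_fluxes(model, n_samples=2000, seed=1)
print(f"sampled {samples.samples.shape[0]} flux vectors over {len(model.reactions)} reactions; "
      f"max steady-state residual {samples.residuals.max():.1e}")

report = classify_correlations(correlate_with_target(samples), threshold=0.7)
print(report.table.to_string(index=False))
print()
print(report.subsystem_summary().to_string(index=False))
print()
print(
    "Reactions downstream of the target are perfectly coupled (r = +1); the\n"
    "chlorophyll branch competes for the same GGPP pool (r = -1); the lipid\n"
    "branch and the disconnected control pair are uncorrelated; fixed-flux\n"
    "steps are flagged constant. On a genome-scale model the same machinery\n"
    "ranks candidate reactions whose engineering could co-drive fucoxanthin."
)
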
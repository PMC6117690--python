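# Methods

## Pigment quantification

Chlorophyll *a* and total carotenoids are computed from blank-subtracted
absorbances of 100 % methanol extracts with the standard coefficient
set for that solvent: `Ca = 15.65·A665 − 7.34·A652` and
`Xcar = (1000·A470 − 2.86·Ca)/221`, both in mg/L of extract. Biomass
normalisation is `content = conc · volume · dilution / biomass_dw`
(mg/L × mL = µg; µg per mg DW = mg/g DW). Negative computed
concentrations are possible for unphysical inputs (typically blank
subtraction errors); they are returned as-is with a `suspect` flag and
a warning rather than clamped, because silent clamping destroys exactly
the evidence needed to diagnose the problem upstream.

The chlorophyll-*a*:carotenoid molar ratio uses 893.5 g/mol for
chlorophyll *a* and — because fucoxanthin dominates the diatom
carotenoid pool — fucoxanthin's 658.9 g/mol as the carotenoid proxy;
both are arguments for other pigment pools. Two normalisation routes to
dry weight are supported, direct weighing (biomass in the extract
record) and OD-calibrated biomass via `od_to_dw`, since instruments and
labs differ in which of the two they log; the OD→DW slope is a
configuration parameter (default 0.3 g DW L⁻¹ per OD625 unit, a typical
value for *P. tricornutum* in f/2 medium) because published campaigns
report the calibration only graphically.

## Growth metrics

The specific growth rate is the OLS slope of ln OD625 against time.
The default exponential window keeps points with OD at or below half
the series maximum — a simple rule that excludes the saturating tail —
and falls back to the whole series when fewer than two points qualify
(e.g. flat series), so a constant culture cleanly yields μ = 0. An
explicit `(t_min, t_max)` window overrides the rule. Lethality is
`100·(1 − treated/control)` on cells or colonies plated identically;
whether counts are per-cell or per-colony is the caller's convention,
as the arithmetic is the same.

The DPA dose-response summary fits μ per dose (averaging replicate
curves), classifies `declines` iff μ < 0, and reports the largest dose
still compatible with growth. Exactly at the zero-growth boundary dose
(40 µM under default calibration) the classification of noisy data is a
coin flip by construction; the noiseless calibration puts it on the
`grows` side (μ = 0).

## The screen

Stage order: colony quantile filter → fluorescence thresholds →
carotenoid gain → stability.

* **Colony stage.** The bench operation "pick large, deeply coloured
  colonies" is made reproducible as an inclusive double-quantile filter
  (defaults: top 20 % by size and by colour). Inclusive thresholds make
  ties deterministic without arbitrary tie-breaking.
* **Fluorescence stage.** Replicate reads are averaged per strain
  first (triplicates are the intended design), then both inequalities
  `RFU_chla ≥ 2309·OD − 24.3` and `RFU_nr ≥ 167.1·OD − 0.21` must hold;
  the boundary is inclusive, matching the printed inequalities. AND was
  chosen over OR as the stricter reading of "screened via both
  equations"; the decision trace records each rule's margin separately,
  so an OR policy is recoverable from the same report. Rows with
  missing or non-positive OD are rejected with a warning; NA
  fluorescence cells are excluded from the replicate mean with a
  warning rather than dropping the strain — auditability over silent
  exclusion.
* **Carotenoid stage.** Keep strains with extraction-grade total
  carotenoids ≥ 1.15 × WT.
* **Stability.** A strain is stable iff its content changed < 10 %
  over the repeated-batch series; a final value within 10 % of the WT
  level also raises a reversion flag (the signature of a heterozygous
  mutation resolving back to wild type in this diploid).

Stage survivor sets are nested by construction and every exclusion
carries its stage and rule.

## Synthetic campaign generator

The generator's defaults are the campaign conditions the package is
tested under:

| parameter | default | meaning |
|---|---|---|
| `wt_car` | 10.3 mg/g DW | wild-type total carotenoids |
| lethality | 0.423 / 0.715 (EMS 0.1/0.2 M), 0.369 / 0.658 (NTG 0.1/0.2 mM) | binomial survival of treated cells |
| carotenoid effect | truncated normal, centre `wt_car − 0.3`, SD 0.6, truncated to the per-dose range (e.g. 8.8–11.1 mg/g for 0.1 M EMS) | most mutations mildly deleterious, right tail up to the observed dose-group maximum |
| `chl_per_car` | 1.831 (mass) | puts the chl:car molar ratio at ≈ 1.35, inside the observed 1.27–1.42 band |
| `od_dw_coeff` | 0.3 g DW/L per OD | biomass calibration |
| `od_base` | 0.15 (exponential) / 0.60 (stationary) | per-well OD625 |
| `rfu_chl_per_mg_l`, `rfu_nr_per_unit_l` | 400, 580 | instrument gains, chosen so the expected WT signal sits a few percent above the screening threshold lines at the exponential-phase OD — the screen must pass above-average strains, so the thresholds must sit just below the typical regression line |
| target R² | 0.8687 / 0.6356 (exponential, chl / Nile red); 0.55 / 0.30 (stationary) | correlation strength of replicate-mean RFU vs carotenoid content |
| `unstable_fraction` | 0.2 | strains whose phenotype decays back to WT |
| `mu0_wt` | 0.645 day⁻¹ | untreated growth rate |

The reported correlation strength is treated as a coefficient of
determination (R²), not a raw r: the source material labels it a
coefficient of determination in its supplementary regressions, and the
generator documents rather than hides that reading.

**Noise calibration.** Fluorescence is `gain · content · dw + ε` with
`dw = od · od_dw_coeff` and Gaussian instrument noise ε. Because the
screening regressions are fit on triplicate means, the calibration
solves for the per-well SD that delivers the target R² *after*
averaging n replicates: total per-well noise variance
`V = n·(slope·σ_car)²·(1−R²)/R²`, from which the multiplicative OD
pipetting noise (log-normal, σ = 0.01) already contributes
`(slope·σ_od)²·E[car²]`; the additive SD makes up the remainder. With
100 strains the refit R̂² then lands within ±0.05 of target (Monte
Carlo: mean 0.860, SD 0.024 over 20 seeds — the residual ≈ 0.009
shortfall is the small-sample bias of R̂² itself) and the slope within
5 % at typical seeds (relative SD 3.5 %). The Nile-red channel is
configured much noisier (R² 0.6356), so equivalent recovery tolerances
require proportionally more strains; its test uses 400.

**Dose-response form.** μ(dose) is piecewise-linear through the three
observed anchors — (0 µM, μ₀), (10 µM, μ₀·0.431/0.645), (40 µM, 0) —
with the last segment extrapolated beyond 40 µM, giving net decline at
higher doses. No particular curve family is claimed; the anchors are
the data.

**OD noise is multiplicative log-normal** (keeps OD positive), RFU
noise additive Gaussian (instrument counts can dip below zero after
blank subtraction). The phase effect is implemented purely as larger
noise SD and higher OD in stationary phase; no mechanistic model of
stationary physiology is attempted.

**Stability series.** Stable strains drift by a truncated-normal
fraction (SD 3 %, hard bound ±9 %), which *guarantees* the < 10 %
stability criterion rather than satisfying it with high probability —
the generator's stable flag is a ground-truth label, so the emulation
must be consistent with it by construction. Unstable strains decay
exponentially toward the WT level (rate 0.5 per batch, 8 batches ≈ two
months of weekly re-seeding ≈ 16 generations), reproducing trajectories
like 13.3 → ≈ 10.3 mg/g.

**Absorbance inversion.** The two pigment equations are
underdetermined in (A665, A652, A470); the generator pins the
A652/A665 ratio (default 0, configurable up to the invertibility limit
15.65/7.34) so quantification of noiseless output reproduces the input
exactly — the basis of the round-trip property tests.

What the generator does **not** emulate: plate-position effects,
instrument drift between reads, pigment photodegradation during
handling, non-linear fluorescence quenching at high OD, or correlated
(non-Gaussian) replicate errors. Tests passing on this generator show
the *arithmetic and decision logic* are correct under the configured
statistical structure, not that a real campaign's data meet that
structure.

## Flux sampling and correlation

Models are dense stoichiometric systems (the intended scale is
desk-size networks; genome-scale SBML loads via cobrapy but sampling
cost grows with the null-space dimension). The sampler is an
artificially-centered hit-and-run walk in the null-space
parameterisation `v = v0 + N·z`: `N` is an orthonormal basis of the
null space of S *augmented with identity rows for fixed-bound
reactions* (otherwise every chord through a lb = ub coordinate has zero
length and the walk cannot move), so every iterate satisfies steady
state to machine precision by construction and only the box bounds
enter the chord search. `v0` is a maximal-slack interior point from a
Chebyshev-style LP, refined by a least-squares projection onto the
steady-state subspace. Directions pass through the running sample
centre via a uniformly chosen previous iterate (isotropic fallback
while the history is degenerate); the direction pool is capped at 500
iterates by random replacement. Defaults: burn-in 1000, thinning 100.
On the packaged network the per-reaction correlation estimates at
n = 1000 have cross-seed SD ≈ 0.02, slightly below the i.i.d. bound —
mixing is not a limiting factor at this scale. A degenerate polytope
(point) is handled explicitly: all samples equal `v0`.

Correlations are Pearson (the relationship screened for is linear);
reactions with numerically zero flux variance are flagged `constant`
and classified uncorrelated, and a zero-variance *target* is an error
suggesting bound relaxation. Classification: positive iff
r ≥ threshold, negative iff r ≤ −threshold, default threshold 0.7 —
the field has no canonical cutoff, so the raw r column always travels
with the report and counts can be recomputed at any threshold
(`threshold = 1.0` is allowed to isolate exact couplings). The
published genome-scale counts of correlated reactions depend on bounds
and threshold settings that are not public, so the package asserts the
qualitative structure on its own network rather than those counts.

**The packaged toy network** encodes the precursor-sharing structure of
diatom pigment/lipid metabolism: GA3P and pyruvate feed DXP synthesis;
a committed step converts DXP to GGPP with *fixed* bounds (lb = ub = 1),
making GGPP a constant pool split between the fucoxanthin branch
(phytoene synthase → fucoxanthin synthesis → export) and the
chlorophyll-*a* branch (geranylgeranyl reductase; chlorophyllide +
phytyl-PP → chlorophyll *a*); pyruvate independently feeds pyruvate
dehydrogenase → fatty-acid elongation; a disconnected
import/export pair serves as an independence control. Fixing the GGPP
supply is a deliberate design choice: it makes every correlation sign
analytic (fucoxanthin branch +1, chlorophyll branch and GA3P uptake
−1, lipid branch and control ≈ 0, upstream committed steps
zero-variance), so the correlation machinery is tested against exact
expectations. It deliberately does *not* reproduce the positive
chlorophyll–fucoxanthin correlations reported for the genome-scale
model, where precursor supply is not fixed.

## Numerical choices

* Boundary comparisons in the screen are inclusive (≥), evaluated on
  replicate means in double precision; exact-equality behaviour is only
  meaningful for single replicates or exactly representable means.
* Steady-state residual tolerance 1e-8 (achieved ~1e-14 by
  construction); bound violations beyond 10 ulp of the bound scale are
  an error, smaller ones are clipped.
* Blocked reactions are detected by per-reaction flux-variability LPs
  (HiGHS) with |flux| ≤ 1e-9 ⇒ blocked.
* Constant-flux detection for correlation uses SD ≤ 1e-12 × column
  scale.
* Seeds: every stochastic function takes an explicit seed; a fixed seed
  yields byte-identical output (numpy `default_rng`).

## Problem sizes in the shipped tests

Unit and property tests run campaigns of 200–1000 strains, refits on
100 (chlorophyll) / 400 (Nile red) strains, and flux chains of up to
5000 retained samples (thinning 100) on the 16-reaction network; the
acceptance script uses a 1000-strain campaign and 5000 flux samples.
These sizes were chosen so each statistical assertion has comfortable
power at its stated tolerance.

## Known limitations

* The TSV model dialect supports irreversible-style equations with
  bounds carrying reversibility; compartments are inferred from the
  metabolite-id suffix convention (`_c` etc.) only when exporting to
  cobra.
* The hit-and-run sampler materialises a dense null-space basis —
  appropriate up to perhaps a few hundred reactions, not genome scale;
  for genome-scale work, sample with cobrapy (`OptGPSampler`) and feed
  the resulting frame to the correlation step.
* Growth fitting assumes a single exponential phase; no lag or
  logistic model is attempted.
* The screen's colony stage models the manual bench step as a score
  filter; it is not an image-analysis tool.
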
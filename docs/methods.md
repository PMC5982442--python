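# Methods

`monoflux` implements the computational chain of a rain-exclusion experiment
on intact grassland monoliths: closed-chamber CO₂ flux derivation,
light-response fitting, normalized-flux resilience metrics, ¹⁵N tracer
accounting, canopy and water bookkeeping, and permutation-based factorial
inference. This note records the models, the defaults and why, and what the
synthetic-data tests do and do not demonstrate.

## Chamber fluxes

A closed transparent chamber (right cylinder, default diameter 0.25 m,
height 0.50 m) is placed on a monolith for ~1 min, logging CO₂ every 5 s
(13 samples). The mixing-ratio slope `b` (ppm s⁻¹) is estimated by ordinary
least squares after discarding a start deadband (default 10 s, which removes
placement disturbance). The areal flux is

    F = b · P / (R·T) · (V/A)   [µmol m⁻² s⁻¹]

with `P` the air pressure (default 101 325 Pa), `T` the measured chamber
air temperature, and `V/A` the effective chamber height. The conversion uses
the ideal gas law for dry air; no water-vapour dilution correction is
applied (a known limitation — the geometry accepts an additive headspace
height for enclosures that extend above the canopy surface, default 0).

Quality control replaces visual inspection with objective criteria: a fit
passes when at least `min_points` (default 8) samples remain and either
r² ≥ 0.90 or the fitted concentration change over the enclosure is at most
`low_signal_ppm` (default 5 ppm ≈ a 2 µmol m⁻² s⁻¹ flux for the default
geometry — a flux-detection limit). The second clause matters: an r²-only
rule systematically rejects valid small fluxes (NEE ≈ 0 when GPP ≈ ER,
exactly the situation at peak drought), biasing retained fluxes away from
zero and, worse, preferentially discarding the peak-drought occasion. The
5-ppm default is sized so that, at sub-ppm instrument noise, the two
acceptance clauses meet with no gap between them: changes small enough to
fail r² are small enough to keep as near-zero fluxes. A series with
literally zero CO₂ variance has undefined r² and is rejected as
`no_signal`.

Sunlit and dark enclosures of the same monolith within `max_gap_min`
(default 30 min) are paired; NEE comes from the sunlit chamber (negative =
uptake), ER from the dark chamber (positive), and GPP = ER − NEE. Negative
ER or GPP is flagged, never clipped. A measurement day enters the analysis
only if every land-use × treatment cell has ≥ 3 QC-passing records that day.

## Light response and GPP_sat

Per land-use × treatment group, pooled (GPP, PFD) pairs are fitted with the
rectangular hyperbola

    GPP(PFD) = α·PFD·p_max / (α·PFD + p_max)

by bounded nonlinear least squares (initialization: α from the three
lowest-PFD points, p_max at 1.2× the observed maximum). Fluxes measured at
PFD ≥ 1000 µmol m⁻² s⁻¹ are treated as light-saturated (GPP_sat); the fit
table reports the fraction of `p_max` reached at the threshold so the
adequacy of that cutoff can be judged on any dataset. Note that pooled fits
for drought groups conflate light limitation with the drought signal (as
they would with real pooled data spanning the drought); only control-group
fits are expected to recover the generator's α and p_max.

## Resilience metrics

Daily group means of GPP_sat and ER in the drought treatment are divided by
the matching control means (ratio of group means, not mean of per-monolith
ratios — more robust when control values are small; the choice is logged).
From the normalized series:

* **Resistance** RST = drought/control at the peak-drought occasion, defined
  as the last retained measurement day inside the rain-exclusion window.
* **Recovery index** = D_rec/C_rec − RST, with the recovery occasion for
  fluxes the mean over a configurable post-rewetting window (default the
  first ~2.5 weeks) and for harvest parameters the first recovery campaign.
  Control values at the recovery occasion (not pretreatment values) are
  used, so seasonal drift in the controls cancels.
* **Response trajectory**: the date-ordered path of daily
  (normalized GPP_sat, normalized ER) points. Segment Euclidean distances
  measure change between occasions; their cumulative sum from the
  pretreatment start measures the overall perturbation. Length is
  translation invariant and homogeneous under scaling, and removing an
  intermediate point can only shorten it (triangle inequality) — all
  property-tested.

Harvest bookkeeping: LAI = Σ groups leaf_biomass/1000 × SLA; community
weighted mean SLA weights each functional group's SLA by its leaf-biomass
share. Both are invariant to splitting a group at identical SLA.

## ¹⁵N tracer accounting

δ¹⁵N (‰ vs AIR-N₂, R_std = 0.0036765 — configurable, as conventions for the
standard ratio differ in the last digit) converts to atom% via
R = R_std(δ/1000 + 1), atom% = 100R/(1+R). Incorporated label is
(atom%_labelled − atom%_NA)·N_pool/100 with atom%_NA the mean of paired
unlabelled samples of the same tissue, and N_pool = N concentration × dry
mass per area. Dividing by the label applied per monolith (default 2 mg
¹⁵N over a 0.0491 m² core) gives recovery fractions. The applied amount is
a direct input rather than being derived from salt mass and enrichment.

## Water balance

ET over a period = water inputs − leachate − Δstorage, with Δstorage =
Δθ/100 × effective depth. The default depth is the monolith height
(280 mm); the representative sensor depth is genuinely uncertain, so it is
configuration, not a constant. Negative ET or leachate exceeding inputs is
flagged as physically suspect, not raised.

## Permutation inference

Two-factor (treatment × land use) ANOVA F statistics use sequential sums of
squares. Main-effect p-values permute raw observations; the interaction
uses the Freedman–Lane scheme (permute residuals of the additive fit, add
back the additive fitted values, recompute the interaction F), the standard
exchangeability-respecting choice. Within-land-use drought tests are
two-sample permutation tests on the mean difference, which orders
rearrangements identically to the one-way F because the total sum of
squares is permutation-invariant. Exhaustive enumeration is used
automatically when the number of distinct rearrangements is ≤ `n_perm`
(default 4999); otherwise p = (1+count)/(1+n_perm), so p ≥ 1/(n_perm+1).
Type-I error under a null 2×2 simulation is verified to sit in the binomial
99% band around 0.05 for all three factors. Block structure is ignored by
default; the monolith is the experimental unit.

## Synthetic experiment generator

The generator is first-class, tested code: it emulates the design (two land
uses × two treatments × 6 blocks, rain exclusion 21 May–28 Jun 2014,
measurement calendar spanning pretreatment/drought/recovery, three harvest
campaigns) with known parameters, and `ground_truth()` returns closed-form
noise-free values of every index the pipeline estimates.

Dynamics (drought/control ratio, per land use): during rain exclusion both
fluxes decline linearly from 1 to the configured resistance, reaching it at
the last scheduled measurement inside the window — so the configured
resistance is exactly the value the pipeline's peak-drought occasion should
recover. After rewetting GPP_sat relaxes to 1 by first-order decay with the
configured half-time; ER jumps to an overshoot ratio ≥ 1 (the rewetting
respiration pulse) and decays back with the same half-time. First-order
decay was chosen over richer saturating forms because the half-time is then
exact by construction and every index has a closed form. Harvest pools
decline to their own resistance ratios by rewetting and relax with a slower
half-time; stem/reproductive scaling is solved from the configured leaf
(LAI) and total-biomass resistances.

Defaults are the study conditions: GPP_sat resistance 0.2 (meadow) / 0.4
(abandoned); ER resistance 0.4 / 0.75; recovery half-times 3 / 6 days
(consistent with full GPP_sat recovery within ~9 days and a faster meadow
recovery rate); ER overshoot 1.3 / 1.15; a +110% meadow shoot-label pulse;
baseline p_max 25 / 18 and ER 8 / 6 µmol m⁻² s⁻¹; control irrigation
180 / 170 mm. Magnitudes that no report states were fixed once at
field-plausible values and documented here rather than tuned:
`noise_sd_ppm` 0.5 (instrument noise on 5-s logged readings),
`block_sd` 0.15 (lognormal between-monolith multiplier, shared by a
monolith's fluxes, biomass and pools), `isotope_delta_sd` 0.3‰.

What the generator does *not* emulate: weather-driven day-to-day flux
variability, seasonal phenology in the controls, diffusion-induced
nonlinearity of chamber ramps, soil ¹⁵N pools and mineralization, LNC
dynamics, and species turnover. Passing parameter-recovery tests therefore
demonstrates the correctness of the estimators under the stated noise
model, not robustness to every failure mode of field data.

Soil-moisture traces keep controls above the 25 vol.% watering threshold;
the drought decline within the window is rendered noise-free (a smoothed
sensor record) so its monotonicity is structural.

## Numerical choices and degenerate inputs

* Slope fits with < 2 points after the deadband or zero time variance raise
  a degenerate-fit error; exactly flat series QC-fail with `no_signal`.
* Light-response fits refuse < 4 points, spread-less PFD, or all-zero GPP,
  and report non-convergence rather than defaulting.
* Normalization raises (naming date and variable) on non-positive control
  means, and drops dates present in only one treatment with a log entry.
* Permutation F statistics treat sums of squares below a ‖y‖²-relative
  tolerance (1e-9) as zero, so a constant response yields F = 0, p = 1
  instead of floating-point noise.
* p-value comparisons use a relative 1e-12 tolerance, keeping them
  invariant under affine transformations of the response.

## Problem sizes

The shipped test suite runs the full pipeline over 200 generator seeds for
parameter recovery, 200 seeds for light-response recovery at n = 50, and
2000 null datasets × 999 permutations for calibration — sizes chosen so the
Monte-Carlo bands in the assertions are meaningful while the whole suite
stays fast (≈1 min single-core). The acceptance script runs one full
pipeline plus a 1000-dataset calibration in a few seconds.

## Known limitations

* No water-vapour dilution or pressure-vent correction in the flux
  conversion; no nonlinear (saturating) chamber accumulation model.
* Ratio-of-means normalization is a choice, not the only defensible one;
  per-block ratios would weight monoliths differently.
* The recovery occasion is configuration; reported recovery indices depend
  on it and should be quoted with it.
* lmPerm-style sequential stopping p-values are deliberately not
  reproduced; fixed `n_perm` with a guaranteed floor is easier to reason
  about and to seed.
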
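# monoflux

Closed-chamber CO₂ flux derivation and drought-resilience metrics for
grassland monolith experiments.

## The problem

Rain-exclusion experiments on intact vegetation–soil monoliths ask how land
use changes a grassland's response to drought: how far carbon fluxes are
suppressed (**resistance**), how they return after rewetting (**recovery**),
and how large the overall excursion is. Answering that from raw field data
requires a chain of derivations — chamber concentration ramps → quality
controlled fluxes → light-saturated GPP → normalized drought/control ratios
→ resilience indices — plus ¹⁵N tracer budgets, canopy/water bookkeeping and
permutation tests. `monoflux` implements that chain as a tested, reusable
pipeline for ecosystem ecologists, together with a synthetic-experiment
generator whose ground truth is known in closed form, so every estimator is
verifiable by parameter recovery.

## The core quantities

* **Chamber flux**: OLS slope *b* (ppm s⁻¹) of the enclosure CO₂ ramp,
  converted by the ideal gas law, F = b·P/(R·T)·(V/A) in µmol m⁻² s⁻¹.
  NEE from sunlit chambers (negative = uptake), ER from darkened chambers
  (positive), and GPP = ER − NEE.
* **Light response**: GPP(PFD) = α·PFD·p_max/(α·PFD + p_max), the
  rectangular hyperbola with initial slope α and asymptote p_max; fluxes at
  PFD ≥ 1000 µmol m⁻² s⁻¹ are light-saturated (GPP_sat).
* **Resistance**: RST = drought/control ratio of daily group means at peak
  drought. **Recovery index**: D_rec/C_rec − RST. **Perturbation**: the
  cumulative Euclidean length of the daily trajectory in normalized
  (GPP_sat, ER) space.
* **¹⁵N budget**: atom% = 100·R/(1+R) with R = R_std(δ/1000+1);
  incorporated ¹⁵N = (atom%_labelled − atom%_NA)·N_pool/100.
* **Inference**: two-factor permutation ANOVA (Freedman–Lane interaction)
  and within-land-use two-sample permutation tests.

## Worked example

Simulate the default experiment (two land uses × control/drought × six
blocks, rain exclusion 21 May – 28 Jun 2014) and compute the resilience
summary:

```python
import monoflux as mf

cfg = mf.PipelineConfig(synthetic=mf.ExperimentConfig(seed=42), run_stats=False)
result = mf.run_pipeline(cfg)
print(result.tables["resilience_summary"]
      [["parameter", "land_use", "resistance", "recovery_index"]]
      .round(3).to_string(index=False))
for lu, traj in sorted(result.trajectories.items()):
    print(f"{lu}: cumulative trajectory length = {traj.cumulative_length:.3f}")
```

prints

```
parameter  land_use  resistance  recovery_index
  gpp_sat abandoned       0.556           0.240
       er abandoned       0.832           0.246
  gpp_sat    meadow       0.402           0.536
       er    meadow       0.580           0.549
      lai abandoned       0.817           0.125
  biomass abandoned       0.867           0.101
      lai    meadow       0.651           0.288
  biomass    meadow       0.743           0.238
abandoned: cumulative trajectory length = 1.259
meadow: cumulative trajectory length = 1.945
```

Reading: at peak drought the meadow's light-saturated GPP fell to ~40% of
the controls in this noisy replicate (the configured truth is 20%; the
drought monoliths of this seed happened to be unusually productive) while
the abandoned grassland kept ~56%; the meadow recovers more strongly
(higher recovery index) and traces the longer path through the normalized
flux space — lower resistance, higher recovery, larger overall
perturbation. Per-seed estimates scatter around the configured truth; the
parameter-recovery tests quantify that over 200 seeds.

The same run is available from the shell:

```sh
monoflux simulate --seed 42 --out data/        # write input tables
monoflux all --seed 42 --out results/          # full pipeline + stats
```

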
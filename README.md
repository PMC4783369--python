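# leaftrack

Image-based measurement of leaf elongation in monocot plants (wheat, barley,
ryegrass and other graminoids), built for field rigs in which each growing
leaf tip is connected by a thread to a white marker bead riding a vertical
rail on a black panel. A camera photographs the panel every two minutes;
because grass leaves elongate from a basal growth zone, the bead's upward
travel equals the whole leaf's elongation. `leaftrack` turns those image
sequences into millimetre-resolution elongation series and
genotype-by-temperature growth statistics, and ships a synthetic rig
simulator so the entire chain is testable without a camera.

## Who it is for

Plant physiologists and breeders measuring leaf elongation rate (LER) *in
situ* — especially near the thermal limit of growth, where rates of a few
tenths of a millimetre per hour must be separated from rig drift and sensor
noise.

## Method

1. **Tracking.** Each bead is localized per frame by zero-normalized
   cross-correlation (ZNCC) against a fixed template cut from the seeding
   frame, refined to sub-pixel precision (upsampled Fourier
   cross-correlation by default; a 3×3 paraboloid fit is available). A
   localization with correlation coefficient CC < 0.5 is marked *lost*,
   excluded downstream, and re-acquired in later frames with a widened
   search region.
2. **Rectification.** A single checkerboard image (square size 45.5 mm) in
   the bead plane calibrates a plane-to-plane projective transform plus one
   radial lens-distortion coefficient; tracked pixel positions map to
   metric panel coordinates.
3. **Displacement.** A second-order polynomial is fitted to all positions
   of each bead; positions are orthogonally projected onto it and
   displacement is the signed arc length along the curve (closed form).
   The mean displacement of reference beads (threads anchored to the
   ground) is subtracted to remove thread stretch and wind-induced drift.
4. **Growth statistics.** LER = ΔL/Δt per clock-aligned hourly interval;
   temperature response LER = a·(T − i) fitted per leaf with the anchor
   i = 0 °C (or free, yielding the base temperature T_b as the
   x-intercept); thermal-time correction LER − aT; genotype comparison by
   one-way ANOVA on per-leaf slopes with Tukey–Kramer HSD letter groups.

## Worked example

A synthetic two-day study: three barley-like genotypes with temperature
sensitivities a = 0.10, 0.06, 0.08 mm h⁻¹ °C⁻¹, seven leaves each, on a
24-rail panel under a 2–16 °C diurnal course, rendered to frames and pushed
through the complete chain (track → rectify → arc length → drift correction
→ hourly LER → per-leaf response fits → ANOVA/HSD):

```python
from leaftrack import (RigConfig, SceneSpec, GrowthParams,
                       generate_experiment)
from leaftrack.growth_stats import tukey_letters
from leaftrack.pipeline import run_growth_study

rig = RigConfig(n_positions=24, n_reference=3, frame_interval_s=1800.0)
scene = SceneSpec(drift_amp_mm=(0.15, 0.08))
genotypes = {"Ascona-like": GrowthParams(0.10, ler_noise_sd_mm_per_h=0.05),
             "Eunova-like": GrowthParams(0.06, ler_noise_sd_mm_per_h=0.05),
             "Quench-like": GrowthParams(0.08, ler_noise_sd_mm_per_h=0.05)}
bundle = generate_experiment(rig, genotypes, n_leaves=7, days=2.0,
                             t_min=2.0, t_max=16.0, scene=scene, seed=0)
result = run_growth_study(bundle)
print(tukey_letters(result.slopes_by_genotype).summary())
```

prints

```
Genotype comparison of temperature sensitivity (slope a)
----------------------------------------------------------
one-way ANOVA: F = 12990.344, p = 3.655e-29
Tukey-Kramer HSD at alpha = 0.05:
  Ascona-like  mean a = 0.0998  n = 7   group a
  Quench-like  mean a = 0.0796  n = 7   group b
  Eunova-like  mean a = 0.0601  n = 7   group c
```

The per-leaf slopes recovered from the rendered images are within a few
percent of the generating values (0.10/0.08/0.06), the ANOVA rejects slope
equality overwhelmingly, and the letter display separates all three
genotypes — the sensitivity the rig design needs to rank varieties in a
week-long field deployment.

## Command line

```sh
leaftrack simulate --genotypes gtA:0.06,gtB:0.08,gtC:0.10 --leaves 7 --days 2
leaftrack run-all            # calibrate -> track -> ler -> respond
leaftrack verify             # stepwise accuracy experiment, prints metrics
```

Each stage writes headered CSVs (tracking, displacement, LER, response) and
JSON-lines logs with per-stage timings, CC distribution summaries and lost
frame counts, so any stage can be re-run from its upstream files alone.

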
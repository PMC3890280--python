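# myoviability

Quantitative scoring of ischemic skeletal-muscle injury from
NADH-tetrazolium-reductase (NADH-TR) stained cross-sections.

The NADH-TR reaction deposits blue-purple formazan wherever fiber
mitochondria are still functional, so the stained area of a muscle
cross-section is a direct readout of tissue viability. This package
implements the full measurement chain used to score hind-limb
ischemia(-reperfusion) injury in rodent muscle:

* **segmentation** — formazan-positive pixels by an inclusive RGB box
  threshold (defaults red 160/0, green 130/0, blue 175/66), fiber area by a
  luminance cutoff against the pale interstitium, and object-level fiber
  typing (intensely stained Type I vs lightly stained Type IIb) by an exact
  Otsu split of per-fiber stain densities;
* **morphometry** — per-field *muscle fiber viability*
  `V = area(positive ∩ fiber) / area(fiber)` (total and per fiber type),
  per-animal means over ten fields, and group mean ± s.e.m. after
  normalizing each measurement to its own untreated-control mean (controls
  are 100% by construction);
* **statistics** — Shapiro–Wilk normality, balanced two-way ANOVA
  (condition × measurement) with Scheffé post-hoc comparisons, and Pearson
  correlation of viability against ischemia duration;
* **synthetic histology** — a calibrated generator of NADH-TR-like sections
  (Voronoi fiber mosaics, two fiber types, spatially correlated patchy stain
  loss, illumination ramp and pixel noise) with per-pixel ground truth, so
  the whole chain is testable by parameter recovery: condition presets
  Control/4I/6I/8I/9I carry per-type stain retentions equal to the published
  group means of a rat aortic-occlusion study (e.g. 8 h ischemia: Type IIb
  0.291, Type I 0.201), and the pipeline must re-measure them.

Audience: experimental pathology / surgical-research groups doing
histochemical morphometry, and anyone needing a ground-truthed test bed for
area-fraction stain quantification.

## Worked example

Simulate a small study (3 control + 3 animals after 8 h ischemia, 4 fields
each at 256²) and push it through segmentation → morphometry → statistics:

```python
from myoviability import RunConfig, run_synthetic_study

result = run_synthetic_study(
    {"Control": 3, "8I": 3},
    config=RunConfig(fields_per_animal=4, seed=42),
    base_spec_overrides=dict(width_px=256, height_px=256,
                             n_fibers=28, interstitium_width_px=5.0),
)
print(result.group_summary.to_string(index=False))
```

```
condition measurement   mean_pct  sem_pct  n
  Control       total 100.000000 6.664598  3
  Control       type1 100.000000 6.760605  3
  Control      type2b 100.000000 6.603788  3
       8I       total  22.478476 2.368739  3
       8I       type1  17.995211 1.811679  3
       8I      type2b  26.613182 2.509576  3
```

The control rows are exactly 100 because each measurement is normalized by
its own control mean; the 8I group's recovered viabilities (total 22.5%,
Type I 18.0%, Type IIb 26.6%) re-estimate the generator's 8-hour presets
(24.3 / 20.1 / 29.1) from the rendered images alone — within the sampling
noise of three animals. Type I fibers read lower than Type IIb, the
oxidative-fiber vulnerability the presets encode.
`result.stats.posthoc` shows the Control-vs-8I Scheffé comparison
significant at p < 10⁻⁵.

The same pipeline runs on real micrographs via a CSV manifest
(`animal_id, condition, field_index, image_path[, labels_path]`):

```sh
myoviability synth --condition 8I --n-animals 6 --fields 10 --seed 1 --out data/8I
myoviability measure --manifest data/8I/manifest.csv --control-label Control --out results/
myoviability simulate-and-run --design "Control:6,4I:6,8I:6,9I:6" --seed 1 --out results/full
```

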
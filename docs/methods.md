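# Methods

## The measurement

NADH-tetrazolium-reductase (NADH-TR) histochemistry deposits blue-purple
formazan wherever mitochondria still reduce the tetrazolium salt, so on a
frozen cross-section of skeletal muscle the stained area marks metabolically
intact tissue. *Muscle fiber viability* is defined as an area fraction:

    viability(field) = area(formazan-positive ∩ fiber) / area(fiber)

computed per photographed field, averaged over the fields of one animal
(ten per animal by default), and finally expressed as a percentage of the
untreated control group's mean. The same ratio is computed within each fiber
type: mitochondria-rich Type I (slow oxidative) fibers stain intensely,
Type IIb (fast glycolytic) fibers lightly, and each type's viability is
normalized by its *own* control mean — which forces all three control means
to exactly 100.0 and makes the normalized numbers comparable across
measurements.

### Positive-stain segmentation

A pixel counts as formazan-positive iff each 8-bit channel lies inside an
inclusive interval; the defaults are red ∈ [0, 160], green ∈ [0, 130],
blue ∈ [66, 175] — low red and green with mid-to-high blue, i.e. the
blue-purple chromophore. Interval bounds are inclusive so the predicate is
unambiguous on integer data; enlarging any interval can only grow the mask
(tested as a superset property).

### Fiber-area segmentation

How the fiber outline (the denominator) is delineated is a genuinely open
design point; commercial morphometry packages do it interactively. We use a
luminance rule: a pixel is fiber tissue when its ITU-601 luma falls below
`cutoff_ratio` (default 0.92) times a reference white — the field's
99th-percentile luma, floored at 200 so that a field with no visible
interstitium is still treated as all tissue. A radius-2 morphological
closing and hole filling clean up stain texture; a minimum-object-size
filter exists but defaults to off. All parameters sit on
`FiberSegmentationParams`.

This assumes a bright, near-white interstitium/background (luma ≳ 200),
which holds for properly exposed brightfield micrographs and for the
synthetic renderer.

### Fiber typing

Typing is object-level, because fibers — not pixels — are categorized as
Type I or Type IIb. Per fiber instance we take the mean optical density
(255 − luma) over its positive pixels (all pixels as a fallback when a fiber
has none), then split the per-fiber means into two classes. The default
split is an exact 1-D Otsu: between-class variance is maximized over all
n−1 splits of the sorted sample, and the threshold is placed at the midpoint
of the optimal split, so the decision boundary sits centered in the
inter-class gap rather than on a histogram bin edge (which is where the
binned Otsu lands when the gap is wide). The denser class is Type I; ties at
the threshold go to Type I. A fixed-threshold mode exists for batch-matched
analyses.

Fiber instances come from a supplied instance raster when one exists
(synthetic ground truth, or an externally drawn annotation); otherwise they
are recovered by watershed on the distance transform of the fiber mask.
Pixels of the measured fiber mask that fall outside every instance (boundary
disagreements) inherit the nearest instance's type, so the two type masks
always partition the fiber mask exactly.

### Morphometry conventions

* A zero denominator (e.g. a field without Type I fibers) makes that
  measurement *undefined* for that field — it is excluded from the animal
  mean with a warning, never silently scored 0.
* Group summaries report mean ± s.e.m. with the sample SD (n−1).
* Normalization uses measurement-matched control means.

## The synthetic test bench

No raw micrographs accompany the study the presets describe, so correctness
is established on synthetic sections with per-pixel ground truth.

Geometry: `n_fibers` random centers, two Lloyd-relaxation passes (on a
stride-2 pixel grid), pixels assigned to the nearest center — a centroidal
Voronoi tessellation whose polygonal, close-packed cells resemble muscle
cross-sections. Pixels whose two nearest-center distances differ by less
than `interstitium_width_px` form the pale interstitial band.

Stain loss: one Gaussian random field per section, smoothed with
`patch_scale_px` (default 6 px), shared by all fibers. Within each fiber,
exactly the top `retention(type) × control_coverage` share of pixels by
field value keeps its stain. This yields focal, droplet-like loss; makes the
per-fiber stained fraction exact up to one pixel of rounding; and makes the
stained set *nested* in retention for a fixed seed (monotonicity is tested).

Rendering: stained pixels take the type's formazan color (Type I
(70, 60, 130), Type IIb (130, 110, 160)); unstained fiber pixels take a pale
tissue tone (210, 195, 200); interstitium is near-white (230, 225, 220).
The two stain colors satisfy the default positive predicate and the two
tissue tones fail it — validated at construction — so threshold segmentation
and ground truth agree by design. The unstained-fiber tone is deliberately
distinct from (darker than) the interstitium: a fiber that has lost its
stain is still tissue, still darker than empty background, and must remain
segmentable as fiber or the denominator of the viability ratio would
collapse in heavily injured sections. A multiplicative illumination ramp
(default ±3%) and per-channel Gaussian noise (default SD 4) are applied
last; ground truth is recorded pre-noise.

Defaults (512×512 px, 110 fibers → ≈ 49 px fiber diameter at the study's
600× magnification context, interstitium 6 px) were chosen once as
realistic; the field raster size is a free parameter since no pixel
calibration is published.

### Condition presets and calibration

Per-type stain retentions are the study's normalized group means / 100:

| condition | retention Type IIb | retention Type I |
|-----------|-------------------:|-----------------:|
| Control   | 1.000 | 1.000 |
| 4I        | 0.619 | 0.588 |
| 6I        | 0.464 | 0.395 |
| 8I        | 0.291 | 0.201 |
| 9I        | 0.155 | 0.095 |

The reperfusion groups have no published numbers; defaults are 8IR = the 9I
retentions (same injury level) and 9IR = one third of those (near-complete
loss), flagged `calibrated=False` on the spec object.

`p_type1 = 0.48`: the published total viability is the type-area-weighted
mean of the two per-type values; solving the weight from the four injured
groups' printed triplets gives 0.45/0.38/0.53/0.57, mean ≈ 0.48 — consistent
with the report that total viability behaves like the median of the two
types. `control_coverage = 0.9` (healthy fibers are nearly but not perfectly
formazan-covered); its exact value cancels in control normalization.

Note the source study's figure caption and results text disagree about which
fiber type suffered more damage; the printed means (Type I lower at every
duration) support the text, and the presets follow the means.

### Between-animal variability

Each injured animal draws one standard-normal severity score shared by both
fiber types, applied with SD 0.08 on the retention scale; a multiplicative
staining-coverage factor (SD 0.08) models batch staining variation for all
animals, controls included. Near the zero-viability floor the retention SD
shrinks by `min(1, preset/(2.5·SD))` so the draw stays centered on the
preset instead of piling against the clip at 0 (uncentered jitter would bias
the most injured group's recovered mean upward by ~2 normalized points).
These defaults reproduce group s.e.m. of ≈ 2–4 percentage points at n = 6,
the magnitude the published summaries show, including their smaller spread
in the most injured group.

What the generator does *not* emulate: freezing/cutting artifacts, uneven
staining batches beyond a scalar factor, out-of-focus blur, vessels and
nerve bundles, fiber-size differences between types. Passing recovery tests
therefore demonstrate the measurement chain's correctness and calibration on
idealized tissue, not robustness to real-world artifacts.

## Statistics

* Shapiro–Wilk per group × measurement (scipy's implementation).
* Balanced fixed-effects two-way ANOVA (condition × measurement) with
  interaction, from the classical sums-of-squares decomposition; every F is
  tested against the residual mean square. Unbalanced tables are rejected
  rather than approximated. One-way ANOVA serves single-measurement tables.
* Scheffé simultaneous pairwise comparisons between conditions:
  statistic (ȳᵢ−ȳⱼ)² / (MS_res(1/nᵢ+1/nⱼ)), significant above
  (k−1)·F_crit(k−1, df_res, α), p from the upper F tail of statistic/(k−1);
  condition marginals pool observations over measurements. α = 0.05.
* Pearson correlation of total viability against ischemia duration, both
  per animal and on group means (the published analysis does not say which
  was used, so both are reported).

A known sensitivity limit, found with this package's own simulation harness:
at the published group means with within-group SD reconstructed as
s.e.m.·√6, the 8 h-vs-9 h comparison has only ≈ 50% power under this
two-way + Scheffé analysis, so simulated studies flag *all* consecutive
durations in far fewer than 95% of runs (observed 0.385 over 200
simulations). The published significance for that pair is not recoverable
from the printed summary statistics alone — plausibly the original analysis
benefited from within-animal correlation between the three measurements,
which printed means and s.e.m. cannot convey.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawning (geometry, typing, patch field and
pixel noise are independent child streams), so reruns are bit-identical;
tabular outputs carry a hash of the run configuration.

The recovery experiment used by `scripts/acceptance.py` runs five
independent replicate studies of the published design (control + 4I + 8I +
9I, six animals × ten 512×512 fields per group) and averages the recovered
group means: a single study's group mean carries ≈ 2.5–4 points of sampling
SD at n = 6 by design, and replication separates calibration bias, which the
check is about, from single-draw luck. The in-suite recovery test uses three
replicates.
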
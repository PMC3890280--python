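"""Synthetic NADH-TR muscle cross-sections with per-pixel ground truth.

Real stained sections of rat anterior tibial muscle show close-packed
polygonal fibers separated by pale interstitium, with two intensity classes:
mitochondria-rich Type I fibers stain intensely blue-purple, Type IIb fibers
lightly.  Ischemia removes the formazan reaction in focal, droplet-like
patches, so a fiber's *stained area fraction* shrinks with injury.  The
generator emulates exactly that geometry and failure mode:

* fiber geometry: seeded random centers relaxed by a couple of Lloyd
  iterations, pixels assigned to the nearest center (a centroidal Voronoi
  tessellation), with an interstitial band carved along cell boundaries;
* fiber typing: Bernoulli(``p_type1``) per fiber;
* stain loss: one spatially correlated Gaussian random field per section
  (correlation length ``patch_scale_px``); within each fiber, exactly the
  top ``retention(type) * control_coverage`` fraction of pixels by field
  value keeps its stain, giving blob-shaped loss and per-fiber stained
  fractions that are exact up to pixel rounding — and monotone in retention
  for a fixed seed;
* rendering: stained pixels take the fiber type's formazan color, unstained
  fiber pixels a pale tissue color, interstitium near-white; a multiplicative
  illumination ramp and per-channel Gaussian noise are applied last.

Ground truth (instance raster, per-fiber types, stained raster, area
fractions) is recorded before noise, so downstream segmentation and
morphometry can be scored against it.

Condition presets encode a rat hind-limb ischemia study: 4, 6, 8 and 9 hours
of aortic occlusion (4I..9I), optionally followed by 2 hours of reperfusion
(8IR, 9IR), against untreated controls; per-type stain retentions are
calibrated to the study's group means (IR groups have no published numbers
and default to documented extrapolations, flagged uncalibrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .segmentation import ChannelThresholds, DEFAULT_THRESHOLDS, FieldImage

__all__ = [
    "SyntheticSectionSpec",
    "GroundTruth",
    "StudyField",
    "StudyAnimal",
    "CONDITIONS",
    "make_condition_preset",
    "generate_section",
    "generate_study",
]

# (retention_type2b, retention_type1) per condition; ischemia-only values are
# the study's normalized group means / 100.  IR retentions are extrapolations
# (8IR injured like 9I; 9IR near-complete loss) and are flagged uncalibrated.
CONDITION_RETENTIONS: dict[str, tuple[float, float]] = {
    "Control": (1.0, 1.0),
    "4I": (0.619, 0.588),
    "6I": (0.464, 0.395),
    "8I": (0.291, 0.201),
    "9I": (0.155, 0.095),
    "8IR": (0.155, 0.095),
    "9IR": (0.155 / 3, 0.095 / 3),
}
CONDITIONS = tuple(CONDITION_RETENTIONS)
_CALIBRATED = {"Control", "4I", "6I", "8I", "9I"}

#: ischemia duration in hours per condition (reperfusion time not counted)
CONDITION_DURATIONS_H: dict[str, float] = {
    "Control": 0.0, "4I": 4.0, "6I": 6.0, "8I": 8.0, "9I": 9.0,
    "8IR": 8.0, "9IR": 9.0,
}


@dataclass(frozen=True)
class SyntheticSectionSpec:
    """Full parameterization of one simulated stained section."""

    width_px: int = 512
    height_px: int = 512
    n_fibers: int = 110
    interstitium_width_px: float = 6.0
    p_type1: float = 0.48
    stain_color_type1: tuple[int, int, int] = (70, 60, 130)
    stain_color_type2b: tuple[int, int, int] = (130, 110, 160)
    background_color: tuple[int, int, int] = (230, 225, 220)
    unstained_fiber_color: tuple[int, int, int] = (210, 195, 200)
    retention_type1: float = 1.0
    retention_type2b: float = 1.0
    control_coverage: float = 0.9
    patch_scale_px: float = 6.0
    noise_sd: float = 4.0
    illumination_gradient: float = 0.06
    seed: int = 0
    condition: str | None = None
    calibrated: bool = True

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.n_fibers <= 0:
            raise ValueError("raster size and n_fibers must be positive")
        for name in ("retention_type1", "retention_type2b", "p_type1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.control_coverage <= 1.0:
            raise ValueError("control_coverage must lie in (0, 1]")
        if self.interstitium_width_px < 0 or self.noise_sd < 0:
            raise ValueError("interstitium width and noise SD must be non-negative")
        if not 0.0 <= self.illumination_gradient < 1.0:
            raise ValueError("illumination_gradient must lie in [0, 1)")
        if self.patch_scale_px <= 0:
            raise ValueError("patch_scale_px must be positive")
        for name in ("stain_color_type1", "stain_color_type2b",
                     "background_color", "unstained_fiber_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not 0 <= c <= 255 for c in col):
                raise ValueError(f"{name} must be an RGB triplet in [0,255]^3")
        # Consistency with the default positive predicate: stain colors must
        # count as positive, tissue background must not, so ground truth and
        # threshold segmentation agree by construction.
        thr = DEFAULT_THRESHOLDS
        for name in ("stain_color_type1", "stain_color_type2b"):
            if not thr.contains(getattr(self, name)):
                raise ValueError(f"{name} does not satisfy the positive-stain predicate")
        for name in ("background_color", "unstained_fiber_color"):
            if thr.contains(getattr(self, name)):
                raise ValueError(f"{name} must not satisfy the positive-stain predicate")


@dataclass
class GroundTruth:
    """Pre-noise truth for one synthetic field."""

    fiber_label_raster: np.ndarray  # 0 = interstitium, k>0 = fiber k
    fiber_types: dict[int, str]  # fiber id -> "TypeI" | "TypeIIb"
    stained_raster: np.ndarray  # bool
    true_total_fraction: float
    true_type1_fraction: float  # nan when no Type I pixels exist
    true_type2b_fraction: float

    def recompute_fractions(self) -> tuple[float, float, float]:
        """Pixel-count oracle: fractions recomputed from the stored rasters."""
        labels = self.fiber_label_raster
        fiber = labels > 0
        type1 = np.zeros(int(labels.max()) + 1, dtype=bool)
        for k, t in self.fiber_types.items():
            type1[k] = t == "TypeI"
        t1 = fiber & type1[labels]
        t2 = fiber & ~type1[labels]
        stained = self.stained_raster

        def frac(num_mask, den_mask):
            den = int(den_mask.sum())
            return float((num_mask & stained).sum() / den) if den else float("nan")

        return frac(fiber, fiber), frac(t1, t1), frac(t2, t2)


def make_condition_preset(condition_name: str, **overrides) -> SyntheticSectionSpec:
    """Spec preset for one experimental group.

    Retentions for the ischemia-only groups are the study's normalized group
    means / 100; Control is (1, 1) by definition.  ``overrides`` are passed
    through to :class:`SyntheticSectionSpec` (so IR retentions can be set
    explicitly)."""
    if condition_name not in CONDITION_RETENTIONS:
        raise ValueError(
            f"unknown condition {condition_name!r}; valid labels: {', '.join(CONDITIONS)}"
        )
    r2b, r1 = CONDITION_RETENTIONS[condition_name]
    kwargs = dict(
        retention_type2b=r2b,
        retention_type1=r1,
        condition=condition_name,
        calibrated=condition_name in _CALIBRATED,
    )
    kwargs.update(overrides)
    return SyntheticSectionSpec(**kwargs)


def _fiber_geometry(spec: SyntheticSectionSpec, rng: np.random.Generator) -> np.ndarray:
    """Centroidal Voronoi fiber instances with an interstitial boundary band."""
    h, w, n = spec.height_px, spec.width_px, spec.n_fibers
    centers = np.column_stack([rng.uniform(0, h, n), rng.uniform(0, w, n)])
    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])

    coarse = pts.reshape(h, w, 2)[::2, ::2].reshape(-1, 2)  # stride-2 grid suffices for centroids
    for _ in range(2):  # Lloyd relaxation for evenly sized polygons
        assign = cKDTree(centers).query(coarse, k=1)[1]
        sums_y = np.bincount(assign, weights=coarse[:, 0], minlength=n)
        sums_x = np.bincount(assign, weights=coarse[:, 1], minlength=n)
        counts = np.bincount(assign, minlength=n)
        nonzero = counts > 0
        centers[nonzero, 0] = sums_y[nonzero] / counts[nonzero]
        centers[nonzero, 1] = sums_x[nonzero] / counts[nonzero]

    dist, assign = cKDTree(centers).query(pts, k=2)
    labels = (assign[:, 0] + 1).astype(np.int32)
    # Pixels whose nearest-center margin is small sit on a Voronoi edge; the
    # band (d2 - d1) < width has total thickness ~ interstitium_width_px.
    labels[(dist[:, 1] - dist[:, 0]) < spec.interstitium_width_px] = 0
    labels = labels.reshape(h, w)

    present = np.bincount(labels.ravel(), minlength=n + 1)[1:] > 0
    if not present.all():
        raise ValueError(
            f"n_fibers={n} too large for a {h}x{w} raster with "
            f"interstitium {spec.interstitium_width_px} px: "
            f"{int((~present).sum())} fibers vanished after erosion"
        )
    return labels


def _stain_raster(
    spec: SyntheticSectionSpec,
    labels: np.ndarray,
    type1_of: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-fiber top-k thresholding of a shared correlated random field."""
    noise = gaussian_filter(rng.standard_normal(labels.shape), spec.patch_scale_px)
    flat_lab = labels.ravel()
    flat_noise = noise.ravel()
    order = np.lexsort((flat_noise, flat_lab))  # by label, then field value
    sorted_lab = flat_lab[order]
    starts = np.searchsorted(sorted_lab, np.arange(1, spec.n_fibers + 1))
    ends = np.searchsorted(sorted_lab, np.arange(1, spec.n_fibers + 1), side="right")

    target = np.where(type1_of, spec.retention_type1, spec.retention_type2b)
    target = target * spec.control_coverage

    stained = np.zeros(flat_lab.size, dtype=bool)
    for i in range(spec.n_fibers):
        npx = ends[i] - starts[i]
        k = int(round(target[i] * npx))
        if k > 0:
            stained[order[ends[i] - k : ends[i]]] = True  # top-k field values
    return stained.reshape(labels.shape)


def generate_section(spec: SyntheticSectionSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    All randomness derives from ``spec.seed`` via independent child streams
    for geometry, typing, stain patches and imaging noise, so two calls with
    the same spec are bit-identical, and changing retention alone never
    changes the geometry or the patch field (stained sets are then nested,
    i.e. monotone in retention).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_type, rng_patch, rng_noise = (np.random.default_rng(c) for c in ss.spawn(4))

    labels = _fiber_geometry(spec, rng_geom)
    type1_of = rng_type.random(spec.n_fibers) < spec.p_type1  # fiber i+1 -> type
    stained = _stain_raster(spec, labels, type1_of, rng_patch)

    fiber = labels > 0
    type1_lut = np.zeros(spec.n_fibers + 1, dtype=bool)
    type1_lut[1:] = type1_of
    t1_mask = fiber & type1_lut[labels]
    t2_mask = fiber & ~type1_lut[labels]

    def frac(mask):
        den = int(mask.sum())
        return float((mask & stained).sum() / den) if den else float("nan")

    gt = GroundTruth(
        fiber_label_raster=labels,
        fiber_types={i + 1: ("TypeI" if type1_of[i] else "TypeIIb") for i in range(spec.n_fibers)},
        stained_raster=stained,
        true_total_fraction=frac(fiber),
        true_type1_fraction=frac(t1_mask),
        true_type2b_fraction=frac(t2_mask),
    )

    img = np.empty((spec.height_px, spec.width_px, 3), dtype=np.float64)
    img[:] = spec.background_color
    img[fiber & ~stained] = spec.unstained_fiber_color
    img[stained & t1_mask] = spec.stain_color_type1
    img[stained & t2_mask] = spec.stain_color_type2b

    if spec.illumination_gradient > 0:
        g = spec.illumination_gradient
        ramp = np.linspace(1 - g / 2, 1 + g / 2, spec.width_px)
        img *= ramp[None, :, None]
    if spec.noise_sd > 0:
        img += rng_noise.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return FieldImage(pixels), gt


@dataclass
class StudyField:
    field_index: int
    image: FieldImage
    ground_truth: GroundTruth


@dataclass
class StudyAnimal:
    animal_id: str
    condition: str
    retention_type1: float  # this animal's jittered truth
    retention_type2b: float
    coverage: float
    fields: list[StudyField] = field(default_factory=list)


def generate_study(
    design: Mapping[str, int],
    fields_per_animal: int = 10,
    base_spec_overrides: Mapping | None = None,
    seed: int = 0,
    between_animal_sd: float = 0.08,
    coverage_jitter_sd: float = 0.08,
) -> Iterator[StudyAnimal]:
    """Yield one :class:`StudyAnimal` at a time for a whole experiment.

    ``design`` maps condition label -> number of animals.  Each animal draws
    one standard-normal severity score shared by both fiber types (controls
    stay at retention 1), applied additively with SD ``between_animal_sd``
    per type; near the zero-viability floor the SD shrinks (factor
    ``min(1, preset / (2.5 SD))``) so the jitter stays centered on the preset
    instead of piling up against the clip at 0 — matching the smaller
    animal-to-animal spread seen in heavily injured groups.  A multiplicative
    staining-coverage factor (SD ``coverage_jitter_sd``) models batch
    staining variation.  Fields within an animal share the animal's
    retentions but have fresh geometry.  Everything derives from ``seed``.
    """
    if not design:
        raise ValueError("design is empty")
    if fields_per_animal < 1:
        raise ValueError("fields_per_animal must be >= 1")
    for cond, n in design.items():
        if cond not in CONDITION_RETENTIONS:
            raise ValueError(
                f"unknown condition {cond!r}; valid labels: {', '.join(CONDITIONS)}"
            )
        if n < 1:
            raise ValueError(f"n_animals must be >= 1 (got {n} for {cond})")

    overrides = dict(base_spec_overrides or {})
    top = np.random.SeedSequence(seed)
    animal_seqs = top.spawn(sum(design.values()))
    idx = 0
    for cond, n_animals in design.items():
        preset = make_condition_preset(cond, **overrides)
        injured = cond != "Control"
        for a in range(n_animals):
            ss = animal_seqs[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            z = rng.standard_normal() if (injured and between_animal_sd > 0) else 0.0

            def jittered(preset_r: float) -> float:
                # SD shrinks near 0 so the draw stays centered on the preset
                sd = between_animal_sd * min(1.0, preset_r / (2.5 * between_animal_sd)) \
                    if between_animal_sd > 0 else 0.0
                return float(np.clip(preset_r + sd * z, 0.0, 1.0))

            r1 = jittered(preset.retention_type1) if injured else preset.retention_type1
            r2b = jittered(preset.retention_type2b) if injured else preset.retention_type2b
            cov_factor = 1.0 + (rng.normal(0.0, coverage_jitter_sd) if coverage_jitter_sd > 0 else 0.0)
            cov = float(np.clip(preset.control_coverage * cov_factor, 0.05, 1.0))

            animal = StudyAnimal(
                animal_id=f"{cond}_{a + 1:02d}",
                condition=cond,
                retention_type1=r1,
                retention_type2b=r2b,
                coverage=cov,
            )
            field_seeds = rng.integers(0, 2**31 - 1, size=fields_per_animal)
            for f in range(fields_per_animal):
                fspec = replace(
                    preset,
                    retention_type1=r1,
                    retention_type2b=r2b,
                    control_coverage=cov,
                    seed=int(field_seeds[f]),
                )
                image, gt = generate_section(fspec)
                image.animal_id = animal.animal_id
                image.condition = cond
                image.field_index = f
                animal.fields.append(StudyField(f, image, gt))
            yield animal
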
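"""End-to-end orchestration: images -> masks -> viability tables -> stats.

Two entry points: :func:`run_synthetic_study` keeps everything in memory
(generate, segment, measure, analyze), while :func:`run_pipeline` consumes a
CSV manifest of images on disk.  Both are deterministic for a fixed
configuration and seed, and stamp every tabular output with a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .morphometry import (
    AnimalViability,
    animal_mean,
    field_viability,
    normalize_to_control,
    summarize_groups,
)
from .segmentation import (
    ChannelThresholds,
    DEFAULT_THRESHOLDS,
    DEFAULT_FIBER_PARAMS,
    FiberSegmentationParams,
    segment_field,
)
from .stats import StatsReport, run_study_stats
from .synthetic import CONDITION_DURATIONS_H, generate_study

log = logging.getLogger("myoviability")

__all__ = [
    "RunConfig",
    "StudyResult",
    "run_synthetic_study",
    "run_pipeline",
    "recovery_experiment",
]


@dataclass(frozen=True)
class RunConfig:
    thresholds: ChannelThresholds = DEFAULT_THRESHOLDS
    fiber_params: FiberSegmentationParams = DEFAULT_FIBER_PARAMS
    typing_mode: str = "otsu"
    fixed_type_threshold: float | None = None
    use_ground_truth_instances: bool = True
    fields_per_animal: int = 10
    control_label: str = "Control"
    alpha: float = 0.05
    seed: int = 0

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    config: RunConfig
    field_table: pd.DataFrame
    animal_table: pd.DataFrame
    normalized: pd.DataFrame
    group_summary: pd.DataFrame
    stats: StatsReport | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("field_viability.csv", self.field_table),
            ("animal_viability.csv", self.animal_table),
            ("normalized_viability.csv", self.normalized),
            ("group_summary.csv", self.group_summary),
        ):
            df.assign(config_hash=self.config.config_hash).to_csv(out / name, index=False)
        summary = {
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config.config_hash,
            "n_animals": int(self.animal_table.shape[0]),
            "n_fields": int(self.field_table.shape[0]),
        }
        if self.stats is not None:
            summary["stats"] = self.stats.to_dict()
        (out / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))


def _measure_animal(fields, animal_id, condition, config: RunConfig):
    """Segment and measure one animal's fields; returns (rows, AnimalViability)."""
    rows, fvs = [], []
    for f in fields:
        instances = None
        if config.use_ground_truth_instances and f.ground_truth is not None:
            instances = f.ground_truth.fiber_label_raster
        masks, _ = segment_field(
            f.image,
            thresholds=config.thresholds,
            fiber_params=config.fiber_params,
            instances=instances,
            typing_mode=config.typing_mode,
            fixed_threshold=config.fixed_type_threshold,
        )
        fv = field_viability(masks)
        fvs.append(fv)
        rows.append(
            {
                "animal_id": animal_id,
                "condition": condition,
                "field_index": f.field_index,
                "total_fraction": fv.total_fraction,
                "type1_fraction": fv.type1_fraction,
                "type2b_fraction": fv.type2b_fraction,
                "positive_px": fv.positive_px,
                "fiber_px": fv.fiber_px,
            }
        )
    return rows, animal_mean(fvs, animal_id=animal_id, condition=condition)


def _assemble(config: RunConfig, field_rows, animals, with_stats: bool) -> StudyResult:
    field_table = pd.DataFrame(field_rows)
    animal_table = pd.DataFrame(
        [
            {
                "animal_id": a.animal_id,
                "condition": a.condition,
                "n_fields": a.n_fields,
                "total_fraction": a.total_fraction,
                "type1_fraction": a.type1_fraction,
                "type2b_fraction": a.type2b_fraction,
            }
            for a in animals
        ]
    )
    normalized = normalize_to_control(animals, config.control_label)
    group_summary = summarize_groups(normalized)
    stats = None
    if with_stats:
        conds = set(normalized["condition"])
        durations = {c: CONDITION_DURATIONS_H[c] for c in conds if c in CONDITION_DURATIONS_H}
        try:
            stats = run_study_stats(normalized, durations_h=durations or None, alpha=config.alpha)
        except ValueError as exc:  # e.g. a single group, or n too small
            log.warning("statistics skipped: %s", exc)
    return StudyResult(config, field_table, animal_table, normalized, group_summary, stats)


def run_synthetic_study(
    design: Mapping[str, int],
    config: RunConfig | None = None,
    base_spec_overrides: Mapping | None = None,
    with_stats: bool = True,
    **study_kwargs,
) -> StudyResult:
    """Generate a synthetic study and push it through the full pipeline.

    ``design`` maps condition labels to animal counts; all randomness flows
    from ``config.seed``.
    """
    config = config or RunConfig()
    field_rows, animals = [], []
    for animal in generate_study(
        design,
        fields_per_animal=config.fields_per_animal,
        base_spec_overrides=base_spec_overrides,
        seed=config.seed,
        **study_kwargs,
    ):
        log.info("measuring %s (%s)", animal.animal_id, animal.condition)
        rows, av = _measure_animal(animal.fields, animal.animal_id, animal.condition, config)
        field_rows.extend(rows)
        animals.append(av)
    return _assemble(config, field_rows, animals, with_stats)


@dataclass
class _DiskField:
    field_index: int
    image: object
    ground_truth: object = None


def run_pipeline(
    config: RunConfig, manifest_path: str | Path, with_stats: bool = True
) -> StudyResult:
    """Run segmentation -> morphometry -> statistics on a manifest of images.

    The manifest CSV needs columns ``animal_id, condition, field_index,
    image_path`` and optionally ``labels_path`` (instance rasters).  Errors
    name the offending manifest row.
    """
    manifest = mio.read_manifest(manifest_path)
    root = Path(manifest_path).parent
    field_rows, animals = [], []
    for (animal_id, condition), sub in manifest.groupby(["animal_id", "condition"], sort=False):
        fields = []
        for idx, row in sub.iterrows():
            img_path = Path(root, str(row["image_path"]))
            try:
                image = mio.read_image(img_path, animal_id=str(animal_id), condition=str(condition))
            except (FileNotFoundError, OSError, ValueError) as exc:
                raise RuntimeError(f"manifest row {idx} ({img_path}): {exc}") from exc
            gt = None
            if isinstance(row.get("labels_path"), str) and row["labels_path"]:
                labels = mio.read_labels(Path(root, row["labels_path"]))

                class _GT:  # minimal instance carrier for segment_field
                    fiber_label_raster = labels

                gt = _GT()
            fields.append(_DiskField(int(row["field_index"]), image, gt))
        rows, av = _measure_animal(fields, str(animal_id), str(condition), config)
        field_rows.extend(rows)
        animals.append(av)
    if not animals:
        raise RuntimeError(f"manifest {manifest_path} contains no usable rows")
    return _assemble(config, field_rows, animals, with_stats)


def recovery_experiment(
    conditions: tuple[str, ...] = ("4I", "8I", "9I"),
    n_animals: int = 6,
    fields_per_animal: int = 10,
    seed: int = 0,
    replicates: int = 5,
) -> pd.DataFrame:
    """Parameter-recovery experiment: how well does the full pipeline
    re-estimate the generator's condition presets?

    Runs ``replicates`` independent synthetic studies (each: a control group
    plus the requested condition groups, ``n_animals`` animals x
    ``fields_per_animal`` fields at defaults), pushes every one through
    segmentation -> morphometry -> normalization, and averages the group
    normalized means over replicates.  Returns a frame with columns
    ``condition, measurement, mean_pct, sd_between_replicates, n_animals``.
    """
    rng = np.random.default_rng(seed)
    study_seeds = rng.integers(0, 2**31 - 1, size=replicates)
    design = {"Control": n_animals, **{c: n_animals for c in conditions}}
    per_rep = []
    for i, s in enumerate(study_seeds):
        config = RunConfig(fields_per_animal=fields_per_animal, seed=int(s))
        log.info("recovery replicate %d/%d (seed %d)", i + 1, replicates, s)
        result = run_synthetic_study(design, config=config, with_stats=False)
        per_rep.append(result.group_summary.assign(replicate=i))
    stacked = pd.concat(per_rep, ignore_index=True)
    out = (
        stacked.groupby(["condition", "measurement"], sort=False)["mean_pct"]
        .agg(mean_pct="mean", sd_between_replicates="std")
        .reset_index()
    )
    out["n_animals"] = n_animals * replicates
    return out
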
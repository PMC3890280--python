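"""Area-fraction viability at field, animal and group level.

The viability statistic: per field, the positively stained area divided by
the muscle-fiber area (total, and separately per fiber type); per animal,
the unweighted mean over its fields; per group, the mean +/- s.e.m. after
expressing every animal as a percentage of the control-group mean, each
measurement normalized by its own control mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import FieldMasks

__all__ = [
    "MEASUREMENTS",
    "FieldViability",
    "AnimalViability",
    "field_viability",
    "animal_mean",
    "normalize_to_control",
    "summarize_groups",
]

MEASUREMENTS = ("total", "type1", "type2b")


@dataclass(frozen=True)
class FieldViability:
    """Stained-area fractions for one field; ``None`` = undefined (0 denominator)."""

    total_fraction: float | None
    type1_fraction: float | None
    type2b_fraction: float | None
    positive_px: int
    fiber_px: int
    type1_px: int
    type2b_px: int
    positive_type1_px: int
    positive_type2b_px: int

    def fraction(self, measurement: str) -> float | None:
        return getattr(self, f"{measurement}_fraction")


@dataclass(frozen=True)
class AnimalViability:
    animal_id: str
    condition: str
    n_fields: int
    n_fields_used: dict[str, int]  # per measurement
    total_fraction: float | None
    type1_fraction: float | None
    type2b_fraction: float | None

    def fraction(self, measurement: str) -> float | None:
        return getattr(self, f"{measurement}_fraction")


def field_viability(masks: FieldMasks) -> FieldViability:
    """Positive-area / fiber-area fractions from one field's masks.

    A zero denominator (e.g. a field with no Type I fiber) yields ``None``
    for that measurement, never 0 — absence of a fiber type is not evidence
    of zero viability.
    """
    fiber = int(masks.fiber.sum())
    pos = int(masks.positive.sum())
    t1 = int(masks.type1.sum())
    t2 = int(masks.type2b.sum())
    p1 = int((masks.positive & masks.type1).sum())
    p2 = int((masks.positive & masks.type2b).sum())

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return FieldViability(
        total_fraction=ratio(pos, fiber),
        type1_fraction=ratio(p1, t1),
        type2b_fraction=ratio(p2, t2),
        positive_px=pos,
        fiber_px=fiber,
        type1_px=t1,
        type2b_px=t2,
        positive_type1_px=p1,
        positive_type2b_px=p2,
    )


def animal_mean(
    fields: list[FieldViability], animal_id: str = "", condition: str = ""
) -> AnimalViability:
    """Unweighted mean over fields, per measurement, skipping undefined fields."""
    if not fields:
        raise ValueError("no fields provided")
    means: dict[str, float | None] = {}
    used: dict[str, int] = {}
    for m in MEASUREMENTS:
        vals = [f.fraction(m) for f in fields if f.fraction(m) is not None]
        used[m] = len(vals)
        if len(vals) < len(fields) and vals:
            warnings.warn(
                f"{animal_id or 'animal'}: {m} undefined in "
                f"{len(fields) - len(vals)}/{len(fields)} fields; averaging the rest"
            )
        means[m] = float(np.mean(vals)) if vals else None
    if means["total"] is None:
        raise ValueError(f"{animal_id or 'animal'}: total viability undefined in every field")
    return AnimalViability(
        animal_id=animal_id,
        condition=condition,
        n_fields=len(fields),
        n_fields_used=used,
        total_fraction=means["total"],
        type1_fraction=means["type1"],
        type2b_fraction=means["type2b"],
    )


def normalize_to_control(
    animals: list[AnimalViability], control_condition: str = "Control"
) -> pd.DataFrame:
    """Express every animal as percent of the control-group mean.

    Each measurement is normalized by its own control mean, so the control
    group's normalized mean is exactly 100.0 for total, Type I and Type IIb
    alike.  Returns a tidy frame with one row per animal x measurement:
    columns ``animal_id, condition, measurement, raw_fraction,
    normalized_pct``.
    """
    controls = [a for a in animals if a.condition == control_condition]
    if not controls:
        raise ValueError(f"no animals with control condition {control_condition!r}")

    control_means: dict[str, float] = {}
    for m in MEASUREMENTS:
        vals = [a.fraction(m) for a in controls if a.fraction(m) is not None]
        if not vals:
            raise ValueError(f"control mean undefined for measurement {m!r}")
        cm = float(np.mean(vals))
        if cm == 0:
            raise ValueError(f"control mean is zero for measurement {m!r}")
        control_means[m] = cm

    rows = []
    for a in animals:
        for m in MEASUREMENTS:
            raw = a.fraction(m)
            rows.append(
                {
                    "animal_id": a.animal_id,
                    "condition": a.condition,
                    "measurement": m,
                    "raw_fraction": raw,
                    "normalized_pct": (100.0 * raw / control_means[m]) if raw is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(normalized: pd.DataFrame) -> pd.DataFrame:
    """Group x measurement summary: mean percent, s.e.m. (sample SD / sqrt(n)), n."""
    def sem(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        normalized.groupby(["condition", "measurement"], sort=False)["normalized_pct"]
        .agg(mean_pct="mean", sem_pct=sem, n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
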
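"""Statistical layer: normality, ANOVA, Scheffé post-hoc, Pearson correlation.

Mirrors the analysis plan of a balanced ischemia-duration study: Shapiro-Wilk
per group, fixed-effects two-way ANOVA (condition x measurement) for the
viability tables (one-way for single-measurement tables), Scheffé's
simultaneous pairwise comparisons between conditions, and Pearson correlation
of viability against ischemia duration.  Alpha defaults to 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "AnovaTable",
    "PosthocResult",
    "NormalityResult",
    "StatsReport",
    "pearson",
    "one_way_anova",
    "two_way_anova",
    "scheffe_posthoc",
    "shapiro_wilk",
    "run_study_stats",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    ss: float
    df: int
    ms: float
    f: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaTable:
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    @property
    def ss_total(self) -> float:
        return sum(e.ss for e in self.effects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.effects])


@dataclass(frozen=True)
class PosthocResult:
    group_i: str
    group_j: str
    mean_difference: float
    statistic: float  # Scheffé F-type statistic (squared standardized difference)
    critical_value: float  # (k-1) * F_crit(k-1, df_res, alpha)
    p_value: float
    significant: bool


@dataclass(frozen=True)
class NormalityResult:
    w: float
    p_value: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t test (n-2 df).

    Constant input is an error: the correlation is undefined there, and
    silently reporting r = 0 would hide a degenerate measurement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, r_squared=r * r, p_value=p, n_pairs=n)


def one_way_anova(values: pd.Series, groups: pd.Series) -> AnovaTable:
    """Fixed-effects one-way ANOVA (no balance requirement)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size or y.size == 0:
        raise ValueError("values and groups must be non-empty and equal-length")
    grand = y.mean()
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ss_a = ss_res = 0.0
    df_res = 0
    for lab in labels:
        yi = y[g == lab]
        ss_a += yi.size * (yi.mean() - grand) ** 2
        ss_res += float(((yi - yi.mean()) ** 2).sum())
        df_res += yi.size - 1
    df_a = len(labels) - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (need >=2 observations per group)")
    ms_a, ms_res = ss_a / df_a, ss_res / df_res
    f = ms_a / ms_res if ms_res > 0 else np.inf
    p = float(sps.f.sf(f, df_a, df_res))
    return AnovaTable(
        (
            AnovaEffect("condition", ss_a, df_a, ms_a, f, p),
            AnovaEffect("residual", ss_res, df_res, ms_res, None, None),
        )
    )


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "condition",
    factor_b: str = "measurement",
) -> AnovaTable:
    """Balanced fixed-effects two-way ANOVA with interaction.

    Sums of squares follow the classical balanced-design decomposition
    (equal cell counts >= 2); every F is tested against the residual mean
    square.  Unbalanced tables are rejected — fit a linear model elsewhere
    if the design is incomplete.
    """
    df = table[[factor_a, factor_b, value]].dropna()
    a_levels = pd.unique(df[factor_a])
    b_levels = pd.unique(df[factor_b])
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("both factors need at least 2 levels")
    counts = df.groupby([factor_a, factor_b], sort=False)[value].count()
    if len(counts) != a * b or counts.nunique() != 1:
        raise ValueError(
            "unbalanced or incomplete design: balanced two-way ANOVA requires "
            "equal cell counts for every condition x measurement cell"
        )
    n = int(counts.iloc[0])
    if n < 2:
        raise ValueError("need at least 2 observations per cell")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = df.groupby([factor_a, factor_b], sort=False)[value].mean()
    a_means = df.groupby(factor_a, sort=False)[value].mean()
    b_means = df.groupby(factor_b, sort=False)[value].mean()

    ss_a = b * n * float(((a_means - grand) ** 2).sum())
    ss_b = a * n * float(((b_means - grand) ** 2).sum())
    ss_ab = n * sum(
        (cell_means[(ai, bi)] - a_means[ai] - b_means[bi] + grand) ** 2
        for ai in a_levels
        for bi in b_levels
    )
    cell_of_row = df.merge(
        cell_means.rename("cell_mean"), left_on=[factor_a, factor_b], right_index=True
    )["cell_mean"]
    ss_res = float(((df[value] - cell_of_row) ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_res = a * b * (n - 1)
    ms_res = ss_res / df_res

    def eff(name, ss, dfe):
        ms = ss / dfe
        f = ms / ms_res if ms_res > 0 else np.inf
        return AnovaEffect(name, ss, dfe, ms, f, float(sps.f.sf(f, dfe, df_res)))

    return AnovaTable(
        (
            eff(factor_a, ss_a, df_a),
            eff(factor_b, ss_b, df_b),
            eff(f"{factor_a}:{factor_b}", float(ss_ab), df_ab),
            AnovaEffect("residual", ss_res, df_res, ms_res, None, None),
        )
    )


def scheffe_posthoc(
    group_means,
    group_sizes,
    ms_residual: float,
    df_residual: int,
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Scheffé's simultaneous pairwise comparisons.

    For groups i, j the statistic is
    ``(mean_i - mean_j)^2 / (MS_res * (1/n_i + 1/n_j))``, declared
    significant when it exceeds ``(k-1) * F_crit(k-1, df_res, alpha)``;
    the p-value is the upper F tail of ``statistic / (k-1)``.  Controls the
    family-wise error over all contrasts, hence conservative for pairs.
    """
    if df_residual <= 0:
        raise ValueError("df_residual must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    means = dict(group_means)
    sizes = dict(group_sizes)
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    fcrit = float(sps.f.isf(alpha, k - 1, df_residual))
    critical = (k - 1) * fcrit
    out = []
    for gi, gj in itertools.combinations(means, 2):
        diff = float(means[gi] - means[gj])
        denom = ms_residual * (1.0 / sizes[gi] + 1.0 / sizes[gj])
        stat = diff * diff / denom if denom > 0 else np.inf
        p = float(sps.f.sf(stat / (k - 1), k - 1, df_residual))
        out.append(
            PosthocResult(
                group_i=str(gi),
                group_j=str(gj),
                mean_difference=diff,
                statistic=float(stat),
                critical_value=critical,
                p_value=p,
                significant=bool(stat > critical),
            )
        )
    return out


def shapiro_wilk(values) -> NormalityResult:
    """Shapiro-Wilk normality test (delegates to scipy's implementation)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError(f"need a 1-D sample with n >= 3, got n={x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    res = sps.shapiro(x)
    return NormalityResult(w=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


@dataclass
class StatsReport:
    """Bundle of the full statistical analysis of one viability table."""

    alpha: float
    normality: pd.DataFrame  # condition, measurement, W, p, n
    anova: AnovaTable
    anova_kind: str  # "one-way" | "two-way"
    posthoc: list[PosthocResult]
    correlation_per_animal: CorrelationResult | None
    correlation_group_means: CorrelationResult | None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "anova_kind": self.anova_kind,
            "normality": self.normality.to_dict(orient="records"),
            "anova": [asdict(e) for e in self.anova.effects],
            "posthoc": [asdict(p) for p in self.posthoc],
            "correlation_per_animal": (
                asdict(self.correlation_per_animal) if self.correlation_per_animal else None
            ),
            "correlation_group_means": (
                asdict(self.correlation_group_means) if self.correlation_group_means else None
            ),
        }


def run_study_stats(
    normalized: pd.DataFrame,
    durations_h: dict[str, float] | None = None,
    alpha: float = 0.05,
    value: str = "normalized_pct",
) -> StatsReport:
    """Full analysis of a tidy animal-level table.

    ``normalized`` needs columns ``animal_id, condition, measurement`` and
    the value column.  With several measurements a two-way ANOVA
    (condition x measurement) is fitted; with one, a one-way ANOVA.
    Scheffé comparisons are made between conditions on their marginal means
    (observations pooled over measurements), using the ANOVA residual.
    If ``durations_h`` maps conditions to ischemia hours, Pearson correlation
    of total viability against duration is computed both per animal and on
    group means.
    """
    required = {"animal_id", "condition", "measurement", value}
    if normalized.empty or not required.issubset(normalized.columns):
        raise ValueError(f"table must be non-empty with columns {sorted(required)}")
    df = normalized.dropna(subset=[value])

    norm_rows = []
    for (cond, meas), sub in df.groupby(["condition", "measurement"], sort=False):
        if len(sub) >= 3:
            r = shapiro_wilk(sub[value].to_numpy())
            norm_rows.append(
                {"condition": cond, "measurement": meas, "w": r.w, "p_value": r.p_value, "n": r.n}
            )
    normality = pd.DataFrame(norm_rows)

    measurements = pd.unique(df["measurement"])
    if len(measurements) >= 2:
        anova = two_way_anova(df, value=value)
        kind = "two-way"
    else:
        anova = one_way_anova(df[value], df["condition"])
        kind = "one-way"
    res = anova["residual"]

    marg = df.groupby("condition", sort=False)[value]
    posthoc = scheffe_posthoc(
        marg.mean().to_dict(), marg.count().to_dict(), res.ms, res.df, alpha=alpha
    )

    corr_animal = corr_group = None
    if durations_h:
        tot = df[(df["measurement"] == "total") & df["condition"].isin(durations_h)]
        if tot["condition"].nunique() >= 3:
            hours = tot["condition"].map(durations_h).to_numpy(dtype=float)
            corr_animal = pearson(hours, tot[value].to_numpy())
            gm = tot.groupby("condition", sort=False)[value].mean()
            corr_group = pearson(
                np.array([durations_h[c] for c in gm.index], dtype=float), gm.to_numpy()
            )

    return StatsReport(
        alpha=alpha,
        normality=normality,
        anova=anova,
        anova_kind=kind,
        posthoc=posthoc,
        correlation_per_animal=corr_animal,
        correlation_group_means=corr_group,
    )
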
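"""Outcome statistics: neurite net growth, one-way ANOVA (raw data or
published summary statistics), Holm-Sidak post hoc comparisons, and
locomotion summaries.

The summary-statistics ANOVA is the workhorse for auditing published group
comparisons: given only each group's mean, SEM and n it reconstructs the
one-way decomposition exactly, because the between-group sum of squares
depends only on means and the within-group mean square only on the group
variances, recovered as n * sem**2. It agrees with the raw-data ANOVA on
any dataset having exactly those summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "net_change",
    "summarize_group",
    "anova_oneway",
    "anova_from_summary",
    "holm_sidak",
    "pairwise_holm_sidak",
    "locomotion_summary",
    "OneWayAnova",
    "AnovaResults",
]


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SEM, n) triplet for one group — the unit of summary-statistics
    ANOVA. SEM is sd/sqrt(n); the group variance is recovered as n * sem**2."""

    group: str
    mean: float
    sem: float
    n: int
    units: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: need n >= 2, got {self.n}")
        if self.sem < 0:
            raise ValueError(f"group {self.group!r}: SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @property
    def variance(self) -> float:
        return self.n * self.sem**2


@dataclass(frozen=True)
class AnovaResult:
    """Classic one-way fixed-effects decomposition."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]
    ms_between: float
    ms_within: float
    infinite_f: bool = False


def net_change(series: pd.DataFrame | dict[float, float], t: float, *, baseline: float = 0.0) -> float:
    """Net neurite length change: length(t) - length(baseline), in the same
    units as the lengths (micrometres for traced neurites). Negative values
    are retraction.

    ``series`` maps time -> length, or is a tidy frame with ``time_hr`` and
    ``length_um`` columns for a single neurite.
    """
    if isinstance(series, pd.DataFrame):
        lookup = dict(zip(series["time_hr"].astype(float), series["length_um"].astype(float)))
    else:
        lookup = {float(k): float(v) for k, v in series.items()}
    for needed in (baseline, t):
        if float(needed) not in lookup:
            raise KeyError(f"no length measured at time {needed}")
    return lookup[float(t)] - lookup[float(baseline)]


def summarize_group(values: Sequence[float], group: str = "", units: str = "") -> GroupSummary:
    """Mean, SEM (= sd/sqrt(n), ddof=1) and n of one group's raw values."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need >= 2 values to form a SEM")
    return GroupSummary(
        group=group,
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(len(arr))),
        n=len(arr),
        units=units,
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw group values.

    With two groups, F equals the square of the pooled two-sample t
    statistic. All groups identical constants give F = 0, p = 1 (the 0/0
    case is guarded).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for i, a in enumerate(arrays):
        if len(a) < 2:
            raise ValueError(f"group {i} has {len(a)} values; need >= 2")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b = len(arrays) - 1
    df_w = int(ns.sum()) - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        if ms_b == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, tuple(means), 0.0, 0.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0, tuple(means), ms_b, 0.0, infinite_f=True)
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p, tuple(means), ms_b, ms_w)


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (mean, SEM, n).

    SS_between = sum n_i (m_i - grand)^2 with the n-weighted grand mean;
    MS_within pools the recovered group variances n_i * sem_i^2 with
    weights (n_i - 1). Identical to :func:`anova_oneway` on any raw data
    having exactly these summaries. All-zero SEMs with unequal means flag an
    infinite F rather than raising.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 group summaries")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    variances = np.array([g.variance for g in groups], dtype=float)
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    ms_b = ss_between / df_b
    ms_w = float(((ns - 1) * variances).sum() / (ns - 1).sum())
    if ms_w == 0:
        if ms_b == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0, tuple(means), 0.0, 0.0)
        return AnovaResult(math.inf, df_b, df_w, 0.0, tuple(means), ms_b, 0.0, infinite_f=True)
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, df_b, df_w, p, tuple(means), ms_b, ms_w)


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjustment.

    Returns (adjusted p-values, reject flags) in the input order. The
    adjusted value of the i-th smallest p is max over j <= i of
    1 - (1 - p_(j))**(m - j + 1), clipped to 1; adjusted p never falls below
    raw p and the rejection set is contiguous from the smallest p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(0 - 1) internally
        reject, adjusted, *_ = multipletests(p, alpha=alpha, method="holm-sidak")
    return adjusted, reject


def pairwise_holm_sidak(
    groups: Sequence[GroupSummary], anova: AnovaResult, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise comparisons after a one-way ANOVA, SigmaStat-style:
    pooled-MS_within t tests on df_within, Holm-Sidak adjusted."""
    rows = []
    raw_p = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            se = math.sqrt(anova.ms_within * (1.0 / gi.n + 1.0 / gj.n))
            diff = gi.mean - gj.mean
            if se > 0:
                t = diff / se
            else:
                t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p = float(2 * stats.t.sf(abs(t), anova.df_within)) if math.isfinite(t) else 0.0
            rows.append({"group_a": gi.group, "group_b": gj.group, "t": t, "p_raw": p})
            raw_p.append(p)
    adj, rej = holm_sidak(raw_p, alpha=alpha)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adj
    out["reject"] = rej
    return out


def locomotion_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per (group, day) mean, SEM and n of crawled distance (cm per 10 min).

    ``records`` needs columns ``snail_id``, ``group``, ``day``,
    ``distance_cm``. Group-days with a single snail get a NaN SEM and a
    ``flagged`` mark instead of an error: such cells still carry a mean.
    """
    required = {"snail_id", "group", "day", "distance_cm"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"locomotion table missing column(s): {sorted(missing)}")
    rows = []
    for (grp, day), sub in records.groupby(["group", "day"], sort=True):
        vals = sub["distance_cm"].to_numpy(float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "group": grp,
                "day": day,
                "mean": float(vals.mean()),
                "sem": sem,
                "n": n,
                "flagged": n < 2,
            }
        )
    return pd.DataFrame(rows)


class OneWayAnova:
    """One-way ANOVA model, constructible from raw data or summaries.

    Examples
    --------
    >>> groups = [GroupSummary("CM", 21.9, 3.1, 14),
    ...           GroupSummary("ctrl_siRNA", 21.2, 3.7, 14),
    ...           GroupSummary("siRNA_1", -1.8, 2.9, 14),
    ...           GroupSummary("siRNA_2", 0.1, 1.3, 14)]
    >>> res = OneWayAnova.from_summary(groups).fit()
    >>> round(res.anova.F, 1)
    20.1
    """

    def __init__(self, groups: Sequence[GroupSummary], raw: Sequence[Sequence[float]] | None = None):
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        self.groups = list(groups)
        self.raw = [np.asarray(g, float) for g in raw] if raw is not None else None

    @classmethod
    def from_summary(cls, groups: Sequence[GroupSummary]) -> "OneWayAnova":
        return cls(groups)

    @classmethod
    def from_groups(cls, raw: dict[str, Sequence[float]], units: str = "") -> "OneWayAnova":
        summaries = [summarize_group(v, group=k, units=units) for k, v in raw.items()]
        return cls(summaries, raw=list(raw.values()))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value: str = "value", group: str = "group") -> "OneWayAnova":
        raw = {str(g): sub[value].to_numpy(float) for g, sub in df.groupby(group, sort=True)}
        return cls.from_groups(raw)

    def fit(self, alpha: float = 0.05) -> "AnovaResults":
        if self.raw is not None:
            anova = anova_oneway(self.raw)
        else:
            anova = anova_from_summary(self.groups)
        posthoc = None
        if math.isfinite(anova.F) and anova.p_value < alpha:
            posthoc = pairwise_holm_sidak(self.groups, anova, alpha=alpha)
        return AnovaResults(self, anova, posthoc, alpha)


class AnovaResults:
    """Fitted one-way ANOVA with optional Holm-Sidak post hoc table."""

    def __init__(self, model: OneWayAnova, anova: AnovaResult, posthoc: pd.DataFrame | None, alpha: float):
        self.model = model
        self.anova = anova
        self.posthoc = posthoc
        self.alpha = alpha

    def summary(self) -> str:
        a = self.anova
        lines = [
            "One-way ANOVA",
            f"  F({a.df_between}, {a.df_within}) = "
            + ("inf (zero within-group variance)" if a.infinite_f else f"{a.F:.2f}"),
            f"  p = {a.p_value:.3g}",
            f"  {'group':<16} {'mean':>10} {'sem':>8} {'n':>4}",
        ]
        for g in self.model.groups:
            lines.append(f"  {g.group:<16} {g.mean:>10.3f} {g.sem:>8.3f} {g.n:>4d}")
        if self.posthoc is not None:
            lines.append("  Holm-Sidak pairwise comparisons:")
            for _, row in self.posthoc.iterrows():
                mark = "*" if row["reject"] else " "
                lines.append(
                    f"    {row['group_a']} vs {row['group_b']}: "
                    f"t = {row['t']:.2f}, adj p = {row['p_adjusted']:.4f} {mark}"
                )
        else:
            lines.append(f"  omnibus not significant at alpha = {self.alpha}; no post hoc run")
        return "\n".join(lines)
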
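"""Relative quantification of qPCR data via the Ct-Ct plot.

The estimator regresses the target gene's threshold cycles against the
control gene's across samples of one condition. Under the standard
exponential-amplification model with sample-independent efficiencies, the
points fall on a line

    Ct_g = m * Ct_c - log10(R) / log10(E_g),      m = log(E_c) / log(E_g)

where ``E_g`` and ``E_c`` are the per-cycle amplification efficiencies of the
target and control primers and ``R`` the relative expression level
(target/control template ratio). The Y-intercept therefore measures ``R``
once ``E_g`` is known from a dilution standard curve, without assuming
perfect doubling: a generalisation of the classic 2**(-ddCt) method to
unequal efficiencies. Variation in per-sample input amount supplies the
spread along the Ct axis that identifies the line; when all samples carry
the same amount the slope is unidentifiable.

The fit is ordinary least squares of Ct_target on Ct_control, matching the
plot as read in practice (an errors-in-variables fit would change the
intercept; see docs/methods.md for the limitation this implies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CtCtFit",
    "FoldChangeResult",
    "fit_standard_curve",
    "efficiency_from_slope",
    "fit_ctct",
    "ratio_from_intercept",
    "condition_fold_change",
    "quantify_timecourse",
    "CtCtQuantModel",
    "CtCtQuantResults",
]

#: fitted slope may deviate this much from log(E_c)/log(E_g) before QC flags it
SLOPE_QC_TOLERANCE = 0.1


class InsufficientDataError(ValueError):
    """Too few points, or no spread, to identify the requested fit."""


@dataclass(frozen=True)
class StandardCurve:
    """A dilution standard curve: Ct regressed on log10(dilution).

    ``slope_m`` is in cycles per decade of dilution; the amplification
    efficiency derives from it as ``E = 10**(-1/slope_m)`` (perfect doubling
    gives -3.32 cycles/decade). Efficiencies above 2.1 are flagged, not
    rejected: they indicate a poor curve rather than super-doubling chemistry.
    """

    gene_name: str
    slope_m: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int

    @property
    def implausible_efficiency(self) -> bool:
        return self.efficiency > 2.1


@dataclass(frozen=True)
class CtCtFit:
    """OLS line of Ct_target on Ct_control for one condition/time point."""

    condition: str
    time_hr: float
    slope_m: float
    y_intercept: float
    r_squared: float
    n_pairs: int
    ratio_R: float | None = None

    def with_ratio(self, efficiency_target: float) -> "CtCtFit":
        r = ratio_from_intercept(self.y_intercept, efficiency_target)
        return CtCtFit(
            self.condition, self.time_hr, self.slope_m, self.y_intercept,
            self.r_squared, self.n_pairs, ratio_R=r,
        )


@dataclass(frozen=True)
class FoldChangeResult:
    """Crush-vs-sham relative expression at one time point, mean +/- SEM over groups."""

    time_hr: float
    fold_change: float
    sem: float | None
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a*x + b; returns (slope, intercept, r_squared)."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_standard_curve(
    points: Sequence[tuple[float, float]] | np.ndarray, gene_name: str = ""
) -> StandardCurve:
    """Fit Ct on log10(dilution) and derive the amplification efficiency.

    Parameters
    ----------
    points : sequence of (log10_dilution, ct) pairs
        At least 3 points spanning at least 3 distinct dilutions.
    gene_name : str
        Label carried into the result.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct dilution values.
    ValueError
        Non-negative fitted slope: Ct must rise with dilution, otherwise the
        efficiency is undefined.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (log10 dilution, Ct) points")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need at least 3 distinct dilution values")
    slope, intercept, r2 = _ols(x, y)
    if slope >= 0:
        raise ValueError(
            f"degenerate standard curve for {gene_name or 'gene'}: "
            f"slope {slope:.3g} >= 0, efficiency undefined"
        )
    return StandardCurve(
        gene_name=gene_name,
        slope_m=slope,
        intercept=intercept,
        efficiency=efficiency_from_slope(slope),
        r_squared=r2,
        n_points=len(x),
    )


def efficiency_from_slope(slope_m: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10**(-1/m).

    A slope of -3.3219 cycles/decade gives E = 2 (perfect doubling); very
    steep slopes approach E = 1 (no amplification).
    """
    if slope_m >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope_m}")
    return 10.0 ** (-1.0 / slope_m)


def fit_ctct(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    condition: str = "",
    time_hr: float = float("nan"),
    *,
    fixed_slope: float | None = None,
) -> CtCtFit:
    """Fit the Ct-Ct line of one condition.

    ``pairs`` holds (Ct_control, Ct_target) per sample. The input-amount
    spread across samples must move the control Ct; identical control Cts
    leave the slope unidentifiable and raise.

    By default the slope and intercept are both estimated by OLS — the fit
    one draws on the plot, used for the slope-consistency QC. When
    ``fixed_slope`` is given (the theoretical log(E_c)/log(E_g) from the
    standard curves), only the intercept is estimated, as
    ``mean(Ct_g) - m * mean(Ct_c)``. Quantification uses this constrained
    intercept whenever both efficiencies are known: the free-slope intercept
    extrapolates ~20 cycles outside the data and its sampling error is on
    the cycle scale, which the fixed slope removes. The two fits coincide
    on noise-free data. ``r_squared`` always describes the linearity of the
    point cloud (the free fit).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need at least 2 (Ct_control, Ct_target) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite Ct values; drop undetermined wells before fitting")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise InsufficientDataError(
            "all control Cts identical: no input-amount spread, slope unidentifiable"
        )
    slope, intercept, r2 = _ols(x, y)
    if fixed_slope is not None:
        slope = float(fixed_slope)
        intercept = float(y.mean() - slope * x.mean())
    return CtCtFit(
        condition=condition,
        time_hr=time_hr,
        slope_m=slope,
        y_intercept=intercept,
        r_squared=r2,
        n_pairs=len(x),
    )


def ratio_from_intercept(y_intercept: float, efficiency_target: float) -> float:
    """Relative expression ratio from a Ct-Ct intercept: R = E_g**(-Y_int).

    Inverts Y_int = -log(R)/log(E_g). An intercept of zero means equal
    target and control abundance; each cycle of negative intercept at E = 2
    doubles R.
    """
    if efficiency_target <= 1.0:
        raise ValueError(f"target efficiency must be > 1, got {efficiency_target}")
    return float(efficiency_target ** (-y_intercept))


def condition_fold_change(
    fit_crush: CtCtFit, fit_sham: CtCtFit, efficiency_target: float
) -> float:
    """Injury-vs-control fold change from two Ct-Ct fits at one time point.

    Returns R_crush / R_sham = E_g**(Y_sham - Y_crush): a smaller intercept
    in the injured group means higher relative target expression.
    """
    t1, t2 = fit_crush.time_hr, fit_sham.time_hr
    if not (t1 == t2 or (math.isnan(t1) and math.isnan(t2))):
        raise ValueError(f"fits are from different time points ({t1} vs {t2})")
    if efficiency_target <= 1.0:
        raise ValueError(f"target efficiency must be > 1, got {efficiency_target}")
    return float(efficiency_target ** (fit_sham.y_intercept - fit_crush.y_intercept))


def _pair_cts(sub: pd.DataFrame, target: str, control: str) -> np.ndarray:
    """Pivot a tidy Ct block into (Ct_control, Ct_target) rows, dropping
    samples that lack either gene or carry a non-finite Ct (pairwise
    exclusion, no imputation)."""
    wide = sub.pivot_table(index="sample_id", columns="gene_name", values="ct", aggfunc="mean")
    if target not in wide.columns or control not in wide.columns:
        missing = [g for g in (target, control) if g not in wide.columns]
        raise KeyError(f"gene(s) {missing} absent from Ct table block")
    wide = wide[[control, target]].dropna()
    return wide.to_numpy()


def quantify_timecourse(
    table: pd.DataFrame,
    efficiency_target: float,
    *,
    efficiency_control: float | None = None,
    target: str = "CEBP",
    control: str = "GAPDH",
    test_condition: str = "crush",
    reference_condition: str = "sham",
) -> tuple[list[FoldChangeResult], pd.DataFrame]:
    """Per-time-point crush/sham fold changes from a replicate-grouped CtTable.

    For every time point and replicate group, a Ct-Ct line is fitted per
    condition and the group's fold change is ``E_g**(Y_sham - Y_crush)``;
    the time point's estimate is the mean +/- SEM over replicate groups
    (SEM omitted at n = 1). A QC frame reports every freely fitted slope
    and, when ``efficiency_control`` is given, flags deviations of more
    than ``SLOPE_QC_TOLERANCE`` from the expected log(E_c)/log(E_g); in
    that case the intercepts entering the fold change are re-estimated with
    the slope fixed at its theoretical value (see :func:`fit_ctct`), which
    keeps the intercept's sampling error on the sub-cycle scale.

    Rows with a non-empty ``dilution`` are standard-curve points and are
    ignored here.
    """
    if efficiency_target <= 1.0:
        raise ValueError("target efficiency must be > 1")
    data = table[table["dilution"].isna()] if "dilution" in table.columns else table
    expected_slope = (
        math.log(efficiency_control) / math.log(efficiency_target)
        if efficiency_control is not None
        else None
    )

    results: list[FoldChangeResult] = []
    qc_rows = []
    for t in sorted(data["time_hr"].dropna().unique()):
        block = data[data["time_hr"] == t]
        present = set(block["condition"].unique())
        missing = {test_condition, reference_condition} - present
        if missing:
            raise ValueError(f"time {t}: missing condition(s) {sorted(missing)} in Ct table")
        folds = []
        for rep in sorted(block["replicate"].unique()):
            rep_block = block[block["replicate"] == rep]
            fits = {}
            for cond in (reference_condition, test_condition):
                pairs = _pair_cts(rep_block[rep_block["condition"] == cond], target, control)
                free = fit_ctct(pairs, condition=cond, time_hr=t)
                fits[cond] = (
                    fit_ctct(pairs, condition=cond, time_hr=t, fixed_slope=expected_slope)
                    if expected_slope is not None
                    else free
                )
                qc_rows.append(
                    {
                        "time_hr": t,
                        "replicate": rep,
                        "condition": cond,
                        "slope": free.slope_m,
                        "y_intercept": fits[cond].y_intercept,
                        "r_squared": free.r_squared,
                        "n_pairs": free.n_pairs,
                        "expected_slope": expected_slope,
                        "slope_flag": (
                            abs(free.slope_m - expected_slope) > SLOPE_QC_TOLERANCE
                            if expected_slope is not None
                            else False
                        ),
                    }
                )
            folds.append(
                condition_fold_change(fits[test_condition], fits[reference_condition], efficiency_target)
            )
        folds_arr = np.asarray(folds)
        n = len(folds_arr)
        sem = float(folds_arr.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        results.append(FoldChangeResult(time_hr=float(t), fold_change=float(folds_arr.mean()), sem=sem, n=n))
    return results, pd.DataFrame(qc_rows)


class CtCtQuantModel:
    """Relative-quantification model over a tidy Ct table.

    The model view of the workflow: a CtTable (with optional standard-curve
    rows marked by a non-empty ``dilution`` column) plus target/control gene
    names; :meth:`fit` estimates primer efficiencies from the standard-curve
    rows (unless given), then runs the per-time-point Ct-Ct quantification.

    Examples
    --------
    >>> model = CtCtQuantModel(ct_table, target="CEBP", control="GAPDH")
    >>> res = model.fit()
    >>> print(res.summary())        # doctest: +SKIP
    """

    def __init__(
        self,
        table: pd.DataFrame,
        target: str = "CEBP",
        control: str = "GAPDH",
        *,
        test_condition: str = "crush",
        reference_condition: str = "sham",
    ):
        required = {"sample_id", "condition", "time_hr", "gene_name", "replicate", "ct"}
        missing = required - set(table.columns)
        if missing:
            raise KeyError(f"Ct table missing column(s): {sorted(missing)}")
        self.table = table.copy()
        if "dilution" not in self.table.columns:
            self.table["dilution"] = np.nan
        self.target = target
        self.control = control
        self.test_condition = test_condition
        self.reference_condition = reference_condition

    def standard_curves(self) -> dict[str, StandardCurve]:
        """Fit a standard curve per gene from the dilution-marked rows.

        The ``dilution`` column stores the dilution factor (100 = hundredfold
        less template); the regression runs on log10 relative template amount,
        ``-log10(dilution)``, giving the conventional negative cycles-per-decade
        slope.
        """
        std = self.table[self.table["dilution"].notna()]
        curves = {}
        for gene, sub in std.groupby("gene_name"):
            pts = np.column_stack(
                [-np.log10(sub["dilution"].to_numpy(float)), sub["ct"].to_numpy(float)]
            )
            curves[str(gene)] = fit_standard_curve(pts, gene_name=str(gene))
        return curves

    def fit(
        self,
        efficiency_target: float | None = None,
        efficiency_control: float | None = None,
    ) -> "CtCtQuantResults":
        curves = self.standard_curves()
        if efficiency_target is None:
            if self.target not in curves:
                raise InsufficientDataError(
                    f"no standard-curve rows for target {self.target!r} and no efficiency supplied"
                )
            efficiency_target = curves[self.target].efficiency
        if efficiency_control is None and self.control in curves:
            efficiency_control = curves[self.control].efficiency
        results, qc = quantify_timecourse(
            self.table,
            efficiency_target,
            efficiency_control=efficiency_control,
            target=self.target,
            control=self.control,
            test_condition=self.test_condition,
            reference_condition=self.reference_condition,
        )
        return CtCtQuantResults(self, results, qc, curves, efficiency_target, efficiency_control)


class CtCtQuantResults:
    """Fitted fold changes per time point with per-fit QC."""

    def __init__(
        self,
        model: CtCtQuantModel,
        fold_changes: list[FoldChangeResult],
        qc: pd.DataFrame,
        standard_curves: Mapping[str, StandardCurve],
        efficiency_target: float,
        efficiency_control: float | None,
    ):
        self.model = model
        self.fold_changes = fold_changes
        self.qc = qc
        self.standard_curves = dict(standard_curves)
        self.efficiency_target = efficiency_target
        self.efficiency_control = efficiency_control

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": [f.time_hr for f in self.fold_changes],
                "fold_change": [f.fold_change for f in self.fold_changes],
                "sem": [f.sem for f in self.fold_changes],
                "n": [f.n for f in self.fold_changes],
            }
        )

    def summary(self) -> str:
        lines = [
            "Ct-Ct relative quantification",
            f"  target {self.model.target} vs control {self.model.control}; "
            f"E_target = {self.efficiency_target:.4f}"
            + (f", E_control = {self.efficiency_control:.4f}" if self.efficiency_control else ""),
            "",
            f"  {'time_hr':>8} {'fold_change':>12} {'sem':>8} {'n':>4}",
        ]
        for f in self.fold_changes:
            sem = f"{f.sem:.3f}" if f.sem is not None else "--"
            lines.append(f"  {f.time_hr:>8g} {f.fold_change:>12.3f} {sem:>8} {f.n:>4d}")
        n_flag = int(self.qc["slope_flag"].sum()) if len(self.qc) else 0
        lines.append("")
        lines.append(f"  slope QC: {n_flag} of {len(self.qc)} fits flagged "
                     f"(|slope - log(E_c)/log(E_g)| > {SLOPE_QC_TOLERANCE})")
        return "\n".join(lines)
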
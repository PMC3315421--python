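"""Synthetic-data generators for qPCR, one-color microarray, and outcome designs.

Every generator mirrors the statistical structure the downstream estimators
assume, so that parameter-recovery (round-trip) tests are meaningful:

* qPCR: threshold cycles are generated from a shared per-sample template
  amount with gene-specific amplification efficiencies, so that the
  (Ct_control, Ct_target) points of one condition lie on a line with slope
  log(E_c)/log(E_g) and intercept -log10(R)/log10(E_g).
* Microarray: probe intensities are per-array scale factors times
  2**(baseline + group effect + Gaussian log2 noise), emulating a one-color
  design with duplicated probe groups.
* Outcomes: Gaussian group draws emulating neurite net-growth and locomotion
  measurement tables.

Ground truth is always returned as a separate record, never embedded in the
data table, so analysis pipelines cannot "see" it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "QpcrSimParams",
    "ArraySimParams",
    "OutcomeSimParams",
    "gen_qpcr_dataset",
    "gen_standard_curve_series",
    "gen_qpcr_timecourse",
    "gen_microarray_dataset",
    "gen_outcome_dataset",
]

CT_COLUMNS = [
    "sample_id",
    "condition",
    "time_hr",
    "gene_role",
    "gene_name",
    "replicate",
    "ct",
    "dilution",
]


class ParameterError(ValueError):
    """A simulation parameter is outside its documented range."""

    def __init__(self, param: str, message: str):
        self.param = param
        super().__init__(f"invalid parameter {param!r}: {message}")


def _check_efficiency(name: str, value: float) -> None:
    if not (1.0 < value <= 2.0):
        raise ParameterError(name, f"amplification efficiency must be in (1, 2], got {value}")


@dataclass(frozen=True)
class QpcrSimParams:
    """Parameters of the paired target/control Ct generator.

    The model: per sample ``s`` a template amount ``A_s = q0 * 10**N(0, spread^2)``
    is drawn; the control gene has ``Q_c = A_s`` template units, the target
    ``Q_g = R * A_s`` where ``R`` is the condition's true expression ratio.
    The threshold cycle is the number of amplification cycles needed to reach
    the common detection threshold ``T``::

        Ct = (log10(T) - log10(Q)) / log10(E) + N(0, ct_noise_sd^2)

    All logs are base 10 (the decade convention of dilution standard curves).
    """

    R_by_condition: Mapping[str, float]
    E_target: float = 2.0
    E_control: float = 2.0
    threshold_T: float = 1e10
    base_quantity_q0: float = 1e4
    sample_spread_sd: float = 0.5
    ct_noise_sd: float = 0.2
    n_samples_per_condition: int = 5
    dilution_series: Sequence[float] = (1.0, 10.0, 100.0)
    seed: int = 0
    target_name: str = "CEBP"
    control_name: str = "GAPDH"

    def validate(self) -> None:
        if not self.R_by_condition:
            raise ParameterError("R_by_condition", "at least one condition required")
        for cond, r in self.R_by_condition.items():
            if not r > 0:
                raise ParameterError("R_by_condition", f"ratio for {cond!r} must be > 0, got {r}")
        _check_efficiency("E_target", self.E_target)
        _check_efficiency("E_control", self.E_control)
        if not self.threshold_T > 0:
            raise ParameterError("threshold_T", "must be > 0")
        if not self.base_quantity_q0 > 0:
            raise ParameterError("base_quantity_q0", "must be > 0")
        if self.sample_spread_sd < 0:
            raise ParameterError("sample_spread_sd", "must be >= 0")
        if self.ct_noise_sd < 0:
            raise ParameterError("ct_noise_sd", "must be >= 0")
        if self.n_samples_per_condition < 2:
            raise ParameterError("n_samples_per_condition", "need >= 2 samples per condition")
        if any(d <= 0 for d in self.dilution_series):
            raise ParameterError("dilution_series", "dilution factors must be > 0")


@dataclass(frozen=True)
class ArraySimParams:
    """Parameters of the one-color microarray intensity generator.

    Defaults emulate the study design this package targets: a 15,000-spot
    chip with 10,333 unique probes (a subset spotted in duplicate, plus
    9-fold technical replicates), hybridised to 4 sham and 4 crush arrays.
    ``true_log2_fc`` names the genes that are genuinely regulated in the
    crush group and their log2 effect sizes.
    """

    n_unique_probes: int = 500
    replicate_groups: Mapping[str, int] | None = None
    n_arrays_per_group: int = 4
    true_log2_fc: Mapping[str, float] = field(default_factory=dict)
    biological_sd: float = 0.25
    array_scale_factors: Sequence[float] | None = None
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    group_names: tuple[str, str] = ("sham", "crush")
    seed: int = 0

    def validate(self) -> None:
        if self.n_unique_probes < 2:
            raise ParameterError("n_unique_probes", "need >= 2 unique probes")
        if self.n_arrays_per_group < 2:
            raise ParameterError("n_arrays_per_group", "need >= 2 arrays per group")
        if self.biological_sd < 0:
            raise ParameterError("biological_sd", "must be >= 0")
        if self.baseline_log2_sd < 0:
            raise ParameterError("baseline_log2_sd", "must be >= 0")
        gene_ids = set(self._gene_ids())
        for g in self.true_log2_fc:
            if g not in gene_ids:
                raise ParameterError("true_log2_fc", f"gene {g!r} is not among unique probes")
        if self.replicate_groups is not None:
            for g, k in self.replicate_groups.items():
                if g not in gene_ids:
                    raise ParameterError("replicate_groups", f"gene {g!r} is not among unique probes")
                if k < 1:
                    raise ParameterError("replicate_groups", f"replicate count for {g!r} must be >= 1")
        if self.array_scale_factors is not None:
            if len(self.array_scale_factors) != 2 * self.n_arrays_per_group:
                raise ParameterError(
                    "array_scale_factors",
                    f"need one factor per array ({2 * self.n_arrays_per_group}), got {len(self.array_scale_factors)}",
                )
            if any(s <= 0 for s in self.array_scale_factors):
                raise ParameterError("array_scale_factors", "scale factors must be > 0")

    def _gene_ids(self) -> list[str]:
        return [f"gene_{i:05d}" for i in range(self.n_unique_probes)]


@dataclass(frozen=True)
class OutcomeSimParams:
    """Group-structured Gaussian outcome generator (neurite growth, locomotion)."""

    group_means: Mapping[str, float]
    group_sds: Mapping[str, float]
    n_per_group: int = 14
    timepoints: Sequence[float] = (0.0,)
    seed: int = 0
    units: str = "um"

    def validate(self) -> None:
        if not self.group_means:
            raise ParameterError("group_means", "at least one group required")
        if set(self.group_means) != set(self.group_sds):
            raise ParameterError("group_sds", "groups must match group_means")
        for g, sd in self.group_sds.items():
            if sd < 0:
                raise ParameterError("group_sds", f"SD for {g!r} must be >= 0")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group", "need n >= 2 per group")
        if len(self.timepoints) == 0:
            raise ParameterError("timepoints", "at least one timepoint required")


def _ct(quantity: np.ndarray | float, efficiency: float, threshold: float) -> np.ndarray:
    return (np.log10(threshold) - np.log10(quantity)) / np.log10(efficiency)


def gen_qpcr_dataset(
    params: QpcrSimParams,
    *,
    time_hr: float = 0.0,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate one paired target/control Ct table.

    Returns a tidy CtTable (one row per gene per sample) and a truth record
    holding the configured ratios and efficiencies.

    With ``ct_noise_sd == 0`` the points of each condition satisfy exactly

        Ct_g = (log E_c / log E_g) * Ct_c - log10(R) / log10(E_g)
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = []
    for cond, ratio in params.R_by_condition.items():
        log_amount = np.log10(params.base_quantity_q0) + rng.normal(
            0.0, params.sample_spread_sd, params.n_samples_per_condition
        )
        amounts = 10.0 ** log_amount
        ct_c = _ct(amounts, params.E_control, params.threshold_T)
        ct_g = _ct(ratio * amounts, params.E_target, params.threshold_T)
        if params.ct_noise_sd > 0:
            ct_c = ct_c + rng.normal(0.0, params.ct_noise_sd, ct_c.shape)
            ct_g = ct_g + rng.normal(0.0, params.ct_noise_sd, ct_g.shape)
        for i in range(params.n_samples_per_condition):
            sid = f"{cond}_t{time_hr:g}_r{replicate}_s{i + 1}"
            rows.append((sid, cond, time_hr, "control", params.control_name, replicate, ct_c[i], np.nan))
            rows.append((sid, cond, time_hr, "target", params.target_name, replicate, ct_g[i], np.nan))
    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    truth = {
        "R_by_condition": dict(params.R_by_condition),
        "E_target": params.E_target,
        "E_control": params.E_control,
        "time_hr": time_hr,
        "replicate": replicate,
    }
    return table, truth


def gen_standard_curve_series(
    efficiency: float,
    dilutions: Sequence[float],
    reps: int = 1,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    *,
    gene_name: str = "gene",
    gene_role: str = "target",
    base_ct: float = 20.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a dilution standard-curve Ct series for one primer pair.

    Ct rises by ``1/log10(E)`` cycles per 10-fold dilution: 3.32 cycles per
    decade at perfect doubling. At least 3 distinct dilutions are required,
    otherwise the slope (and hence the efficiency) is unidentifiable.
    """
    _check_efficiency("efficiency", efficiency)
    dilutions = list(dilutions)
    if len(set(dilutions)) < 3:
        raise ParameterError("dilutions", "need >= 3 distinct dilution factors to identify a slope")
    if any(d <= 0 for d in dilutions):
        raise ParameterError("dilutions", "dilution factors must be > 0")
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd", "must be >= 0")
    if reps < 1:
        raise ParameterError("reps", "must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, reps + 1):
        for d in dilutions:
            ct = base_ct + np.log10(d) / np.log10(efficiency)
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append((f"std_d{d:g}_r{r}", "standard", np.nan, gene_role, gene_name, r, ct, d))
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def gen_qpcr_timecourse(
    base: QpcrSimParams,
    ratios_by_time: Mapping[float, float],
    n_groups: int = 5,
    *,
    sham_ratio: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Assemble a crush-vs-sham time-course CtTable with replicate groups.

    For each time point and each of ``n_groups`` independent replicate groups,
    a fresh paired dataset is generated with the sham condition at
    ``sham_ratio`` and the crush condition at the time point's true ratio.
    The ``replicate`` column holds the group index, the unit over which
    fold-change mean +/- SEM is later computed.
    """
    base.validate()
    if n_groups < 1:
        raise ParameterError("n_groups", "must be >= 1")
    rng = np.random.default_rng(base.seed)
    tables = []
    for t, ratio in ratios_by_time.items():
        for g in range(1, n_groups + 1):
            p = QpcrSimParams(
                R_by_condition={"sham": sham_ratio, "crush": ratio},
                E_target=base.E_target,
                E_control=base.E_control,
                threshold_T=base.threshold_T,
                base_quantity_q0=base.base_quantity_q0,
                sample_spread_sd=base.sample_spread_sd,
                ct_noise_sd=base.ct_noise_sd,
                n_samples_per_condition=base.n_samples_per_condition,
                seed=base.seed,
                target_name=base.target_name,
                control_name=base.control_name,
            )
            tab, _ = gen_qpcr_dataset(p, time_hr=t, replicate=g, rng=rng)
            tables.append(tab)
    truth = {
        "ratios_by_time": dict(ratios_by_time),
        "sham_ratio": sham_ratio,
        "E_target": base.E_target,
        "E_control": base.E_control,
        "n_groups": n_groups,
    }
    return pd.concat(tables, ignore_index=True), truth


def gen_microarray_dataset(params: ArraySimParams) -> tuple[pd.DataFrame, dict]:
    """Generate a probe-level one-color intensity matrix plus truth record.

    Intensity of probe p (of gene g) on array a::

        I = scale_a * 2 ** (baseline_g + fc_g * [a in crush] + eps_{p,a})

    with ``eps ~ N(0, biological_sd^2)`` independent per probe and array, so
    duplicate probes of a gene share the gene-level signal but carry
    independent noise, which the downstream median collapse attenuates.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = params._gene_ids()
    rep_counts = {g: 1 for g in genes}
    if params.replicate_groups:
        rep_counts.update(params.replicate_groups)

    probe_rows = []  # (probe_id, gene_id)
    for g in genes:
        for k in range(1, rep_counts[g] + 1):
            probe_rows.append((f"{g}_p{k}", g))
    n_probes = len(probe_rows)

    g1, g2 = params.group_names
    n = params.n_arrays_per_group
    arrays = [f"{g1}_{i + 1}" for i in range(n)] + [f"{g2}_{i + 1}" for i in range(n)]
    in_group2 = np.array([0] * n + [1] * n, dtype=float)

    baselines = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, len(genes))
    baseline_by_gene = dict(zip(genes, baselines))
    fc = {g: params.true_log2_fc.get(g, 0.0) for g in genes}

    if params.array_scale_factors is None:
        scales = 2.0 ** rng.normal(0.0, 0.25, len(arrays))
    else:
        scales = np.asarray(params.array_scale_factors, dtype=float)

    log2_signal = np.empty((n_probes, len(arrays)))
    for i, (_pid, g) in enumerate(probe_rows):
        log2_signal[i] = baseline_by_gene[g] + fc[g] * in_group2
    if params.biological_sd > 0:
        log2_signal += rng.normal(0.0, params.biological_sd, log2_signal.shape)
    intensities = scales[None, :] * 2.0 ** log2_signal

    out = pd.DataFrame(
        {
            "probe_id": [p for p, _ in probe_rows],
            "gene_id": [g for _, g in probe_rows],
            "replicate_group": [g for _, g in probe_rows],
        }
    )
    for j, a in enumerate(arrays):
        out[a] = intensities[:, j]
    truth = {
        "regulated_genes": {g: v for g, v in params.true_log2_fc.items() if v != 0.0},
        "biological_sd": params.biological_sd,
        "array_scale_factors": [float(s) for s in scales],
        "group_names": list(params.group_names),
    }
    return out, truth


def gen_outcome_dataset(params: OutcomeSimParams) -> pd.DataFrame:
    """Generate a tidy outcome-measurement table (group, timepoint, subject)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows = []
    for t in params.timepoints:
        for g, mu in params.group_means.items():
            draws = mu + rng.normal(0.0, params.group_sds[g], params.n_per_group)
            for i, v in enumerate(draws, start=1):
                rows.append((f"{g}_s{i}", g, t, v))
    return pd.DataFrame(rows, columns=["subject_id", "group", "time", "value"])
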
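"""One-color microarray differential expression.

Pipeline, in fixed order: 75th-percentile scaling per array (linear scale),
log2 transform, median collapse of replicate probes to genes, per-gene
unpaired equal-variance t-test between array groups, then a raw p < alpha
significance filter combined with a fold-change cutoff (2-fold by default).
Benjamini-Hochberg q-values are reported for context alongside the raw-p
filter, which is what the filtering actually uses. Hierarchical clustering
of the regulated genes (Pearson-correlation distance, average linkage)
supplies a deterministic heat-map row ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ANNOTATION_COLUMNS",
    "percentile_normalize",
    "collapse_replicate_probes",
    "gene_ttest",
    "DESummary",
    "summary_from_counts",
    "ClusterOrdering",
    "hierarchical_cluster",
    "MicroarrayDEModel",
    "DEResults",
]

ANNOTATION_COLUMNS = ["probe_id", "gene_id", "replicate_group"]


def _split(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    ann = [c for c in ANNOTATION_COLUMNS if c in matrix.columns]
    arrays = [c for c in matrix.columns if c not in ann]
    return matrix[ann], arrays


def percentile_normalize(matrix: pd.DataFrame, q: float = 75.0) -> pd.DataFrame:
    """Scale each array to its own q-th percentile, then log2 transform.

    Input intensities must be linear-scale and strictly positive. Percentiles
    use the linear-interpolation definition, so after scaling every array's
    q-th percentile is exactly 1 (0 on the log2 scale). Arrays that are
    scalar multiples of one another become identical, which is the point of
    between-array scaling in a one-color design.
    """
    if not (0 < q < 100):
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    ann, arrays = _split(matrix)
    values = matrix[arrays].to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        rows = matrix.index[bad.any(axis=1)].tolist()
        probes = (
            matrix.loc[rows, "probe_id"].tolist() if "probe_id" in matrix.columns else rows
        )
        raise ValueError(f"non-positive intensities at probes {probes[:10]} (linear scale required)")
    scale = np.percentile(values, q, axis=0)
    out = ann.copy()
    normalized = np.log2(values / scale[None, :])
    for j, a in enumerate(arrays):
        out[a] = normalized[:, j]
    return out


def collapse_replicate_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate probes to one row per gene by the per-array median.

    Expects a log2-scale matrix with a ``replicate_group`` column naming each
    probe's gene; singleton groups pass through unchanged. The median is the
    robust choice for the 2- and 9-fold replicated probes of spotted designs.
    """
    if "replicate_group" not in matrix.columns:
        raise KeyError("matrix lacks a 'replicate_group' column")
    if matrix["replicate_group"].isna().any():
        orphans = matrix.loc[matrix["replicate_group"].isna(), "probe_id"].tolist()
        raise ValueError(f"probes without replicate-group assignment: {orphans[:10]}")
    _, arrays = _split(matrix)
    collapsed = matrix.groupby("replicate_group", sort=True)[arrays].median()
    collapsed.index.name = "gene_id"
    return collapsed.reset_index()


def gene_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided unpaired equal-variance (Student) t-test.

    Returns (t, df, p) with df = n_a + n_b - 2. Degenerate zero-variance
    input: equal means give t = 0, p = 1; unequal means give p -> 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 finite values per group for a t-test")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t-test input")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


@dataclass(frozen=True)
class DESummary:
    """Counts and percentages of regulated genes.

    Percentages are taken of the significant set (raw p < alpha): the share
    changing by at least the fold cutoff, and its up/down split. Rounding is
    half-up to one decimal.
    """

    n_tested: int
    n_significant: int
    n_fc: int
    n_up: int
    n_down: int

    def __post_init__(self):
        if self.n_up + self.n_down != self.n_fc:
            raise ValueError("n_fc must equal n_up + n_down")
        if not (self.n_fc <= self.n_significant <= self.n_tested):
            raise ValueError("need n_fc <= n_significant <= n_tested")

    @staticmethod
    def _pct(count: int, total: int, decimals: int = 1) -> float:
        if total == 0:
            return float("nan")
        # round-half-up, not banker's rounding
        shift = 10**decimals
        return float(np.floor(100.0 * count / total * shift + 0.5) / shift)

    @property
    def pct_fc_of_significant(self) -> float:
        return self._pct(self.n_fc, self.n_significant)

    @property
    def pct_up_of_significant(self) -> float:
        return self._pct(self.n_up, self.n_significant)

    @property
    def pct_down_of_significant(self) -> float:
        return self._pct(self.n_down, self.n_significant)

    @property
    def pct_lt_fc_of_significant(self) -> float:
        return self._pct(self.n_significant - self.n_fc, self.n_significant)

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        """Percentage breakdown of the significant set at a chosen precision
        (0 decimals when quoting against whole-percent figures)."""
        return {
            "pct_fc_of_significant": self._pct(self.n_fc, self.n_significant, decimals),
            "pct_up_of_significant": self._pct(self.n_up, self.n_significant, decimals),
            "pct_down_of_significant": self._pct(self.n_down, self.n_significant, decimals),
            "pct_lt_fc_of_significant": self._pct(
                self.n_significant - self.n_fc, self.n_significant, decimals
            ),
        }

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_tested": [self.n_tested],
                "n_significant": [self.n_significant],
                "n_fc": [self.n_fc],
                "n_up": [self.n_up],
                "n_down": [self.n_down],
                "pct_fc_of_significant": [self.pct_fc_of_significant],
                "pct_up_of_significant": [self.pct_up_of_significant],
                "pct_down_of_significant": [self.pct_down_of_significant],
                "pct_lt_fc_of_significant": [self.pct_lt_fc_of_significant],
            }
        )


def summary_from_counts(n_tested: int, n_significant: int, n_up: int, n_down: int) -> DESummary:
    """Build a DESummary from published-style counts (worked-example entry point)."""
    return DESummary(
        n_tested=n_tested,
        n_significant=n_significant,
        n_fc=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
    )


@dataclass(frozen=True)
class ClusterOrdering:
    """Agglomerative merge tree and the leaf order it induces."""

    linkage: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    leaf_order: list[str]
    labels: list[str]
    metric: str
    linkage_method: str
    zero_variance_genes: list[str]


def _correlation_distance(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise 1 - Pearson r between rows; zero-variance rows get maximal
    dissimilarity (distance 1) to every other row."""
    sd = values.std(axis=1)
    zero_var = sd == 0
    n = values.shape[0]
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = ~zero_var
    if ok.sum() >= 2:
        r = np.corrcoef(values[ok])
        dist[np.ix_(ok, ok)] = 1.0 - r
        np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return dist, zero_var


def hierarchical_cluster(
    matrix: pd.DataFrame,
    *,
    label_column: str = "gene_id",
    metric: str = "correlation",
    method: str = "average",
) -> ClusterOrdering:
    """Cluster genes for heat-map ordering.

    Pearson-correlation distance (1 - r) with average linkage by default.
    Rows of zero variance have undefined correlation; their distance to every
    other row is defined as 1 (maximal dissimilarity) and they are listed in
    the result for the caller's log.
    """
    if label_column in matrix.columns:
        labels = matrix[label_column].astype(str).tolist()
        values = matrix.drop(columns=[c for c in ANNOTATION_COLUMNS if c in matrix.columns]).to_numpy(float)
    else:
        labels = [str(i) for i in matrix.index]
        values = matrix.to_numpy(float)
    if len(labels) < 2:
        raise ValueError("need >= 2 genes to cluster")
    if metric == "correlation":
        dist, zero_var = _correlation_distance(values)
    elif metric == "euclidean":
        d = values[:, None, :] - values[None, :, :]
        dist = np.sqrt((d**2).sum(axis=2))
        zero_var = np.zeros(len(labels), dtype=bool)
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    order = hierarchy.leaves_list(link)
    return ClusterOrdering(
        linkage=link,
        leaf_order=[labels[i] for i in order],
        labels=labels,
        metric=metric,
        linkage_method=method,
        zero_variance_genes=[labels[i] for i in np.flatnonzero(zero_var)],
    )


class MicroarrayDEModel:
    """Differential-expression model for a probe-level one-color design.

    Parameters
    ----------
    matrix : DataFrame
        Probe-level linear intensities: annotation columns ``probe_id``,
        ``gene_id``, ``replicate_group`` followed by one column per array.
    design : mapping or None
        array label -> group label. If None, groups are parsed from array
        names of the form ``<group>_<index>``.
    alpha : float
        Raw-p significance cutoff.
    fold_cutoff : float
        Linear fold-change magnitude a significant gene must reach to count
        as regulated.
    reference, test : str
        Group labels; fold changes are test over reference.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design: dict[str, str] | None = None,
        *,
        alpha: float = 0.05,
        fold_cutoff: float = 2.0,
        percentile_q: float = 75.0,
        reference: str = "sham",
        test: str = "crush",
    ):
        if not (0 < alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        if fold_cutoff < 1:
            raise ValueError(f"fold cutoff must be >= 1, got {fold_cutoff}")
        self.matrix = matrix
        _, arrays = _split(matrix)
        if design is None:
            design = {a: a.rsplit("_", 1)[0] for a in arrays}
        self.design = design
        self.alpha = alpha
        self.fold_cutoff = fold_cutoff
        self.percentile_q = percentile_q
        self.reference = reference
        self.test = test
        for grp in (reference, test):
            n = sum(1 for a in arrays if design.get(a) == grp)
            if n < 2:
                raise ValueError(f"group {grp!r} has {n} arrays; need >= 2 for a t-test")

    def fit(self) -> "DEResults":
        """Run normalize -> log2 -> collapse -> test -> filter."""
        norm = percentile_normalize(self.matrix, q=self.percentile_q)
        genes = collapse_replicate_probes(norm)
        _, arrays = _split(genes)
        cols_ref = [a for a in arrays if self.design.get(a) == self.reference]
        cols_tst = [a for a in arrays if self.design.get(a) == self.test]
        ref = genes[cols_ref].to_numpy(float)
        tst = genes[cols_tst].to_numpy(float)

        n1, n2 = ref.shape[1], tst.shape[1]
        df = n1 + n2 - 2
        t, p = stats.ttest_ind(tst, ref, axis=1, equal_var=True)
        # zero pooled variance: equal means -> t=0,p=1; unequal -> degenerate p=0
        degenerate = ~np.isfinite(t)
        mean_ref = ref.mean(axis=1)
        mean_tst = tst.mean(axis=1)
        equal = degenerate & (mean_ref == mean_tst)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, np.where(degenerate, 0.0, p))

        log2_fc = mean_tst - mean_ref
        signed_fold = np.sign(log2_fc) * 2.0 ** np.abs(log2_fc)
        signed_fold = np.where(log2_fc == 0, 1.0, signed_fold)
        q = multipletests(p, method="fdr_bh")[1]

        res = pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "mean_log2_sham": mean_ref,
                "mean_log2_crush": mean_tst,
                "log2_fc": log2_fc,
                "fold_change_signed": signed_fold,
                "t_statistic": t,
                "degrees_of_freedom": df,
                "p_value": p,
                "q_value_bh": q,
                "passes_p": p < self.alpha,
                "passes_fc": np.abs(log2_fc) >= np.log2(self.fold_cutoff),
            }
        ).sort_values("p_value", kind="mergesort", ignore_index=True)

        regulated = res["passes_p"] & res["passes_fc"]
        summary = DESummary(
            n_tested=len(res),
            n_significant=int(res["passes_p"].sum()),
            n_fc=int(regulated.sum()),
            n_up=int((regulated & (res["log2_fc"] > 0)).sum()),
            n_down=int((regulated & (res["log2_fc"] < 0)).sum()),
        )
        return DEResults(self, res, summary, gene_matrix=genes)


class DEResults:
    """Per-gene test results, regulated-gene summary, and clustering helper."""

    def __init__(self, model: MicroarrayDEModel, table: pd.DataFrame, de_summary: DESummary, gene_matrix: pd.DataFrame):
        self.model = model
        self.table = table
        self.de_summary = de_summary
        self.gene_matrix = gene_matrix

    @property
    def regulated_genes(self) -> list[str]:
        mask = self.table["passes_p"] & self.table["passes_fc"]
        return self.table.loc[mask, "gene_id"].tolist()

    def cluster_regulated(self, **kwargs) -> ClusterOrdering:
        """Hierarchically cluster the regulated genes' log2 profiles."""
        sub = self.gene_matrix[self.gene_matrix["gene_id"].isin(self.regulated_genes)]
        return hierarchical_cluster(sub, **kwargs)

    def summary(self) -> str:
        s = self.de_summary
        lines = [
            "One-color microarray differential expression",
            f"  design: {self.model.test} vs {self.model.reference}; "
            f"alpha = {self.model.alpha}, fold cutoff = {self.model.fold_cutoff}",
            f"  genes tested:            {s.n_tested}",
            f"  significant (p < alpha): {s.n_significant}",
            f"  >= {self.model.fold_cutoff:g}-fold of those:     {s.n_fc} "
            f"({s.pct_fc_of_significant}% of significant)",
            f"    up-regulated:          {s.n_up} ({s.pct_up_of_significant}%)",
            f"    down-regulated:        {s.n_down} ({s.pct_down_of_significant}%)",
        ]
        return "\n".join(lines)
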
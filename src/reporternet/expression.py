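"""Expression-matrix handling and per-gene differential testing.

The analysis starts from probe/gene x sample intensity matrices with a
sample sheet assigning each sample to a (group, time_point) cell, where
group is ``control`` or ``treatment``.  Intensities are quantile
normalized across all samples, log2 transformed, optionally inspected by
PCA, and reduced to one two-sample t-test p-value per row.  Probe-level
p-values are collapsed to gene level with a configurable top-probe rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, StructuralError, ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATMENT = "treatment"


@dataclass
class ExpressionMatrix:
    """A rectangular probes/genes x samples matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by row id (probe or gene), one column per sample.
    samples
        DataFrame indexed by sample id with columns ``group`` (control or
        treatment) and ``time_point``.  Optional; defaults to an empty sheet
        so purely numeric operations work without metadata.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["group", "time_point"]))

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise StructuralError(f"duplicate row ids: {dup[:5]}")
        if not self.samples.empty:
            missing = [s for s in self.samples.index if s not in self.values.columns]
            if missing:
                raise StructuralError(f"sample sheet entries absent from matrix: {missing[:5]}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        sheet = self.samples.loc[[s for s in sample_ids if s in self.samples.index]]
        return ExpressionMatrix(self.values[sample_ids].copy(), sheet.copy())

    @classmethod
    def from_tsv(cls, matrix_path, sample_sheet_path=None) -> "ExpressionMatrix":
        """Read a TSV matrix (first column = row id) and optional sample sheet."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        if sample_sheet_path is not None:
            sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
        else:
            sheet = pd.DataFrame(columns=["group", "time_point"])
        return cls(values, sheet)

    def to_tsv(self, matrix_path, sample_sheet_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="row_id")
        if sample_sheet_path is not None:
            self.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def _check_finite(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("expression matrix contains non-finite values")


def drop_missing_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop rows containing any missing value, logging how many were lost."""
    mask = matrix.values.notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing values", n_dropped)
    return ExpressionMatrix(matrix.values.loc[mask].copy(), matrix.samples.copy())


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the shared mean order-statistic profile.

    The reference distribution is the across-column mean of within-column
    order statistics.  Ties within a column receive the mean of their tied
    reference values, so tied inputs stay tied in the output.
    """
    if matrix.values.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    _check_finite(matrix.values)
    vals = matrix.values.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference values over groups of tied input values
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col), sort=False).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples.copy())


def log2_vs_control(matrix: ExpressionMatrix, time_point) -> ExpressionMatrix:
    """Log2-transform the samples of one time point, pairing treatment to control.

    Returns the log2 intensities of every sample annotated with
    ``time_point``; the sample sheet of the result records, for treatment
    samples, the control group they are compared against
    (column ``paired_control_time``).
    """
    if matrix.samples.empty:
        raise ConfigurationError("log2_vs_control requires a sample sheet")
    sheet = matrix.samples
    sel = sheet[sheet["time_point"] == time_point]
    groups = set(sel["group"])
    if CONTROL not in groups:
        raise ConfigurationError(f"no control samples for time point {time_point!r}")
    sub = matrix.subset_samples(list(sel.index))
    arr = sub.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValidationError("log2 transform requires strictly positive intensities")
    values = pd.DataFrame(np.log2(arr), index=sub.values.index, columns=sub.values.columns)
    out_sheet = sub.samples.copy()
    out_sheet["paired_control_time"] = [
        time_point if g == TREATMENT else "" for g in out_sheet["group"]
    ]
    return ExpressionMatrix(values, out_sheet)


def pca_scores(matrix: ExpressionMatrix, n_components: int):
    """Project samples onto principal axes of the row space.

    Returns ``(scores, explained)`` where ``scores`` is a samples x
    components DataFrame and ``explained`` the fraction of variance per
    component (non-increasing).
    """
    from sklearn.decomposition import PCA

    n_rows, n_samples = matrix.values.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if n_components > min(n_rows, n_samples):
        raise ValidationError(
            f"n_components={n_components} exceeds min(rows, samples)={min(n_rows, n_samples)}"
        )
    _check_finite(matrix.values)
    X = matrix.values.to_numpy(dtype=float).T  # samples as observations
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(X)
    scores = pd.DataFrame(
        proj,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, pca.explained_variance_ratio_.copy()


def ttest_pvalues(control: ExpressionMatrix, treatment: ExpressionMatrix) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per row, treatment minus control.

    Returns a DataFrame indexed by row id with columns ``t`` (signed
    treatment − control), ``p`` (two-sided) and ``degenerate`` (True where
    both groups had zero variance).  Rows with any missing value in either
    group are dropped with a logged count.  By convention a row with zero
    variance in both groups gets p = 1 when the means agree and p = 0
    (flagged degenerate) when they differ.
    """
    common = control.values.index.intersection(treatment.values.index)
    if len(common) == 0:
        raise ValidationError("control and treatment share no row ids")
    ctl = control.values.loc[common]
    trt = treatment.values.loc[common]
    if ctl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValidationError("need at least 2 replicates per group")
    keep = ctl.notna().all(axis=1) & trt.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("ttest_pvalues: dropping %d rows with missing values", n_dropped)
    a = trt.loc[keep].to_numpy(dtype=float)
    b = ctl.loc[keep].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = zero_var & (mean_diff != 0)
    t = np.where(zero_var & (mean_diff == 0), 0.0, t)
    p = np.where(zero_var & (mean_diff == 0), 1.0, p)
    if degenerate.any():
        t[degenerate] = np.sign(mean_diff[degenerate]) * np.inf
        p[degenerate] = 0.0
    return pd.DataFrame(
        {"t": t, "p": p, "degenerate": degenerate},
        index=ctl.index[keep],
    )


def gene_pvalue_from_probes(
    probe_pvalues: Mapping[str, float],
    probe_map: pd.DataFrame,
    rule: Literal["min_p", "rank"] = "min_p",
) -> pd.Series:
    """Collapse probe-set p-values to one p-value per gene.

    ``probe_map`` needs columns ``probe_id`` and ``gene_id`` (and ``rank``
    for the rank rule).  The default ``min_p`` rule keeps the most
    significant probe of each gene; ``rank`` keeps the probe with the
    smallest declared rank.  Probes absent from the map are dropped with a
    logged count; genes without any mapped probe are absent from the output.
    """
    if rule not in ("min_p", "rank"):
        raise ValidationError(f"unknown top-probe rule {rule!r}")
    pm = probe_map.set_index("probe_id") if "probe_id" in probe_map.columns else probe_map
    records = []
    n_unmapped = 0
    for probe, p in probe_pvalues.items():
        if probe not in pm.index:
            n_unmapped += 1
            continue
        row = pm.loc[probe]
        rank = row.get("rank", np.nan) if isinstance(row, pd.Series) else np.nan
        records.append((row["gene_id"], probe, float(p), rank))
    if n_unmapped:
        logger.warning("gene_pvalue_from_probes: %d probes had no gene mapping", n_unmapped)
    if not records:
        logger.warning("gene_pvalue_from_probes: empty probe/map intersection")
        return pd.Series(dtype=float, name="p")
    df = pd.DataFrame(records, columns=["gene_id", "probe_id", "p", "rank"])
    if rule == "min_p":
        out = df.groupby("gene_id")["p"].min()
    else:
        if df["rank"].isna().any():
            raise ValidationError("rank rule requires a rank for every mapped probe")
        idx = df.groupby("gene_id")["rank"].idxmin()
        out = df.loc[idx].set_index("gene_id")["p"]
    out.name = "p"
    return out.sort_index()


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """Optional BH adjustment for users who want FDR-controlled gene calls."""
    from scipy.stats import false_discovery_control

    adj = false_discovery_control(pvalues.to_numpy(dtype=float), method="bh")
    return pd.Series(adj, index=pvalues.index, name="p_bh")
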
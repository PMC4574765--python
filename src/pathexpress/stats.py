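"""Two-group differential expression over a log2 expression matrix.

This is the analysis core behind the data-engine endpoints: per-gene fold
change (difference of group means on the log2 scale, so 0 is the neutral
point), per-sample fold change relative to the reference-group mean,
two-sample t-tests (Welch by default) and Benjamini–Hochberg adjustment.

Conventions that matter for interpretation:

* the input matrix is assumed to already be on the log2 scale; "fold
  change" everywhere means ``mean(case) - mean(reference)`` in log2 units
  (use :func:`linear_ratio` for a linear-scale display value);
* BH q-values are always computed over the full gene universe of the
  dataset and then subset to a query — adjusting within a queried subset
  would make q-values depend on the query;
* genes absent from the dataset yield ``None`` at query operations, never
  errors: pathway gene sets routinely exceed array content;
* degenerate zero-variance groups use documented conventions instead of
  NaN: equal means → t=0, p=1; different means → t=±inf, p=0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DatasetError",
    "ExpressionDataset",
    "GeneStatistics",
    "load_dataset",
    "mean_log2_fold_change",
    "per_sample_fold_change",
    "two_sample_t",
    "bh_adjust",
    "differential_expression",
    "raw_expression",
    "linear_ratio",
]

TTestVariant = Literal["welch", "student"]


class DatasetError(ValueError):
    """Invalid expression matrix / design combination."""


@dataclass
class ExpressionDataset:
    """A genes × samples log2 expression matrix with a two-level group factor.

    Parameters
    ----------
    values
        DataFrame of log2 intensities; index = gene ids, columns = sample ids.
    groups
        Mapping sample id → group label; exactly two distinct labels, each
        with at least two samples.
    reference_group
        Which of the two labels is the reference (denominator) group.  The
        other label is the case group; fold changes are case − reference.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    reference_group: str

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DatasetError(f"duplicate gene id {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DatasetError(f"duplicate sample id {dup!r}")
        for s in cols:
            if s not in self.groups:
                raise DatasetError(f"sample {s!r} missing from design")
        for s in self.groups:
            if s not in cols:
                raise DatasetError(f"design sample {s!r} not in expression matrix")
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise DatasetError(
                f"expected exactly two group labels, got {labels!r}"
            )
        if self.reference_group not in labels:
            raise DatasetError(
                f"reference group {self.reference_group!r} is not one of {labels!r}"
            )
        for lab in labels:
            n = sum(1 for g in self.groups.values() if g == lab)
            if n < 2:
                raise DatasetError(f"group {lab!r} has {n} sample(s); need >= 2")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_group(self) -> str:
        labels = set(self.groups.values())
        labels.discard(self.reference_group)
        return labels.pop()

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == self.reference_group]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] != self.reference_group]


@dataclass(frozen=True)
class GeneStatistics:
    """Per-gene differential-expression summary."""

    gene_id: str
    log2_fc: float
    t_stat: float
    p_value: float
    q_value: float


def load_dataset(
    matrix_file: str | Path,
    design_file: str | Path,
    reference_group: str,
) -> ExpressionDataset:
    """Load a tab-delimited genes × samples matrix plus a sample→group design.

    The matrix has gene ids in the first column and sample ids in the header
    row; values are taken as already log2-scale.  The design file is a
    two-column table (sample id, group label) with a header row.
    """
    values = pd.read_csv(matrix_file, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    design = pd.read_csv(design_file, sep="\t", dtype=str)
    if design.shape[1] < 2:
        raise DatasetError(
            f"design file {design_file} must have two columns (sample, group)"
        )
    groups = dict(zip(design.iloc[:, 0], design.iloc[:, 1]))
    return ExpressionDataset(values=values, groups=groups, reference_group=reference_group)


def mean_log2_fold_change(
    ds: ExpressionDataset, genes: Iterable[str]
) -> dict[str, float | None]:
    """Per-gene log2 fold change, case mean − reference mean.

    Genes absent from the dataset map to ``None`` (they are data, not
    errors); an empty query yields an empty mapping.
    """
    case = ds.values[ds.case_samples]
    ref = ds.values[ds.reference_samples]
    out: dict[str, float | None] = {}
    for g in genes:
        if g in ds.values.index:
            out[g] = float(case.loc[g].mean() - ref.loc[g].mean())
        else:
            out[g] = None
    return out


def per_sample_fold_change(
    ds: ExpressionDataset, gene: str
) -> list[tuple[str, float]]:
    """Each sample's log2 value minus the reference-group mean, in dataset order.

    The bar-chart view of a single gene: reference entries average to zero,
    case entries show the per-sample shift.
    """
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    row = ds.values.loc[gene]
    ref_mean = row[ds.reference_samples].mean()
    return [(s, float(row[s] - ref_mean)) for s in ds.sample_ids]


def _degenerate_t(mx: float, my: float) -> tuple[float, float]:
    # Both groups constant: no within-group noise to test against.
    if mx == my:
        return 0.0, 1.0
    return float(np.copysign(np.inf, mx - my)), 0.0


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: TTestVariant = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test of ``x`` versus ``y``.

    Welch (unequal variances, Welch–Satterthwaite df) by default;
    ``variant="student"`` pools variances.  Swapping the groups negates t
    and preserves p.  Zero variance in both groups falls back to the
    documented conventions (equal means → t=0, p=1; else t=±inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return _degenerate_t(float(x[0]), float(y[0]))
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q_i = min_{j: p_(j) >= p_(i)} min(1, p_(j) * n / rank(j))`` — output is
    elementwise ≥ input and ≤ 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        bad = arr[(arr < 0) | (arr > 1) | np.isnan(arr)][0]
        raise ValueError(f"p-value {bad!r} outside [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def differential_expression(
    ds: ExpressionDataset, variant: TTestVariant = "welch"
) -> list[GeneStatistics]:
    """Fold change, t, raw p and BH q for every gene of the dataset.

    Vectorized over genes; q-values are adjusted over the full gene
    universe, so subsetting the result never changes a gene's q.
    Deterministic for a fixed dataset.
    """
    case = ds.values[ds.case_samples].to_numpy(dtype=float)
    ref = ds.values[ds.reference_samples].to_numpy(dtype=float)
    fc = case.mean(axis=1) - ref.mean(axis=1)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision warning; their t/p are replaced below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(case, ref, axis=1, equal_var=(variant == "student"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)

    flat = (np.ptp(case, axis=1) == 0) & (np.ptp(ref, axis=1) == 0)
    if flat.any():
        equal = flat & (fc == 0)
        diff = flat & (fc != 0)
        t[equal], p[equal] = 0.0, 1.0
        t[diff] = np.copysign(np.inf, fc[diff])
        p[diff] = 0.0

    q = bh_adjust(p)
    return [
        GeneStatistics(g, float(fc[i]), float(t[i]), float(p[i]), float(q[i]))
        for i, g in enumerate(ds.gene_ids)
    ]


def raw_expression(
    ds: ExpressionDataset, genes: Iterable[str]
) -> dict[str, dict | None]:
    """Full expression rows for the requested genes, samples in dataset order.

    Present genes map to ``{"samples": [...], "values": [...]}``; absent
    genes map to ``None``.
    """
    out: dict[str, dict | None] = {}
    samples = ds.sample_ids
    for g in genes:
        if g in ds.values.index:
            out[g] = {
                "samples": samples,
                "values": [float(v) for v in ds.values.loc[g]],
            }
        else:
            out[g] = None
    return out


def linear_ratio(log2_fc: float | None) -> float | None:
    """Linear-scale fold ratio ``2**log2_fc`` for display purposes."""
    return None if log2_fc is None else float(2.0 ** log2_fc)
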
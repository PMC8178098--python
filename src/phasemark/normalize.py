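"""Cross-platform meta-analysis normalization.

Each dataset is quantile-normalized independently: every sample's order
statistics are replaced by the across-sample average of order statistics
(the reference distribution), so after normalization all samples of a
dataset share one value distribution.  Genes measured by several probes
are collapsed to their per-sample median *before* normalization, matching
the meta-analysis order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, ProbeAnnotation


@dataclass
class NormalizationAudit:
    dataset_id: str
    reference_quantiles: np.ndarray
    n_probes_collapsed: int = 0
    tie_policy: str = "mean-of-tied-ranks"

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_quantiles, dtype=float)
        if np.any(np.diff(ref) < 0):
            raise ValueError("reference quantiles must be non-decreasing")
        self.reference_quantiles = ref


def average_quantile_reference(matrices: list[ExpressionMatrix]) -> np.ndarray:
    """Shared reference: the across-dataset mean of per-dataset average
    order statistics.  All matrices must have the same column count."""
    refs = []
    for m in matrices:
        if m.missing_mask.any():
            raise ValueError("impute missing values before building a reference")
        refs.append(np.sort(m.values, axis=1).mean(axis=0))
    if len({r.size for r in refs}) != 1:
        raise ValueError("matrices must share a column count")
    return np.mean(refs, axis=0)


def quantile_normalize(
    matrix: ExpressionMatrix,
    dataset_id: str = "",
    reference: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, NormalizationAudit]:
    """Force every sample onto the average-quantile reference distribution.

    By default the reference is this dataset's own across-sample mean of
    order statistics; pass ``reference`` (e.g. from
    :func:`average_quantile_reference`) to transform several datasets onto
    one shared target, which is what aligns platforms with different value
    scales.  Tied values within a sample receive the mean of the reference
    values at their tied ranks, so ties stay tied and within-sample rank
    order is preserved.
    """
    if matrix.missing_mask.any():
        raise ValueError(
            "matrix contains missing values; run curation.impute_missing_zero first"
        )
    if reference is None and matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = matrix.values
    order = np.argsort(X, axis=1, kind="stable")
    if reference is None:
        sorted_vals = np.take_along_axis(X, order, axis=1)
        reference = sorted_vals.mean(axis=0)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.size != matrix.n_probes:
            raise ValueError("reference length must equal the probe count")
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        row = np.empty(X.shape[1])
        row[order[i]] = reference
        # ties within the sample -> mean reference over the tied ranks
        uniq, inverse, counts = np.unique(
            X[i], return_inverse=True, return_counts=True
        )
        if uniq.size != X.shape[1]:
            sums = np.bincount(inverse, weights=row)
            row = (sums / counts)[inverse]
        out[i] = row
    norm = ExpressionMatrix(
        list(matrix.sample_ids),
        list(matrix.probe_ids),
        out,
        np.zeros_like(out, dtype=bool),
    )
    return norm, NormalizationAudit(dataset_id, reference)


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation
) -> tuple[ExpressionMatrix, int]:
    """Collapse multi-probe genes to their per-sample median.

    Output columns are gene ids in order of first probe occurrence;
    probes absent from the annotation are kept under their probe id.
    Returns the collapsed matrix and the number of probes collapsed away.
    """
    groups: dict[str, list[int]] = {}
    for j, probe in enumerate(matrix.probe_ids):
        key = annotation.gene_for(probe) or probe
        groups.setdefault(key, []).append(j)
    vals = matrix.values.copy()
    vals[matrix.missing_mask] = np.nan
    cols = []
    for key, idx in groups.items():
        with np.errstate(all="ignore"):
            cols.append(np.nanmedian(vals[:, idx], axis=1))
    out = np.column_stack(cols)
    collapsed = ExpressionMatrix(
        list(matrix.sample_ids), list(groups), out, np.isnan(out)
    )
    return collapsed, matrix.n_probes - collapsed.n_probes


@dataclass
class LabeledDataset:
    """Integrated case/control matrix with binary labels and provenance."""

    sample_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    source: list[str]


def integrate_labeled(
    datasets: list[tuple[str, ExpressionMatrix, np.ndarray]],
    gene_subset: list[str],
) -> LabeledDataset:
    """Row-concatenate datasets restricted to ``gene_subset`` (stated order).

    Each element of ``datasets`` is (dataset_id, matrix, per-sample binary
    labels).  Every dataset must contain every requested gene.
    """
    if not datasets:
        raise ValueError("no datasets to integrate")
    rows, labels, ids, src = [], [], [], []
    for ds_id, matrix, y in datasets:
        missing = [g for g in gene_subset if g not in matrix.probe_ids]
        if missing:
            raise ValueError(f"dataset {ds_id!r} is missing genes {missing}")
        sub = matrix.subset_probes(list(gene_subset))
        y = np.asarray(y, dtype=int)
        if y.shape[0] != sub.n_samples:
            raise ValueError(f"dataset {ds_id!r}: label length mismatch")
        rows.append(sub.values)
        labels.append(y)
        ids.extend(f"{ds_id}:{s}" for s in sub.sample_ids)
        src.extend([ds_id] * sub.n_samples)
    return LabeledDataset(
        ids, list(gene_subset), np.vstack(rows), np.concatenate(labels), src
    )


def integrate_cohorts(
    case: ExpressionMatrix,
    controls: list[ExpressionMatrix],
    gene_subset: list[str],
    case_id: str = "case",
) -> LabeledDataset:
    """Label a case cohort 1 and control cohorts 0 and integrate them."""
    if not controls:
        raise ValueError("at least one control cohort is required")
    datasets = [(case_id, case, np.ones(case.n_samples, dtype=int))]
    for k, ctl in enumerate(controls):
        datasets.append((f"control{k}", ctl, np.zeros(ctl.n_samples, dtype=int)))
    return integrate_labeled(datasets, gene_subset)
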
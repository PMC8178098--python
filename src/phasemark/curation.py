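"""Quality control: zero imputation, outlier samples, high-covariance genes.

Outlier samples are scored by two multivariate detectors (isolation forest
and local outlier factor) and flagged only when *both* rank them inside the
contamination budget — a conservative consensus, since either detector
alone is noisy at cohort sizes of a few dozen samples.  Genes with
exceptionally high covariance to another gene (near-duplicate probes,
saturated channels) are removed by a quantile rule on the per-gene maximum
absolute off-diagonal covariance.  Detection runs before imputation is
finalized; detectors see missing cells as zeros for scoring only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor

from .datatypes import ExpressionMatrix


@dataclass
class CurationReport:
    flagged_samples: dict[str, dict[str, float]] = field(default_factory=dict)
    removed_genes: dict[str, float] = field(default_factory=dict)
    n_imputed: int = 0


def impute_missing_zero(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Replace missing entries with zero and clear the mask.

    Returns the imputed matrix and the number of cells filled.  Non-missing
    cells are untouched.
    """
    out = matrix.copy()
    n = int(out.missing_mask.sum())
    out.values[out.missing_mask] = 0.0
    out.missing_mask[:] = False
    return out, n


def detect_outlier_samples(
    matrix: ExpressionMatrix, contamination: float = 0.05, seed: int = 0
) -> CurationReport:
    """Score samples with isolation forest and LOF; flag the consensus.

    A sample is flagged only when both detectors rank it within the top
    ``contamination`` fraction of outlier scores.  Scores are computed on a
    canonical sample-id ordering so the result is permutation-equivariant,
    and a detector whose scores are all tied (e.g. identical samples)
    contributes no flags.
    """
    if not 0.0 <= contamination <= 0.5:
        raise ValueError("contamination must lie in [0, 0.5]")
    n = matrix.n_samples
    if n < 5:
        raise ValueError("outlier detection needs at least 5 samples")
    report = CurationReport()
    budget = int(np.floor(contamination * n))
    if budget == 0:
        return report

    order = np.argsort(np.asarray(matrix.sample_ids))
    X = matrix.values[order].copy()
    X[matrix.missing_mask[order]] = 0.0  # scoring only; imputation is separate

    iso = IsolationForest(random_state=seed, contamination="auto")
    iso_score = -iso.fit(X).score_samples(X)  # higher = more anomalous
    lof = LocalOutlierFactor(n_neighbors=min(20, n - 1))
    lof.fit(X)
    lof_score = -lof.negative_outlier_factor_

    def top_k(score: np.ndarray) -> set[int]:
        if np.ptp(score) == 0:  # all tied: no outlier definable
            return set()
        ranked = np.argsort(-score, kind="stable")
        return set(ranked[:budget].tolist())

    consensus = top_k(iso_score) & top_k(lof_score)
    ids = np.asarray(matrix.sample_ids)[order]
    for i in sorted(consensus, key=lambda i: ids[i]):
        report.flagged_samples[str(ids[i])] = {
            "isolation_forest": float(iso_score[i]),
            "local_outlier_factor": float(lof_score[i]),
        }
    return report


def filter_high_covariance_genes(
    matrix: ExpressionMatrix, covariance_quantile: float = 0.999
) -> tuple[ExpressionMatrix, CurationReport]:
    """Drop genes whose max |off-diagonal covariance| exceeds a quantile.

    For each gene the statistic is the maximum absolute covariance with any
    other gene; genes at or above the ``covariance_quantile`` of all
    statistics are removed.  For a tied mutual pair (e.g. duplicated
    probes) only the later column is removed.  A single-gene matrix has no
    off-diagonal entries and is returned unchanged.
    """
    if not 0.0 < covariance_quantile <= 1.0:
        raise ValueError("covariance_quantile must lie in (0, 1]")
    if matrix.n_probes < 2:
        return matrix.copy(), CurationReport()
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples")
    X = matrix.values.copy()
    X[matrix.missing_mask] = 0.0
    cov = np.cov(X, rowvar=False)
    acov = np.abs(cov)
    np.fill_diagonal(acov, -np.inf)
    stats = acov.max(axis=0)
    threshold = float(np.quantile(stats, covariance_quantile))
    flagged = np.flatnonzero(stats >= threshold)
    removed: list[int] = []
    flagged_set = set(flagged.tolist())
    for j in flagged:
        partner = int(np.argmax(acov[:, j]))
        tied_pair = (
            partner in flagged_set
            and np.isclose(stats[partner], stats[j])
            and np.isclose(acov[partner, j], stats[j])
        )
        if tied_pair and partner < j:
            removed.append(int(j))  # keep the earlier column of the pair
        elif not tied_pair:
            removed.append(int(j))
    report = CurationReport(
        removed_genes={matrix.probe_ids[j]: float(stats[j]) for j in removed}
    )
    keep = [p for j, p in enumerate(matrix.probe_ids) if j not in set(removed)]
    return matrix.subset_probes(keep), report


def curate(
    matrix: ExpressionMatrix,
    contamination: float = 0.05,
    covariance_quantile: float = 0.999,
    seed: int = 0,
    remove_outliers: bool = False,
) -> tuple[ExpressionMatrix, CurationReport]:
    """Full curation pass: detect, filter, then impute.

    Outliers are reported (and optionally removed); the covariance filter
    and detection both run before the final zero-imputation so imputed
    values never drive removal decisions.
    """
    report = detect_outlier_samples(matrix, contamination=contamination, seed=seed)
    if remove_outliers and report.flagged_samples:
        keep = [s for s in matrix.sample_ids if s not in report.flagged_samples]
        matrix = matrix.subset_samples(keep)
    matrix, cov_report = filter_high_covariance_genes(matrix, covariance_quantile)
    report.removed_genes = cov_report.removed_genes
    matrix, n_imp = impute_missing_zero(matrix)
    report.n_imputed = n_imp
    return matrix, report
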
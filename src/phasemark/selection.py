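"""Per-phase ANOVA F feature selection with Benjamini-Hochberg FDR.

Within each phase, every probe is scored by the one-way ANOVA F statistic
against the super-cluster labels:

    F = MST / MSE,
    MST = sum_i n_i (zbar_i - zbar)^2 / (N - 1),
    MSE = sum_i (n_i - 1) s_i^2 / (n - N),

with N groups and n samples; p comes from the upper tail of F(N-1, n-N).
The p-values of one phase (all probes of that phase form the family) are
adjusted by the BH step-up procedure at alpha = 0.01, and the proposed
probe set is the intersection of the three per-phase significant sets.

Degenerate probes: MSE = 0 with MST > 0 gives F = inf and p = 0; a probe
constant within and between groups (MST = MSE = 0) has no defined F and is
excluded from the family and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


def anova_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p for a list of sample groups.

    Requires >= 2 groups, more samples than groups, and at least one group
    with >= 2 members (otherwise MSE has no degrees of freedom).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    N = len(groups)
    if N < 2:
        raise ValueError("need at least two groups")
    n = sum(g.size for g in groups)
    if n <= N:
        raise ValueError("total sample count must exceed the group count")
    grand = np.concatenate(groups).mean()
    mst = sum(g.size * (g.mean() - grand) ** 2 for g in groups) / (N - 1)
    mse = sum((g.size - 1) * g.var(ddof=1) if g.size > 1 else 0.0 for g in groups) / (
        n - N
    )
    if mse == 0.0:
        if mst == 0.0:
            return float("nan"), float("nan")
        return float("inf"), 0.0
    F = mst / mse
    return float(F), float(stats.f.sf(F, N - 1, n - N))


def anova_f_matrix(
    X: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across columns of ``X`` against ``labels``.

    Returns (F, p) arrays, one entry per column; degenerate columns get
    F = inf, p = 0 (MSE = 0, MST > 0) or F = p = NaN (all-constant).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    codes, _ = pd.factorize(labels)
    N = codes.max() + 1
    n = X.shape[0]
    if N < 2:
        raise ValueError("need at least two groups")
    if n <= N:
        raise ValueError("total sample count must exceed the group count")
    counts = np.bincount(codes).astype(float)  # n_i
    Xc = X - X.mean(axis=0)  # centering improves the sum-of-squares conditioning
    sums = np.zeros((N, X.shape[1]))
    np.add.at(sums, codes, Xc)
    means = sums / counts[:, None]
    mst = (counts[:, None] * means**2).sum(axis=0) / (N - 1)
    total_ss = (Xc**2).sum(axis=0)
    within_ss = np.maximum(total_ss - mst * (N - 1), 0.0)
    mse = within_ss / (n - N)
    # tolerance for "exactly zero" sums of squares under floating rounding
    scale = np.maximum((X**2).mean(axis=0), 1.0)
    mse_zero = mse <= 1e-12 * scale
    mst_zero = mst <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mse_zero, np.inf, mst / np.where(mse_zero, 1.0, mse))
        F = np.where(mse_zero & mst_zero, np.nan, F)
        p = np.where(
            np.isfinite(F),
            stats.f.sf(np.where(np.isfinite(F), F, 1.0), N - 1, n - N),
            0.0,
        )
        p = np.where(np.isnan(F), np.nan, p)
    return F, p


def benjamini_hochberg(
    p_values: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up: reject the k smallest p with p_(k) <= k*alpha/m.

    Returns (adjusted q-values capped at 1, rejection mask).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class PhaseSelection:
    """Per-phase ANOVA/BH table and the significant probe set."""

    phase: str
    table: pd.DataFrame  # columns: probe, F, p, q, significant
    significant: list[str]
    excluded: list[str] = field(default_factory=list)  # undefined-F probes


def select_per_phase(
    matrix: ExpressionMatrix,
    super_labels: np.ndarray,
    alpha: float = 0.01,
    phase: str = "",
) -> PhaseSelection:
    """Score every probe of one phase and apply BH across the phase family.

    The BH family is all probes of the phase with a defined F statistic;
    constant probes are excluded and logged.
    """
    super_labels = np.asarray(super_labels)
    if super_labels.shape[0] != matrix.n_samples:
        raise ValueError("labels must cover all samples")
    if np.unique(super_labels).size < 2:
        raise ValueError("need at least two super-clusters")
    X = matrix.values.copy()
    X[matrix.missing_mask] = 0.0
    F, p = anova_f_matrix(X, super_labels)
    defined = ~np.isnan(F)
    q = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if defined.any():
        q[defined], sig[defined] = benjamini_hochberg(p[defined], alpha)
    table = pd.DataFrame(
        {
            "probe": matrix.probe_ids,
            "F": F,
            "p": p,
            "q": q,
            "significant": sig,
        }
    )
    probes = np.asarray(matrix.probe_ids, dtype=object)
    return PhaseSelection(
        phase=phase,
        table=table,
        significant=list(probes[sig]),
        excluded=list(probes[~defined]),
    )


@dataclass
class SelectionResult:
    per_phase: dict[str, PhaseSelection]
    final_set: list[str]
    alpha: float


def intersect_phases(selections: list[PhaseSelection], alpha: float = 0.01) -> SelectionResult:
    """Intersect the three per-phase significant sets (sorted by probe id).

    An empty intersection is legal; downstream consumers decide how to
    proceed.
    """
    if len(selections) != 3:
        raise ValueError("exactly three phase selections required")
    sets = [set(s.significant) for s in selections]
    final = sorted(sets[0] & sets[1] & sets[2])
    return SelectionResult(
        per_phase={s.phase: s for s in selections}, final_set=final, alpha=alpha
    )
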
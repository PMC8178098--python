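"""Core containers for phased expression cohorts.

An :class:`ExpressionMatrix` is a samples x probes real matrix with an
explicit missing-value mask; a :class:`PhaseTensor` stacks one matrix per
clinical phase (Acute, Subacute, Convalescent) over a shared sample and
probe universe.  Missing entries are carried explicitly and only replaced
by the curation step, so imputation remains auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical phase order: Acute, Subacute, Convalescent.
PHASES = ("A", "SA", "C")


def _check_unique(ids: list[str], what: str) -> None:
    dupes = [k for k, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """Samples x probes expression matrix with a missing-value mask.

    Values are dimensionless expression units as deposited (log2 ratios or
    normalized intensities).  ``missing_mask`` is True wherever the value is
    undefined; the stored value at masked positions is NaN until imputed.
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if p != len(self.probe_ids):
            raise ValueError(
                f"column count {p} != number of probe ids {len(self.probe_ids)}"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.probe_ids, "probe ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.sample_ids),
            list(self.probe_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples-in-rows DataFrame; missing entries become NaN."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.probe_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        vals = frame.to_numpy(dtype=float)
        return cls(list(frame.index), list(frame.columns), vals, np.isnan(vals))

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionMatrix(
            keep, list(self.probe_ids), self.values[idx], self.missing_mask[idx]
        )

    def subset_probes(self, keep: list[str]) -> "ExpressionMatrix":
        pos = {p: j for j, p in enumerate(self.probe_ids)}
        idx = [pos[p] for p in keep]
        return ExpressionMatrix(
            list(self.sample_ids), keep, self.values[:, idx], self.missing_mask[:, idx]
        )


@dataclass
class PhaseTensor:
    """Case cohort stacked over the three phases (fixed order A, SA, C).

    All three matrices share identical sample and probe ids in identical
    order, so the tensor is patients x probes x phases.
    """

    matrices: tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]
    phases: tuple[str, str, str] = PHASES

    def __post_init__(self) -> None:
        if tuple(self.phases) != PHASES:
            raise ValueError(f"phases must be {PHASES} in order")
        if len(self.matrices) != 3:
            raise ValueError("exactly three phase matrices required")
        ref = self.matrices[0]
        for m in self.matrices[1:]:
            if m.sample_ids != ref.sample_ids:
                raise ValueError("phase matrices must share sample ids in order")
            if m.probe_ids != ref.probe_ids:
                raise ValueError("phase matrices must share probe ids in order")

    @property
    def sample_ids(self) -> list[str]:
        return self.matrices[0].sample_ids

    @property
    def probe_ids(self) -> list[str]:
        return self.matrices[0].probe_ids

    @property
    def shape(self) -> tuple[int, int, int]:
        n, p = self.matrices[0].shape
        return (n, p, 3)

    def phase(self, label: str) -> ExpressionMatrix:
        return self.matrices[PHASES.index(label)]

    def stack(self) -> np.ndarray:
        """patients x probes x phases array (missing as NaN)."""
        out = np.stack([m.values for m in self.matrices], axis=2).astype(float)
        mask = np.stack([m.missing_mask for m in self.matrices], axis=2)
        out = out.copy()
        out[mask] = np.nan
        return out


@dataclass
class ProbeAnnotation:
    """Many-to-one map from probe id to gene id; unmapped probes permitted."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def gene_for(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def unmapped(self, probe_ids: list[str]) -> list[str]:
        return [p for p in probe_ids if p not in self.mapping]

    def __len__(self) -> int:
        return len(self.mapping)
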
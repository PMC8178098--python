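"""Synthetic phased cohorts with known ground truth.

The generator emulates the statistical structure the workflow assumes: a
small case cohort measured at three disease phases, partitioned into
latent patient subgroups; a handful of *phase-consistent* marker probes
whose group-specific mean offsets repeat in every phase (the signal the
cross-phase intersection is designed to keep); a larger complement of
*phase-specific* probes whose offsets act in a single phase (they give
each per-phase map real structure to cluster, but must not survive the
intersection); background probes of pure Gaussian noise; and, for the
cross-platform suite, per-dataset affine location/scale distortions and
multi-probe genes.

Offsets are drawn as balanced sign patterns: each informative probe gives
every subgroup an offset of +/- effect_size * noise_sd (never the same
sign for all groups), which is exactly the one-way ANOVA alternative the
selection statistic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import PHASES, ExpressionMatrix, PhaseTensor, ProbeAnnotation
from .clustering import derive_seed

#: Study-scale default subgroup sizes for a 20-patient cohort.
DEFAULT_GROUP_SIZES = (6, 5, 2, 7)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    super_cluster_assignment: dict[str, int]  # patient -> 1-based group
    marker_probes: list[str]
    marker_offsets: dict[str, np.ndarray]  # probe -> per-group offsets
    phase_specific_probes: dict[str, str]  # probe -> active phase
    platform_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    outlier_samples: list[str] = field(default_factory=list)
    seed: int = 0


def _group_sizes(n_patients: int, n_groups: int) -> tuple[int, ...]:
    if n_patients == 20 and n_groups == 4:
        return DEFAULT_GROUP_SIZES
    base = n_patients // n_groups
    sizes = [base] * n_groups
    for i in range(n_patients - base * n_groups):
        sizes[i] += 1
    return tuple(sizes)


def _sign_pattern(rng: np.random.Generator, n_groups: int) -> np.ndarray:
    """Random +/-1 per group, redrawn until both signs appear."""
    while True:
        s = rng.choice([-1.0, 1.0], size=n_groups)
        if len(set(s.tolist())) > 1:
            return s


def generate_case_cohort(
    n_patients: int = 20,
    n_probes: int = 2000,
    n_groups: int = 4,
    n_markers: int = 5,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    n_phase_specific: int | None = None,
    group_sizes: tuple[int, ...] | None = None,
    n_outliers: int = 0,
    outlier_shift: float = 10.0,
    seed: int = 0,
) -> tuple[PhaseTensor, SyntheticTruth]:
    """Three-phase case cohort with planted subgroups and markers.

    Background probes are Normal(0, noise_sd^2) in every phase.  The
    ``n_markers`` marker probes carry group offsets of magnitude
    effect_size * noise_sd identically in all three phases; the
    ``n_phase_specific`` probes (default 45% of the panel, split
    round-robin over A/SA/C) carry the same kind of offsets in their
    single active phase only.  Missing
    entries are planted uniformly at ``missing_rate``; optional outlier
    patients are shifted by ``outlier_shift * noise_sd`` everywhere.
    """
    if n_phase_specific is None:
        # subgroup signatures span broad co-expression programs: 45% of the
        # panel split over the three phases (900 probes at the 2,000 default)
        n_phase_specific = int(round(0.45 * n_probes))
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n_markers + n_phase_specific >= n_probes:
        raise ValueError("markers + phase-specific probes must be < n_probes")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    sizes = tuple(group_sizes) if group_sizes else _group_sizes(n_patients, n_groups)
    if sum(sizes) != n_patients or len(sizes) != n_groups:
        raise ValueError("group sizes must sum to n_patients")
    rng = np.random.default_rng(derive_seed(seed, 101))

    patients = [f"KD{i + 1:03d}" for i in range(n_patients)]
    probes = [f"P{j + 1:05d}" for j in range(n_probes)]
    groups = np.repeat(np.arange(n_groups), sizes)  # 0-based group per patient

    special = rng.choice(n_probes, size=n_markers + n_phase_specific, replace=False)
    marker_idx = special[:n_markers]
    spec_idx = special[n_markers:]
    spec_phase = {int(j): PHASES[k % 3] for k, j in enumerate(spec_idx)}

    marker_offsets = {
        int(j): _sign_pattern(rng, n_groups) * effect_size * noise_sd
        for j in marker_idx
    }
    spec_offsets = {
        int(j): _sign_pattern(rng, n_groups) * effect_size * noise_sd
        for j in spec_idx
    }

    mats = []
    for phase in PHASES:
        vals = rng.normal(0.0, noise_sd, size=(n_patients, n_probes))
        for j, off in marker_offsets.items():
            vals[:, j] += off[groups]
        for j, off in spec_offsets.items():
            if spec_phase[j] == phase:
                vals[:, j] += off[groups]
        mats.append(vals)

    outliers: list[str] = []
    if n_outliers:
        out_idx = rng.choice(n_patients, size=n_outliers, replace=False)
        outliers = [patients[i] for i in sorted(out_idx)]
        for vals in mats:
            vals[out_idx] += outlier_shift * noise_sd

    tensors = []
    for vals in mats:
        mask = (
            rng.random(vals.shape) < missing_rate
            if missing_rate > 0
            else np.zeros(vals.shape, dtype=bool)
        )
        v = vals.copy()
        v[mask] = np.nan
        tensors.append(ExpressionMatrix(patients, probes, v, mask))

    truth = SyntheticTruth(
        super_cluster_assignment={p: int(g) + 1 for p, g in zip(patients, groups)},
        marker_probes=[probes[j] for j in sorted(marker_offsets)],
        marker_offsets={probes[j]: off for j, off in marker_offsets.items()},
        phase_specific_probes={probes[j]: ph for j, ph in spec_phase.items()},
        outlier_samples=outliers,
        seed=seed,
    )
    return PhaseTensor(tuple(tensors)), truth  # type: ignore[arg-type]


def generate_control_cohort(
    n_controls: int = 67,
    n_probes: int = 2000,
    shift: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Control cohort: background noise only, optional global location shift."""
    rng = np.random.default_rng(derive_seed(seed, 202))
    vals = rng.normal(shift, noise_sd, size=(n_controls, n_probes))
    ids = [f"CTL{i + 1:03d}" for i in range(n_controls)]
    probes = [f"P{j + 1:05d}" for j in range(n_probes)]
    return ExpressionMatrix(ids, probes, vals, np.zeros(vals.shape, dtype=bool))


@dataclass
class SyntheticDataset:
    """One cross-platform dataset: probe-level matrix, labels, annotation."""

    dataset_id: str
    platform: str
    matrix: ExpressionMatrix
    labels: np.ndarray  # 1 = case, 0 = control
    annotation: ProbeAnnotation


#: Study-scale cross-platform defaults: six datasets on two platforms,
#: 1,347 samples of which 558 are cases.
DEFAULT_XPLAT_SIZES = (206, 129, 459, 171, 149, 233)
DEFAULT_XPLAT_CASES = (0, 0, 78, 171, 76, 233)


def generate_cross_platform_suite(
    n_datasets: int = 6,
    per_dataset_sizes: tuple[int, ...] = DEFAULT_XPLAT_SIZES,
    per_dataset_cases: tuple[int, ...] = DEFAULT_XPLAT_CASES,
    n_genes: int = 300,
    n_markers: int = 5,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    multiprobe_rate: float = 0.3,
    probe_noise_sd: float = 0.3,
    platform_effects: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[list[SyntheticDataset], SyntheticTruth]:
    """Multi-dataset suite with per-dataset affine distortions.

    Each dataset lives on one of two platforms; a platform represents a
    fraction of genes by 2-3 probes sharing the gene signal plus probe
    noise.  Case samples carry marker-gene shifts of magnitude
    effect_size * noise_sd; each dataset additionally applies its own
    location/scale distortion (mimicking heterogeneous deposit scales).
    """
    if len(per_dataset_sizes) < n_datasets or len(per_dataset_cases) < n_datasets:
        raise ValueError("need sizes and case counts for every dataset")
    if any(s <= 0 for s in per_dataset_sizes[:n_datasets]):
        raise ValueError("dataset sizes must be positive")
    rng = np.random.default_rng(derive_seed(seed, 303))
    genes = [f"G{j + 1:04d}" for j in range(n_genes)]
    marker_gene_idx = rng.choice(n_genes, size=n_markers, replace=False)
    marker_shift = {
        int(j): float(rng.choice([-1.0, 1.0])) * effect_size * noise_sd
        for j in marker_gene_idx
    }

    platforms = {}
    for plat in ("GPLX", "GPLY"):
        n_probes_per_gene = np.where(
            rng.random(n_genes) < multiprobe_rate, rng.integers(2, 4, n_genes), 1
        )
        mapping: dict[str, str] = {}
        probe_gene_idx: list[int] = []
        for j, g in enumerate(genes):
            for r in range(int(n_probes_per_gene[j])):
                pid = f"{plat}_{g}_{r + 1}"
                mapping[pid] = g
                probe_gene_idx.append(j)
        platforms[plat] = (ProbeAnnotation(mapping), np.asarray(probe_gene_idx))

    datasets: list[SyntheticDataset] = []
    effects: dict[str, tuple[float, float]] = {}
    for d in range(n_datasets):
        ds_id = f"DS{d + 1}"
        plat = "GPLX" if d < n_datasets // 3 else "GPLY"
        annotation, gene_idx = platforms[plat]
        n = per_dataset_sizes[d]
        n_case = per_dataset_cases[d]
        labels = np.concatenate([np.ones(n_case, int), np.zeros(n - n_case, int)])
        gene_vals = rng.normal(0.0, noise_sd, size=(n, n_genes))
        for j, shift in marker_shift.items():
            gene_vals[labels == 1, j] += shift
        probe_vals = gene_vals[:, gene_idx] + rng.normal(
            0.0, probe_noise_sd, size=(n, gene_idx.size)
        )
        if platform_effects and ds_id in platform_effects:
            loc, scale = platform_effects[ds_id]
        else:
            loc = float(rng.uniform(-2.0, 4.0))
            scale = float(rng.uniform(0.5, 3.0))
        effects[ds_id] = (loc, scale)
        probe_vals = loc + scale * probe_vals
        ids = [f"{ds_id}S{i + 1:04d}" for i in range(n)]
        matrix = ExpressionMatrix(
            ids,
            list(annotation.mapping),
            probe_vals,
            np.zeros(probe_vals.shape, dtype=bool),
        )
        datasets.append(SyntheticDataset(ds_id, plat, matrix, labels, annotation))

    truth = SyntheticTruth(
        super_cluster_assignment={},
        marker_probes=[genes[j] for j in sorted(marker_shift)],
        marker_offsets={genes[j]: np.array([s]) for j, s in marker_shift.items()},
        phase_specific_probes={},
        platform_effects=effects,
        seed=seed,
    )
    return datasets, truth
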
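"""Two-stage patient clustering and super-cluster formation.

Stage one trains one SOM per clinical phase on that phase's samples x
probes matrix, giving each patient a cluster label per phase.  The label
rows (one patient = one 3-vector of per-phase labels) are the input to a
second-stage SOM that groups patients with similar per-phase cluster
membership.  Empty second-stage nodes are pruned, and the surviving
prototypes are merged into super-clusters by hierarchical clustering on
the Euclidean distances between their weight vectors, with a dendrogram
cut at ``cut_k`` groups (default 4).

Cluster labels are 1-based (1..9 on a 3x3 grid) to match the usual map
numbering; super-clusters are renumbered 1..cut_k by first patient
occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .datatypes import PHASES, PhaseTensor
from .som import SOMModel, SOMTrainParams, assign_clusters, train_som


def derive_seed(master_seed: int, offset: int) -> int:
    """Deterministic child seed: SeedSequence((master, offset)), < 2**31."""
    return int(np.random.SeedSequence((master_seed, offset)).generate_state(1)[0] % (2**31))


@dataclass
class PhaseLabelMatrix:
    """Per-patient cluster labels per phase plus derived stage-two labels."""

    patient_ids: list[str]
    labels: np.ndarray  # (n_patients, 3) int, 1-based, columns A/SA/C
    second_stage_labels: np.ndarray | None = None  # (n_patients,) 1-based
    super_labels: np.ndarray | None = None  # (n_patients,) 1..cut_k

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.patient_ids), 3):
            raise ValueError("labels must be n_patients x 3")

    def validate_refinement(self) -> None:
        """Each second-stage cluster must map to exactly one super-cluster."""
        if self.second_stage_labels is None or self.super_labels is None:
            return
        for node in np.unique(self.second_stage_labels):
            members = self.super_labels[self.second_stage_labels == node]
            if np.unique(members).size > 1:
                raise ValueError(f"second-stage cluster {node} split across super-clusters")


@dataclass
class SuperClusterTree:
    prototype_ids: list[int]  # surviving second-stage node labels (1-based)
    distance_matrix: np.ndarray
    linkage: np.ndarray
    cut_k: int
    member_counts: dict[int, int] = field(default_factory=dict)


def per_phase_clustering(
    tensor: PhaseTensor,
    params: SOMTrainParams,
    master_seed: int | None = None,
    phase_seed_offsets: tuple[int, int, int] = (0, 1, 2),
) -> tuple[PhaseLabelMatrix, list[SOMModel]]:
    """Train one SOM per phase and label every patient in every phase.

    Per-phase seeds are derived from the master seed (params.seed when not
    given) by a fixed documented derivation, so runs are reproducible and
    phases are trained independently; pass equal ``phase_seed_offsets`` to
    share one seed across phases.  Training consumes the samples in
    canonical sample-id order, so permuting the patients permutes the
    labels identically.
    """
    master = params.seed if master_seed is None else master_seed
    order = np.argsort(np.asarray(tensor.sample_ids))
    labels = np.zeros((len(tensor.sample_ids), 3), dtype=int)
    models: list[SOMModel] = []
    for k, phase in enumerate(PHASES):
        mat = tensor.phase(phase)
        if mat.missing_mask.any():
            raise ValueError(f"phase {phase} contains missing values; curate first")
        p = SOMTrainParams(
            **{**params.__dict__, "seed": derive_seed(master, phase_seed_offsets[k])}
        )
        model = train_som(mat.values[order], p)
        labels[:, k] = assign_clusters(model, mat.values) + 1
        models.append(model)
    return PhaseLabelMatrix(list(tensor.sample_ids), labels), models


def second_stage_som(
    label_matrix: PhaseLabelMatrix,
    params: SOMTrainParams,
    master_seed: int | None = None,
    encoding: str = "grid",
    stage1_shape: tuple[int, int] = (3, 3),
) -> tuple[SOMModel, np.ndarray]:
    """Cluster the patients on their per-phase label rows.

    ``encoding`` controls how categorical node labels become coordinates —
    the single most consequential choice in the workflow.  ``"grid"``
    (default) maps each label to its (row, col) position on the stage-one
    grid, preserving map topology: a patient blob tiled by grid-adjacent
    nodes stays a compact cloud.  ``"raw"`` feeds the integer labels
    directly (the label matrix itself), whose arithmetic distances are
    partly arbitrary; ``"onehot"`` makes all distinct labels equidistant.
    Returns the trained model and 1-based node labels.
    """
    if encoding == "raw":
        data = label_matrix.labels.astype(float)
    elif encoding == "grid":
        # each phase label -> (row, col) of its node on the stage-one grid;
        # grid-adjacent nodes (which tile one patient blob) stay adjacent
        _, cols1 = stage1_shape
        data = np.column_stack(
            [
                np.column_stack(
                    [
                        (label_matrix.labels[:, c] - 1) // cols1,
                        (label_matrix.labels[:, c] - 1) % cols1,
                    ]
                )
                for c in range(3)
            ]
        ).astype(float)
    elif encoding == "onehot":
        n_nodes = int(label_matrix.labels.max())
        n = len(label_matrix.patient_ids)
        data = np.zeros((n, 3 * n_nodes))
        for c in range(3):
            data[np.arange(n), c * n_nodes + label_matrix.labels[:, c] - 1] = 1.0
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    master = params.seed if master_seed is None else master_seed
    p = SOMTrainParams(**{**params.__dict__, "seed": derive_seed(master, 3)})
    order = np.argsort(np.asarray(label_matrix.patient_ids))
    model = train_som(data[order], p)
    labels = assign_clusters(model, data) + 1
    label_matrix.second_stage_labels = labels
    return model, labels


def prune_empty_clusters(
    model: SOMModel, labels: np.ndarray
) -> tuple[list[int], dict[int, int]]:
    """Drop prototypes with zero members; report member counts.

    Returns the surviving 1-based node labels and their member counts.
    Every sample has a BMU, so at least one node always survives.
    """
    labels = np.asarray(labels, dtype=int)
    counts = {int(v): int(c) for v, c in zip(*np.unique(labels, return_counts=True))}
    survivors = sorted(counts)
    assert survivors, "every sample has a BMU; no survivors is impossible"
    return survivors, counts


def super_cluster(
    model: SOMModel,
    labels: np.ndarray,
    cut_k: int = 4,
    linkage_method: str = "average",
) -> tuple[SuperClusterTree, np.ndarray]:
    """Merge surviving prototypes into ``cut_k`` super-clusters.

    Agglomerative clustering (default average linkage) runs on the
    Euclidean distances between the surviving prototype weight vectors;
    the dendrogram is cut into ``cut_k`` groups and every patient inherits
    its prototype's group.  Super-clusters are renumbered 1..cut_k by
    first patient occurrence.
    """
    survivors, counts = prune_empty_clusters(model, labels)
    if cut_k > len(survivors):
        raise ValueError(
            f"cut_k={cut_k} exceeds the {len(survivors)} surviving prototypes"
        )
    weights = model.weights[[s - 1 for s in survivors]]
    if len(survivors) == 1:
        proto_groups = {survivors[0]: 1}
        Z = np.empty((0, 4))
        dmat = np.zeros((1, 1))
    else:
        dvec = pdist(weights, metric="euclidean")
        dmat = squareform(dvec)
        Z = linkage(dvec, method=linkage_method)
        flat = fcluster(Z, t=cut_k, criterion="maxclust")
        proto_groups = {node: int(g) for node, g in zip(survivors, flat)}
    raw = np.array([proto_groups[int(l)] for l in labels], dtype=int)
    renumber: dict[int, int] = {}
    for g in raw:
        if int(g) not in renumber:
            renumber[int(g)] = len(renumber) + 1
    super_labels = np.array([renumber[int(g)] for g in raw], dtype=int)
    tree = SuperClusterTree(survivors, dmat, Z, cut_k, counts)
    return tree, super_labels


def two_stage_cluster(
    tensor: PhaseTensor,
    stage1_params: SOMTrainParams,
    stage2_params: SOMTrainParams | None = None,
    cut_k: int = 4,
    linkage_method: str = "average",
    encoding: str = "grid",
    master_seed: int | None = None,
) -> tuple[PhaseLabelMatrix, list[SOMModel], SOMModel, SuperClusterTree]:
    """Full two-stage workflow: per-phase SOMs -> label SOM -> super-clusters."""
    master = stage1_params.seed if master_seed is None else master_seed
    label_matrix, phase_models = per_phase_clustering(tensor, stage1_params, master)
    stage2 = stage2_params or stage1_params
    model2, labels2 = second_stage_som(
        label_matrix, stage2, master, encoding, (stage1_params.rows, stage1_params.cols)
    )
    tree, supers = super_cluster(model2, labels2, cut_k, linkage_method)
    label_matrix.super_labels = supers
    label_matrix.validate_refinement()
    return label_matrix, phase_models, model2, tree
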
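"""End-to-end workflow orchestration.

``run_workflow`` executes the common-platform path: curation, per-phase
SOM clustering, second-stage SOM, super-cluster formation, per-phase
FDR-controlled ANOVA selection, cross-phase intersection, and a boosting
comparison of the selected probe set against a reference probe set on the
integrated case/control cohort.  ``run_cross_platform`` executes the
multi-dataset path: per-dataset probe collapse and quantile
normalization, integration with binary labels, and the same comparison.

Every stage's output is persisted under the run directory and recorded in
a JSON manifest with SHA-256 checksums, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boosting import AdaBoostStumps, GradBoostParams, GradientBoostedTrees
from .clustering import SOMTrainParams, derive_seed, two_stage_cluster
from .curation import curate
from .datatypes import PHASES, ExpressionMatrix, PhaseTensor
from .evaluation import compare_gene_sets
from .io import (
    assemble_phase_tensor,
    read_expression_matrix,
    read_gene_list,
    write_expression_matrix,
)
from .normalize import (
    average_quantile_reference,
    collapse_probes_to_genes,
    integrate_labeled,
    quantile_normalize,
)
from .selection import intersect_phases, select_per_phase
from .synthetic import (
    generate_case_cohort,
    generate_control_cohort,
    generate_cross_platform_suite,
)

log = logging.getLogger("phasemark")


@dataclass
class WorkflowConfig:
    """Declarative configuration; defaults mirror the study constants."""

    # inputs: either file paths per phase + controls, or a synthetic spec
    phase_paths: dict[str, str] | None = None
    control_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    known_genes_path: str | None = None
    synthetic: dict | None = None  # kwargs for generate_case_cohort
    synthetic_controls: dict | None = None  # kwargs for generate_control_cohort
    # stages
    som: dict = field(default_factory=dict)  # SOMTrainParams overrides, both stages
    cut_k: int = 4
    linkage_method: str = "average"
    encoding: str = "grid"
    alpha: float = 0.01
    contamination: float = 0.05
    covariance_quantile: float = 0.999
    remove_outliers: bool = False
    exclude_samples: list[str] = field(default_factory=list)
    normalize_comparison: bool = True
    # evaluation
    cv_folds: int = 10
    cv_repeats: int = 10
    adaboost_rounds: int = 100
    gbt: dict = field(default_factory=dict)  # GradBoostParams overrides
    n_reference_probes: int = 8
    seed: int = 0
    out_dir: str = "phasemark_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path, config: WorkflowConfig):
        self.run_dir = run_dir
        cfg = json.dumps(asdict(config), sort_keys=True, default=str)
        self.data = {
            "package_version": __version__,
            "config": json.loads(cfg),
            "config_hash": hashlib.sha256(cfg.encode()).hexdigest(),
            "outputs": {},
            "stages": [],
        }

    def add(self, name: str) -> None:
        path = self.run_dir / name
        self.data["outputs"][name] = _sha256(path)

    def stage(self, name: str, seconds: float) -> None:
        self.data["stages"].append({"stage": name, "seconds": round(seconds, 3)})

    def write(self) -> None:
        (self.run_dir / "manifest.json").write_text(json.dumps(self.data, indent=1))


def _model_factories(config: WorkflowConfig) -> dict:
    gbt_params = GradBoostParams(**config.gbt)
    return {
        "adaboost": lambda: AdaBoostStumps(n_rounds=config.adaboost_rounds),
        "gbt": lambda: GradientBoostedTrees(params=gbt_params),
    }


def _load_inputs(
    config: WorkflowConfig,
) -> tuple[PhaseTensor, list[ExpressionMatrix], list[str] | None]:
    """Returns (tensor, controls, truth marker probes when synthetic)."""
    if config.synthetic is not None:
        spec = dict(config.synthetic)
        spec.setdefault("seed", config.seed)
        tensor, truth = generate_case_cohort(**spec)
        ctl_spec = dict(config.synthetic_controls or {})
        ctl_spec.setdefault("n_probes", tensor.shape[1])
        ctl_spec.setdefault("seed", config.seed)
        controls = [generate_control_cohort(**ctl_spec)]
        return tensor, controls, truth.marker_probes
    if not config.phase_paths:
        raise ValueError("config needs either phase_paths or a synthetic spec")
    per_phase = {
        ph: read_expression_matrix(path) for ph, path in config.phase_paths.items()
    }
    tensor, _ = assemble_phase_tensor(per_phase)
    controls = [read_expression_matrix(p) for p in config.control_paths]
    return tensor, controls, None


def _reference_probes(
    config: WorkflowConfig, tensor: PhaseTensor, exclude: list[str]
) -> list[str]:
    """The comparison reference set: a gene-list file, or (synthetic runs)
    a seeded draw of background probes standing in for the literature set."""
    if config.known_genes_path:
        return read_gene_list(config.known_genes_path)
    rng = np.random.default_rng(derive_seed(config.seed, 404))
    pool = [p for p in tensor.probe_ids if p not in set(exclude)]
    k = min(config.n_reference_probes, len(pool))
    return sorted(rng.choice(np.asarray(pool, dtype=object), size=k, replace=False))


def run_workflow(config: WorkflowConfig) -> tuple[Path, dict]:
    """Execute the full common-platform workflow; returns (run_dir, results)."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, config)
    results: dict = {}
    stage_t0 = time.time()

    def done(stage: str) -> None:
        nonlocal stage_t0
        manifest.stage(stage, time.time() - stage_t0)
        log.info("stage %s done", stage)
        stage_t0 = time.time()

    try:
        tensor, controls, truth_markers = _load_inputs(config)
        if config.exclude_samples:
            keep = [s for s in tensor.sample_ids if s not in set(config.exclude_samples)]
            tensor = PhaseTensor(
                tuple(m.subset_samples(keep) for m in tensor.matrices)  # type: ignore[arg-type]
            )
        done("load")

        curated, reports = [], {}
        for ph in PHASES:
            mat, rep = curate(
                tensor.phase(ph),
                contamination=config.contamination,
                covariance_quantile=config.covariance_quantile,
                seed=derive_seed(config.seed, 10 + PHASES.index(ph)),
                remove_outliers=config.remove_outliers,
            )
            curated.append(mat)
            reports[ph] = {
                "flagged_samples": rep.flagged_samples,
                "removed_genes": rep.removed_genes,
                "n_imputed": rep.n_imputed,
            }
        probe_sets = [set(m.probe_ids) for m in curated]
        common = [p for p in curated[0].probe_ids if all(p in s for s in probe_sets)]
        curated = [m.subset_probes(common) for m in curated]
        tensor = PhaseTensor(tuple(curated))  # type: ignore[arg-type]
        (run_dir / "curation.json").write_text(json.dumps(reports, indent=1))
        manifest.add("curation.json")
        done("curate")

        som_params = SOMTrainParams(**{**config.som, "seed": config.seed})
        label_matrix, phase_models, model2, tree = two_stage_cluster(
            tensor,
            som_params,
            cut_k=config.cut_k,
            linkage_method=config.linkage_method,
            encoding=config.encoding,
            master_seed=config.seed,
        )
        labels_df = pd.DataFrame(
            {
                "patient": label_matrix.patient_ids,
                "label_A": label_matrix.labels[:, 0],
                "label_SA": label_matrix.labels[:, 1],
                "label_C": label_matrix.labels[:, 2],
                "node": label_matrix.second_stage_labels,
                "super": label_matrix.super_labels,
            }
        )
        labels_df.to_csv(run_dir / "labels.tsv", sep="\t", index=False)
        manifest.add("labels.tsv")
        results["label_matrix"] = label_matrix
        results["super_cluster_sizes"] = (
            labels_df.groupby("super").size().to_dict()
        )
        done("cluster")

        selections = []
        for k, ph in enumerate(PHASES):
            sel = select_per_phase(
                tensor.phase(ph), label_matrix.super_labels, config.alpha, phase=ph
            )
            selections.append(sel)
        selection = intersect_phases(selections, config.alpha)
        ftab = selections[0].table[["probe"]].copy()
        for sel in selections:
            ftab[f"F_{sel.phase}"] = sel.table["F"]
            ftab[f"p_{sel.phase}"] = sel.table["p"]
            ftab[f"q_{sel.phase}"] = sel.table["q"]
        ftab.to_csv(run_dir / "anova.tsv", sep="\t", index=False)
        (run_dir / "final_probes.txt").write_text(
            "\n".join(selection.final_set) + "\n"
        )
        manifest.add("anova.tsv")
        manifest.add("final_probes.txt")
        results["selection"] = selection
        results["final_set"] = selection.final_set
        if truth_markers is not None:
            results["truth_markers"] = truth_markers
        done("select")

        if not selection.final_set:
            log.warning("empty cross-phase intersection; skipping comparison")
            results["comparison"] = None
        else:
            reference = _reference_probes(config, tensor, selection.final_set)
            results["reference_set"] = reference
            comparison: dict = {}
            for ph in PHASES:
                case = tensor.phase(ph).subset_probes(
                    [p for p in tensor.probe_ids if p in set(selection.final_set) | set(reference)]
                )
                cohorts = [("case", case, 1)] + [
                    (f"control{i}", c.subset_probes(case.probe_ids), 0)
                    for i, c in enumerate(controls)
                ]
                if config.normalize_comparison:
                    # full-panel normalization onto the shared reference,
                    # then subsetting: normalizing a handful of probes alone
                    # would keep only within-sample rank patterns
                    shared = average_quantile_reference([m for _, m, _ in cohorts])
                    cohorts = [
                        (ds_id, quantile_normalize(m, ds_id, reference=shared)[0], lab)
                        for ds_id, m, lab in cohorts
                    ]
                datasets_a, datasets_b = [], []
                for ds_id, mat, label in cohorts:
                    y = np.full(mat.n_samples, label, dtype=int)
                    datasets_a.append((ds_id, mat.subset_probes(selection.final_set), y))
                    datasets_b.append((ds_id, mat.subset_probes(reference), y))
                la = integrate_labeled(datasets_a, selection.final_set)
                lb = integrate_labeled(datasets_b, reference)
                comparison[ph] = compare_gene_sets(
                    la.X,
                    lb.X,
                    la.y,
                    _model_factories(config),
                    k=config.cv_folds,
                    repeats=config.cv_repeats,
                    seed=derive_seed(config.seed, 20 + PHASES.index(ph)),
                )
            results["comparison"] = comparison
            rows = []
            for ph, per_model in comparison.items():
                for model, rep in per_model.items():
                    for which in ("A", "B"):
                        row = {"phase": ph, "model": model, "set": which}
                        row.update(rep[which].mean)  # type: ignore[union-attr]
                        rows.append(row)
            pd.DataFrame(rows).to_csv(run_dir / "evaluation.tsv", sep="\t", index=False)
            manifest.add("evaluation.tsv")
        done("evaluate")

        for ph in PHASES:
            write_expression_matrix(run_dir / f"curated_{ph}.tsv", tensor.phase(ph))
            manifest.add(f"curated_{ph}.tsv")
        manifest.write()
    except Exception as exc:  # persist partial outputs, then re-raise with stage
        manifest.data["error"] = str(exc)
        manifest.write()
        raise
    return run_dir, results


def run_cross_platform(config: WorkflowConfig) -> tuple[Path, dict]:
    """Multi-dataset path: collapse, normalize, integrate, compare."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, config)
    results: dict = {}

    spec = dict(config.synthetic or {})
    spec.setdefault("seed", config.seed)
    datasets, truth = generate_cross_platform_suite(**spec)
    proposed = truth.marker_probes
    rng = np.random.default_rng(derive_seed(config.seed, 404))
    all_genes = [
        g
        for g in datasets[0].annotation.genes()
        if g not in set(proposed)
    ]
    reference = (
        read_gene_list(config.known_genes_path)
        if config.known_genes_path
        else sorted(
            rng.choice(
                np.asarray(all_genes, dtype=object),
                size=min(config.n_reference_probes, len(all_genes)),
                replace=False,
            )
        )
    )

    collapsed_all = []
    for ds in datasets:
        mat = ds.matrix
        if config.exclude_samples:
            keep = [s for s in mat.sample_ids if s not in set(config.exclude_samples)]
            idx = [mat.sample_ids.index(s) for s in keep]
            labels = ds.labels[idx]
            mat = mat.subset_samples(keep)
        else:
            labels = ds.labels
        collapsed, _ = collapse_probes_to_genes(mat, ds.annotation)
        collapsed_all.append((ds.dataset_id, collapsed, labels))
    shared_ref = average_quantile_reference([c for _, c, _ in collapsed_all])
    labeled = []
    for ds_id, collapsed, labels in collapsed_all:
        normalized, _ = quantile_normalize(collapsed, ds_id, reference=shared_ref)
        labeled.append((ds_id, normalized, labels))
    la = integrate_labeled(labeled, list(proposed))
    lb = integrate_labeled(labeled, list(reference))
    results["n_samples"] = la.X.shape[0]
    results["n_cases"] = int(la.y.sum())
    comparison = compare_gene_sets(
        la.X,
        lb.X,
        la.y,
        _model_factories(config),
        k=config.cv_folds,
        repeats=config.cv_repeats,
        seed=derive_seed(config.seed, 30),
    )
    results["comparison"] = comparison
    rows = []
    for model, rep in comparison.items():
        for which in ("A", "B"):
            row = {"model": model, "set": which}
            row.update(rep[which].mean)  # type: ignore[union-attr]
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(run_dir / "evaluation_xplat.tsv", sep="\t", index=False)
    manifest.add("evaluation_xplat.tsv")
    summary = {
        "n_samples": results["n_samples"],
        "n_cases": results["n_cases"],
        "metrics": {
            model: {which: rep[which].mean for which in ("A", "B")}
            for model, rep in comparison.items()
        },
    }
    (run_dir / "xplat_summary.json").write_text(json.dumps(summary, indent=1))
    manifest.add("xplat_summary.json")
    manifest.write()
    return run_dir, results
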
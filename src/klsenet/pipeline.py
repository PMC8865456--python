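"""End-to-end orchestration: simulate -> density -> network -> metrics -> aging.

Two surfaces: fast in-memory helpers (``subject_matrix``, ``cohort_matrices``,
``run_recovery_experiment``) used by analyses and tests, and the file-based
``pipeline_run`` behind the command line, which writes every stage's outputs
together with a JSON provenance sidecar.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .aging import hub_count_table, render_report, run_full_analysis
from .atlas import ParcellationAtlas
from .density import (
    StandardGrid,
    botev_bandwidth,
    estimate_parcel_pdf,
    extract_parcel_samples,
    normalize_to_gm_mean,
    silverman_bandwidth,
)
from .exceptions import InputError
from .io import RunConfig, write_matrix_csv, write_parcel_table, write_sidecar, write_volume
from .metrics import compute_nodal_metrics, identify_hubs, count_hubs_by_scope, network_summaries, threshold_edges
from .network import ConnectivityMatrix, build_matrix

log = logging.getLogger("klsenet")

__all__ = [
    "subject_matrix",
    "cohort_matrices",
    "run_recovery_experiment",
    "pipeline_run",
]


def _bandwidth(values: np.ndarray, method: str) -> float:
    if method == "botev":
        return botev_bandwidth(values)
    if method == "silverman":
        return silverman_bandwidth(values)
    raise InputError(f"unknown bandwidth method {method!r}")


def subject_matrix(
    volume: np.ndarray,
    atlas: ParcellationAtlas,
    grid: StandardGrid | None = None,
    min_voxels: int = 800,
    epsilon: float = 1e-12,
    bandwidth: str = "botev",
    subject_id: str | None = None,
    retain_only: set[int] | None = None,
) -> ConnectivityMatrix:
    """Density + network stages for one subject, in memory.

    ``retain_only`` restricts the node set (cohort-wide exclusion: a parcel
    excluded for any subject is excluded for all, so every matrix of a
    cohort shares one node set).
    """
    grid = grid or StandardGrid()
    samples, _excluded = extract_parcel_samples(volume, atlas, min_voxels=min_voxels)
    if retain_only is not None:
        samples = [s for s in samples if s.parcel_id in retain_only]
        if not samples:
            raise InputError("no parcels retained after cohort-wide exclusion")
    samples = normalize_to_gm_mean(samples)
    estimates = [
        estimate_parcel_pdf(s, grid, _bandwidth(s.values, bandwidth)) for s in samples
    ]
    return build_matrix(estimates, epsilon=epsilon, subject_id=subject_id)


def cohort_matrices(
    subjects: list[synthetic.SyntheticSubject],
    atlas: ParcellationAtlas,
    grid: StandardGrid | None = None,
    min_voxels: int = 800,
    epsilon: float = 1e-12,
    bandwidth: str = "botev",
) -> list[ConnectivityMatrix]:
    """Build every subject's KLS matrix on a common, cohort-wide node set."""
    grid = grid or StandardGrid()
    retained: set[int] | None = None
    for subj in subjects:
        samples, _ = extract_parcel_samples(subj.volume, atlas, min_voxels=min_voxels)
        ids = {s.parcel_id for s in samples}
        retained = ids if retained is None else (retained & ids)
    if not retained:
        raise InputError("no parcels retained across the whole cohort")
    return [
        subject_matrix(
            subj.volume,
            atlas,
            grid,
            min_voxels=min_voxels,
            epsilon=epsilon,
            bandwidth=bandwidth,
            subject_id=subj.subject_id,
            retain_only=retained,
        )
        for subj in subjects
    ]


def run_recovery_experiment(
    n_cohorts: int = 50,
    effect_kind: str = "linear",
    n_subjects: int = 67,
    age_range: tuple[float, float] = (20.0, 82.0),
    base_seed: int = 0,
    alpha: float = 0.05,
    atlas_spec: synthetic.PhantomSpec | None = None,
    include_pairs: bool = False,
) -> pd.DataFrame:
    """Simulate cohorts through the full pipeline and regress mean strength.

    ``effect_kind`` is ``"linear"``, ``"quadratic"`` (dispersion effect in
    the designated affected networks, none elsewhere) or ``"null"`` (no age
    effect anywhere).  Returns one row per cohort x scope with the chosen
    model, p-value and slope of the within-scope mean connectivity
    strength, the raw material for parameter-recovery checks.
    """
    spec = atlas_spec or synthetic.PhantomSpec()
    atlas = synthetic.build_phantom_atlas(spec)
    if effect_kind == "null":
        effects = synthetic.null_effect_model()
    else:
        effects = synthetic.aging_effect_model(kind=effect_kind)
    rows = []
    for c in range(n_cohorts):
        seed = int((base_seed + 1_000_003 * c) % (2**31))
        subjects, cohort = synthetic.simulate_cohort(
            atlas, effects, n_subjects=n_subjects, age_range=age_range, seed=seed
        )
        mats = cohort_matrices(subjects, atlas, min_voxels=spec.min_voxels)
        report = run_full_analysis(
            mats,
            cohort["age"].to_numpy(),
            atlas,
            alpha=alpha,
            metrics=("mean_strength",),
            include_pairs=include_pairs,
        )
        report.insert(0, "cohort", c)
        report.insert(1, "cohort_seed", seed)
        rows.append(report)
        log.info("recovery cohort %d/%d done (seed %d)", c + 1, n_cohorts, seed)
    return pd.concat(rows, ignore_index=True)


def _log_stage(stage: str, t0: float, **info) -> None:
    fields = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", stage, time.time() - t0, fields)


def pipeline_run(config: RunConfig, out_dir: str | Path) -> dict:
    """File-based end-to-end run: simulate a phantom cohort, build per-
    subject matrices, compute metrics and the aging report.  Every artifact
    is written under ``out_dir`` with a config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.grid()

    t0 = time.time()
    atlas = synthetic.build_phantom_atlas(synthetic.PhantomSpec(min_voxels=config.min_voxels, seed=config.seed))
    if config.effects == "null":
        effects = synthetic.null_effect_model()
    elif config.effects in ("aging-linear", "aging-quadratic"):
        effects = synthetic.aging_effect_model(kind=config.effects.split("-")[1])
    else:
        raise InputError(f"unknown effects preset {config.effects!r}")
    subjects, cohort = synthetic.simulate_cohort(
        atlas,
        effects,
        n_subjects=config.n_subjects,
        age_range=(config.age_min, config.age_max),
        seed=config.seed,
    )
    write_volume(out / "atlas_labels.nii.gz", atlas.labels, atlas.affine, dtype=np.int32)
    write_parcel_table(out / "parcels.tsv", atlas)
    cohort.to_csv(out / "cohort.csv", index=False)
    for subj in subjects:
        write_volume(out / f"{subj.subject_id}_intensity.nii.gz", subj.volume, atlas.affine, dtype=np.float32)
    _log_stage("simulate", t0, n_subjects=len(subjects), n_parcels=atlas.parcel_ids.size)

    t0 = time.time()
    mats = cohort_matrices(
        subjects, atlas, grid,
        min_voxels=config.min_voxels, epsilon=config.epsilon, bandwidth=config.bandwidth,
    )
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for subj, m in zip(subjects, mats):
        write_matrix_csv(mat_dir / f"{subj.subject_id}_klse.csv", m)
    _log_stage("network", t0, n_nodes=mats[0].n_nodes)

    t0 = time.time()
    nodal_frames = []
    hub_counts = []
    for subj, m in zip(subjects, mats):
        nodal = compute_nodal_metrics(m)
        hubs = identify_hubs(nodal, top_fraction=config.top_fraction)
        nodal = hubs.assign(subject_id=subj.subject_id)
        nodal_frames.append(nodal)
        hub_counts.append(count_hubs_by_scope(hubs, atlas).rename(subj.subject_id))
    pd.concat(nodal_frames, ignore_index=True).to_csv(out / "nodal_metrics.csv", index=False)
    pd.DataFrame(hub_counts).to_csv(out / "hub_counts.csv", index_label="subject_id")
    threshold_edges(mats[0], config.viz_threshold).to_csv(
        out / "viz_edges_first_subject.tsv", sep="\t", index=False
    )
    summaries = []
    for subj, m in zip(subjects, mats):
        s = network_summaries(m, atlas)
        s.insert(0, "subject_id", subj.subject_id)
        summaries.append(s)
    pd.concat(summaries, ignore_index=True).to_csv(out / "network_summaries.csv", index=False)
    _log_stage("metrics", t0, n_subjects=len(subjects))

    t0 = time.time()
    report = run_full_analysis(mats, cohort["age"].to_numpy(), atlas, alpha=config.alpha)
    report.to_csv(out / "aging_report.csv", index=False)
    render_report(report).to_csv(out / "aging_report_table.csv", index=False)
    hub_table = hub_count_table(mats, cohort["age"].to_numpy(), atlas, top_fraction=config.top_fraction)
    hub_table.to_csv(out / "hub_count_table.csv", index=False)
    _log_stage("aging", t0, n_rows=len(report))

    write_sidecar(out / "run_config.json", config, n_subjects=len(subjects), n_nodes=mats[0].n_nodes)
    return {
        "out_dir": str(out),
        "n_subjects": len(subjects),
        "n_nodes": mats[0].n_nodes,
        "report": report,
        "hub_table": hub_table,
    }
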
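"""End-to-end orchestration of the classification workflow.

Stages: cohort acquisition (synthetic generation or a directory of volumes)
-> head-motion exclusion -> temporal preprocessing -> ReHo mapping
(raw -> normalized -> smoothed) -> LOSOCV classification for the three
binary contrasts and the three-class problem -> permutation inference and
discriminative-map clustering -> ROI-symptom partial correlation.

Every run writes a manifest (parameters, package version, input checksums);
reruns with the same configuration and seed reproduce all outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import io as rio
from .mvpa import CVResult, build_features, features_to_map, losocv, pairwise_auc
from .permutation import (
    DiscriminativeMap,
    build_discriminative_map,
    clusters_to_label_map,
    permute_performance,
)
from .preprocess import exclude_by_motion, preprocess_series
from .reho import normalize_global_mean, reho_map, smooth_gaussian
from .roicorr import DEFAULT_COVARIATES, extract_roi_means, roi_symptom_correlation
from .synthetic import SyntheticConfig, iter_cohort, make_mask
from .types import ReHoMap, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "BINARY_CONTRASTS"]

#: The binary contrasts, patient-like class first (that class is "positive").
BINARY_CONTRASTS = (("DET", "HC"), ("ET", "HC"), ("DET", "ET"))


@dataclass
class PipelineConfig:
    """All knobs of the full workflow in one place."""

    output_dir: str = "pipeline_out"
    # data source: a synthetic cohort (default) or a directory written by
    # the `simulate` stage / external tooling
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cohort_dir: str | None = None
    # preprocessing
    fd_threshold_mm: float = 0.2
    low_hz: float = 0.01
    high_hz: float = 0.08
    # reho
    fwhm_mm: float = 4.0
    edge_policy: str = "subset"
    # classification
    algorithm: str = "svm"
    c_param: float = 1.0
    sigma0_sq: float = 10.0
    positive_class: str | None = None
    center: str = "fold"
    # inference
    n_perm: int = 1000
    alpha: float = 0.001
    min_cluster: int = 30
    connectivity: int = 26
    # roi correlation
    corr_alpha: float = 0.05
    bonferroni_mode: str = "tests"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_dir is None:
            self.synthetic.validate()
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.algorithm not in ("svm", "bgpc"):
            raise ValueError("binary algorithm must be 'svm' or 'bgpc'")


def _log_stage(stage: str, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"stage={stage} {pairs}", file=sys.stderr)


def _smoothed_maps(config: PipelineConfig) -> tuple[list[ReHoMap], list[SubjectRecord], np.ndarray]:
    """Produce per-subject smoothed ReHo maps, streaming one volume at a time."""
    if config.cohort_dir is not None:
        records = rio.read_records(Path(config.cohort_dir) / "records.csv")
        mask = rio.read_mask(Path(config.cohort_dir) / "mask.nii.gz")
        sources = [
            (rio.read_bold(Path(config.cohort_dir) / f"{r.subject_id}.nii.gz"), r)
            for r in records
        ]
        stream = iter(sources)
    else:
        mask = make_mask(config.synthetic)
        stream = iter_cohort(config.synthetic)

    retained_maps: list[ReHoMap] = []
    retained_records: list[SubjectRecord] = []
    all_records: list[SubjectRecord] = []
    for series, record in stream:
        all_records.append(record)
        if record.fd_power > config.fd_threshold_mm:
            continue  # gate before the expensive stages
        try:
            clean = preprocess_series(series, low_hz=config.low_hz, high_hz=config.high_hz)
            raw = reho_map(clean, mask, edge_policy=config.edge_policy)
            sm = smooth_gaussian(normalize_global_mean(raw), fwhm_mm=config.fwhm_mm)
        except Exception as exc:
            raise RuntimeError(
                f"stage=reho subject={record.subject_id}: {exc}"
            ) from exc
        retained_maps.append(sm)
        retained_records.append(record)

    _, report = exclude_by_motion(all_records, config.fd_threshold_mm)
    _log_stage(
        "exclusion",
        n_input=report["n_input"],
        n_retained=report["n_retained"],
        excluded=",".join(report["excluded_ids"]) or "-",
    )
    return retained_maps, retained_records, mask


def _binary_task(
    config: PipelineConfig,
    maps: list[ReHoMap],
    records: list[SubjectRecord],
    mask: np.ndarray,
    pos: str,
    neg: str,
    out: Path,
    seed: int,
) -> dict:
    sel = [i for i, r in enumerate(records) if r.group in (pos, neg)]
    labels = np.array([records[i].group for i in sel])
    feats = build_features([maps[i] for i in sel], mask)
    observed = losocv(
        feats,
        labels,
        algorithm=config.algorithm,
        c_param=config.c_param,
        sigma0_sq=config.sigma0_sq,
        positive_class=pos,
        center=config.center,
    )
    task = f"{pos}_vs_{neg}"
    task_dir = out / task
    task_dir.mkdir(parents=True, exist_ok=True)
    _write_cv_outputs(observed, task_dir)
    w_map = features_to_map(observed.mean_weights, feats.voxel_index, feats.grid_shape)
    rio.write_reho_map(
        ReHoMap(w_map, mask, stage="raw", subject_id=task, affine=maps[0].affine),
        task_dir / "weight_map.nii.gz",
    )

    result = {"task": task, "metrics": observed.metrics, "observed": observed}
    if config.n_perm > 0:
        perm, _ = permute_performance(
            feats,
            labels,
            algorithm=config.algorithm,
            n_perm=config.n_perm,
            seed=seed,
            collect_weights=True,
            observed=observed,
            c_param=config.c_param,
            sigma0_sq=config.sigma0_sq,
            positive_class=pos,
            center=config.center,
        )
        dmap = build_discriminative_map(
            feats,
            observed,
            perm,
            alpha=config.alpha,
            min_cluster=config.min_cluster,
            connectivity=config.connectivity,
        )
        _write_inference_outputs(perm, dmap, maps[0].affine, mask, task_dir)
        result["permutation"] = perm
        result["discriminative_map"] = dmap
    else:
        logger.warning("n_perm = 0: skipping permutation inference for %s", task)
    _log_stage("classify", task=task, total_accuracy=f"{observed.metrics['total_accuracy']:.4f}")
    return result


def _write_cv_outputs(observed: CVResult, task_dir: Path) -> None:
    flat = {
        k: v
        for k, v in observed.metrics.items()
        if not isinstance(v, dict)
    }
    pd.DataFrame([flat]).to_csv(task_dir / "metrics.csv", index=False)
    np.savetxt(
        task_dir / "confusion_matrix.txt",
        observed.confusion,
        fmt="%d",
        header=" ".join(map(str, observed.classes)),
    )
    preds = pd.DataFrame(
        {
            "subject_id": observed.subject_ids,
            "true": observed.y_true,
            "predicted": observed.y_pred,
        }
    )
    preds.to_csv(task_dir / "predictions.csv", index=False)
    if observed.scores.ndim == 1:
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(
            observed.y_true == observed.positive_class, observed.scores
        )
        np.savetxt(task_dir / "roc.txt", np.column_stack([fpr, tpr]), fmt="%.6f")


def _write_inference_outputs(
    perm, dmap: DiscriminativeMap, affine: np.ndarray, mask: np.ndarray, task_dir: Path
) -> None:
    with open(task_dir / "permutation_summary.txt", "w") as fh:
        fh.write(f"n_perm: {perm.n_perm}\nseed: {perm.seed}\n")
        for name, obs in perm.observed.items():
            fh.write(f"{name}: observed={obs:.4f} {perm.p_strings[name]}\n")
    rio.write_reho_map(
        ReHoMap(dmap.voxel_p, mask, stage="raw", subject_id="voxel_p", affine=affine),
        task_dir / "voxel_p.nii.gz",
    )
    nib.save(
        nib.Nifti1Image(
            clusters_to_label_map(dmap.clusters, mask.shape), affine
        ),
        str(task_dir / "cluster_labels.nii.gz"),
    )
    rows = []
    for c in dmap.clusters:
        mm = affine @ np.array([*c.peak, 1.0])
        rows.append(
            {
                "label": c.label,
                "size": c.size,
                "sign": c.sign,
                "peak_i": c.peak[0],
                "peak_j": c.peak[1],
                "peak_k": c.peak[2],
                "peak_x_mm": mm[0],
                "peak_y_mm": mm[1],
                "peak_z_mm": mm[2],
            }
        )
    pd.DataFrame(
        rows, columns=["label", "size", "sign", "peak_i", "peak_j", "peak_k",
                       "peak_x_mm", "peak_y_mm", "peak_z_mm"]
    ).to_csv(task_dir / "clusters.csv", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a report dict of all stage results."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    maps, records, mask = _smoothed_maps(config)
    rio.write_records(records, out / "retained_records.csv")

    report: dict = {"n_subjects": len(records), "tasks": {}}
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)

    groups_present = {r.group for r in records}
    for i, (pos, neg) in enumerate(BINARY_CONTRASTS):
        if not ({pos, neg} <= groups_present):
            continue
        res = _binary_task(
            config, maps, records, mask, pos, neg, out, int(seeds[i])
        )
        report["tasks"][res["task"]] = res

    # three-class task (multiclass Gaussian process)
    if len(groups_present) == 3:
        labels = np.array([r.group for r in records])
        feats = build_features(maps, mask)
        observed = losocv(
            feats,
            labels,
            algorithm="mgpc",
            sigma0_sq=config.sigma0_sq,
            center=config.center,
        )
        task_dir = out / "three_class"
        task_dir.mkdir(exist_ok=True)
        _write_cv_outputs(observed, task_dir)
        res3: dict = {"task": "three_class", "metrics": observed.metrics, "observed": observed}
        if observed.scores.ndim == 2:
            res3["pairwise_auc"] = pairwise_auc(
                observed.y_true, observed.scores, observed.classes
            )
        if config.n_perm > 0:
            perm, _ = permute_performance(
                feats,
                labels,
                algorithm="mgpc",
                n_perm=config.n_perm,
                seed=int(seeds[3]),
                observed=observed,
                sigma0_sq=config.sigma0_sq,
                center=config.center,
            )
            with open(task_dir / "permutation_summary.txt", "w") as fh:
                fh.write(f"n_perm: {perm.n_perm}\nseed: {perm.seed}\n")
                for name, obs in perm.observed.items():
                    fh.write(f"{name}: observed={obs:.4f} {perm.p_strings[name]}\n")
            res3["permutation"] = perm
        report["tasks"]["three_class"] = res3
        _log_stage("classify", task="three_class",
                   total_accuracy=f"{observed.metrics['total_accuracy']:.4f}")

    # ROI-symptom correlation from the DET-vs-HC discriminative clusters
    det_hc = report["tasks"].get("DET_vs_HC")
    if det_hc and "discriminative_map" in det_hc and det_hc["discriminative_map"].clusters:
        clusters = det_hc["discriminative_map"].clusters
        det_idx = [i for i, r in enumerate(records) if r.group == "DET"]
        det_maps = [maps[i] for i in det_idx]
        det_records = [records[i] for i in det_idx]
        try:
            roi_table = extract_roi_means(det_maps, clusters)
            corr = roi_symptom_correlation(
                roi_table,
                det_records,
                covariates=config.covariates,
                alpha=config.corr_alpha,
                bonferroni_mode=config.bonferroni_mode,
            )
            corr.to_csv(out / "roi_correlation.csv")
            report["roi_correlation"] = corr
            _log_stage("correlate", n_roi=len(clusters))
        except ValueError as exc:
            logger.warning("ROI correlation skipped: %s", exc)

    params = asdict(config)
    rio.write_manifest(out, params)
    _log_stage("done", output_dir=str(out))
    return report
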
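"""File formats and run manifests.

Machine-readable tables are TSV with 17-significant-digit floats (so
re-reading reproduces values bit-for-bit); human reports round to 3 decimal
places.  Motion traces use the 6-column whitespace realignment-parameter
dialect (3 translations in mm, 3 rotations in rad).  Models, candidate sets,
ground truth and manifests are JSON.  All ids and edge indices are 0-based
in machine files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossval import CVResult
from .dataset import FCDataset, edge_pairs
from .fcprep import FCVector, MotionTrace, ROITimeSeries
from .slr import SLRModel
from .synthcohort import GroundTruth, SubjectRecord

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_motion", "read_motion",
    "write_metadata", "read_subject_table",
    "write_fc_vector", "read_fc_vector",
    "write_fc_matrix", "read_fc_matrix",
    "write_ground_truth", "read_ground_truth",
    "write_model", "read_model",
    "write_cv_result",
    "write_manifest", "file_checksum",
]

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# -- time series and motion -------------------------------------------------

def write_timeseries(ts: ROITimeSeries, path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.region_names)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path, tr: float) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ROITimeSeries(df.to_numpy(float), tr, list(df.columns))


def write_motion(motion: MotionTrace | np.ndarray, path) -> None:
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion)
    np.savetxt(path, params, fmt=_FLOAT_FMT)


def read_motion(path) -> MotionTrace:
    return MotionTrace(np.loadtxt(path, ndmin=2))


# -- subject metadata -------------------------------------------------------

def write_metadata(records: list, path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "cohort": r.cohort,
               "age": r.age, "sex": r.sex, "bdi_total": r.bdi_total, "eros": r.eros}
        for k, v in enumerate(r.bdi_items, start=1):
            row[f"bdi_item_{k:02d}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_subject_table(path) -> list:
    """Read and validate a metadata TSV into SubjectRecord objects.

    Validation errors (group/BDI inconsistency, out-of-range items) name the
    offending subject id.
    """
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"no subjects in {path}")
    item_cols = [f"bdi_item_{k:02d}" for k in range(1, 22)]
    required = ["subject_id", "group", "age", "sex", "bdi_total", "eros"] + item_cols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table is missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            bdi_total=int(row["bdi_total"]),
            bdi_items=[int(row[c]) for c in item_cols],
            eros=int(row["eros"]),
            cohort=str(row.get("cohort", "training")),
        ))
    return records


# -- FC vectors -------------------------------------------------------------

def write_fc_vector(fc: FCVector, path) -> None:
    """Per-subject FC table: edge_id, region_i, region_j, value (r or z)."""
    pairs = edge_pairs(fc.n_regions)
    col = "r" if fc.scale == "pearson_r" else "z"
    df = pd.DataFrame({"edge_id": np.arange(fc.n_edges),
                       "region_i": pairs[:, 0], "region_j": pairs[:, 1],
                       col: fc.values})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_fc_vector(path, n_regions: int) -> FCVector:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    scale = "pearson_r" if "r" in df.columns else "fisher_z"
    col = "r" if scale == "pearson_r" else "z"
    return FCVector(df[col].to_numpy(float), scale=scale, n_regions=n_regions)


def write_fc_matrix(ds: FCDataset, path) -> None:
    """Cohort FC matrix: one row per subject, edges in canonical order."""
    df = pd.DataFrame(ds.X, columns=[f"e{k}" for k in range(ds.n_features)])
    df.insert(0, "subject_id", ds.subject_ids)
    df.insert(1, "group", np.where(ds.y == 1, "StD", "HC"))
    df.insert(2, "age", ds.age)
    df.insert(3, "sex", np.where(np.asarray(ds.sex) == 1.0, "male", "female"))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_fc_matrix(path, n_regions: int, scale: str = "fisher_z") -> FCDataset:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    return FCDataset(
        X=df[cols].to_numpy(float),
        y=(df["group"] == "StD").astype(int).to_numpy(),
        age=df["age"].to_numpy(float),
        sex=(df["sex"] == "male").astype(float).to_numpy(),
        subject_ids=[str(s) for s in df["subject_id"]],
        n_regions=n_regions,
        scale=scale,
    )


# -- ground truth, models, results ------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    obj = {
        "discriminative_edge_ids": truth.discriminative_edge_ids.tolist(),
        "z_mean_std": truth.z_mean_std.tolist(),
        "z_mean_hc": truth.z_mean_hc.tolist(),
        "nuisance_map": {str(k): v for k, v in truth.nuisance_map.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        obj = json.load(fh)
    return GroundTruth(
        discriminative_edge_ids=np.array(obj["discriminative_edge_ids"], dtype=int),
        z_mean_std=np.array(obj["z_mean_std"]),
        z_mean_hc=np.array(obj["z_mean_hc"]),
        nuisance_map={int(k): [tuple(e) for e in v]
                      for k, v in obj["nuisance_map"].items()},
    )


def write_model(model: SLRModel, path, n_regions: int | None = None,
                config_hash: str = "") -> None:
    edge_ids = getattr(model, "edge_ids", None)
    obj = {
        "feature_ids": model.feature_ids.tolist(),
        "edge_ids": None if edge_ids is None else np.asarray(edge_ids).tolist(),
        "m": model.m.tolist(),
        "S_diag": np.diag(model.S).tolist(),
        "alpha": model.alpha.tolist(),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "config_hash": config_hash,
    }
    if n_regions is not None and edge_ids is not None:
        pairs = edge_pairs(n_regions)
        obj["edge_pairs"] = pairs[np.asarray(edge_ids)].tolist()
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_model(path) -> SLRModel:
    with open(path) as fh:
        obj = json.load(fh)
    model = SLRModel(
        feature_ids=np.array(obj["feature_ids"], dtype=int),
        m=np.array(obj["m"]),
        S=np.diag(obj["S_diag"]),
        alpha=np.array(obj["alpha"]),
        xi=np.array([]),
        mean_=np.array(obj["mean"]),
        scale_=np.array(obj["scale"]),
        converged=obj["converged"],
        n_iter=obj["n_iter"],
    )
    if obj.get("edge_ids") is not None:
        model.edge_ids = np.array(obj["edge_ids"], dtype=int)
    return model


def write_cv_result(cv: CVResult, json_path, weights_path=None,
                    config_hash: str = "") -> None:
    obj = {
        "n_subjects": cv.n_subjects,
        "n_features": cv.n_features,
        "accuracy": cv.accuracy,
        "sensitivity": cv.sensitivity,
        "specificity": cv.specificity,
        "auc": cv.auc,
        "predictions": cv.predictions.tolist(),
        "labels": cv.labels.tolist(),
        "selected": [np.asarray(s).tolist() for s in cv.selected],
        "ever_selected": cv.ever_selected.tolist(),
        "config_hash": config_hash,
    }
    with open(json_path, "w") as fh:
        json.dump(obj, fh)
    if weights_path is not None:
        # sparse triplet dialect: fold, edge_id, weight (nonzero entries only)
        folds, edges = np.nonzero(cv.weights)
        with open(weights_path, "w") as fh:
            fh.write("fold\tedge_id\tweight\n")
            for f, e in zip(folds, edges):
                fh.write(f"{f}\t{e}\t{_fmt(cv.weights[f, e])}\n")


# -- manifests --------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, stage: str, config_hash: str, seed: int,
                   inputs: list | None = None, outputs: list | None = None,
                   elapsed_s: float | None = None) -> None:
    obj = {
        "stage": stage,
        "version": __version__,
        "config_hash": config_hash,
        "seed": int(seed),
        "elapsed_s": elapsed_s,
        "inputs": {str(p): file_checksum(p) for p in (inputs or []) if Path(p).exists()},
        "outputs": {str(p): file_checksum(p) for p in (outputs or []) if Path(p).exists()},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
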
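"""Reading and writing on-disk formats, motion QC, and voxel-to-ROI pooling.

File dialects
-------------
Time-series matrices are plain delimited text (whitespace or comma,
auto-detected), rows = time points, columns = regions.  The manifest is a
delimited table with columns ``subject_id, group, age, gender, education,
timeseries_file`` and an optional ``motion_file``.  Viewer exports follow the
BrainNet Viewer ``.node`` (x, y, z, color, size, label) and ``.edge``
(N x N matrix) conventions.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MotionSummary,
    RegionAtlasLabels,
    SubjectRecord,
    VALID_GROUPS,
    cohort_n_regions,
)

logger = logging.getLogger(__name__)

# Viewer color codes for nodal group differences.
NODE_COLOR_NONE = 0.0
NODE_COLOR_PATIENT_GT = 1.0
NODE_COLOR_PATIENT_LT = 2.0

_MANIFEST_REQUIRED = ("subject_id", "group", "age", "gender", "education",
                      "timeseries_file")


def load_matrix(path: str | Path) -> np.ndarray:
    """Load a delimited-text numeric matrix, auto-detecting the delimiter."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None  # None -> any whitespace
    mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return mat


def save_matrix(mat: np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited text at full float precision."""
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.17g")


def default_atlas() -> RegionAtlasLabels:
    """The packaged 90-region AAL parcellation name list."""
    ref = importlib.resources.files("roinet.data") / "aal90_labels.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return RegionAtlasLabels(
        names=table["name"].tolist(),
        abbreviations=table["abbreviation"].tolist(),
    )


def load_cohort(manifest_path: str | Path,
                data_dir: str | Path | None = None) -> list[SubjectRecord]:
    """Load a cohort of subjects from a manifest table.

    Parameters
    ----------
    manifest_path : path
        Delimited table with one row per subject.  File paths in the table
        are resolved relative to ``data_dir`` (default: the manifest's
        directory).
    data_dir : path, optional
        Base directory for ``timeseries_file`` / ``motion_file`` entries.

    Returns
    -------
    list of SubjectRecord in manifest row order.
    """
    manifest_path = Path(manifest_path)
    base = Path(data_dir) if data_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep=None, engine="python",
                           dtype={"subject_id": str})
    missing_cols = [c for c in _MANIFEST_REQUIRED if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {missing_cols}")

    records: list[SubjectRecord] = []
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        group = str(row.group)
        if group not in VALID_GROUPS:
            raise ValueError(
                f"subject {sid!r}: unknown group label {group!r}"
            )
        ts_path = base / str(row.timeseries_file)
        if not ts_path.is_file():
            raise FileNotFoundError(
                f"subject {sid!r}: time-series file not found: {ts_path}"
            )
        ts = load_matrix(ts_path)
        motion = None
        motion_file = getattr(row, "motion_file", None)
        if motion_file is not None and not pd.isna(motion_file):
            mot_path = base / str(motion_file)
            if not mot_path.is_file():
                raise FileNotFoundError(
                    f"subject {sid!r}: motion file not found: {mot_path}"
                )
            motion = load_matrix(mot_path)
        records.append(SubjectRecord(
            subject_id=sid,
            group=group,
            timeseries=ts,
            motion=motion,
            covariates={
                "age": float(row.age),
                "gender": float(row.gender),
                "education": float(row.education),
            },
        ))
    cohort_n_regions(records)  # enforce dimension consistency
    return records


def apply_motion_exclusion(
    records: list[SubjectRecord],
    trans_limit: float = 1.5,
    rot_limit: float = 1.5,
) -> tuple[list[SubjectRecord], list[MotionSummary]]:
    """Exclude subjects that moved more than the translation/rotation limits.

    A subject is excluded when its maximum absolute frame-wise translation
    exceeds ``trans_limit`` (mm) or its maximum absolute rotation exceeds
    ``rot_limit`` (degrees); the comparison is strict, so a subject exactly
    at a limit is retained.  Subjects without a motion trace are retained
    with a logged warning and NaN summary values.
    """
    retained: list[SubjectRecord] = []
    summaries: list[MotionSummary] = []
    for rec in records:
        if rec.motion is None:
            logger.warning(
                "subject %s has no motion trace; retained without motion QC",
                rec.subject_id,
            )
            summaries.append(MotionSummary(rec.subject_id, np.nan, np.nan,
                                           excluded=False))
            retained.append(rec)
            continue
        max_trans = float(np.max(np.abs(rec.motion[:, :3])))
        max_rot = float(np.max(np.abs(rec.motion[:, 3:])))
        excluded = (max_trans > trans_limit) or (max_rot > rot_limit)
        summaries.append(MotionSummary(rec.subject_id, max_trans, max_rot,
                                       excluded))
        if not excluded:
            retained.append(rec)
    return retained, summaries


def average_voxels_to_roi(voxel_series: np.ndarray,
                          labels: np.ndarray) -> np.ndarray:
    """Pool a voxel-level series to ROI level by unweighted averaging.

    Parameters
    ----------
    voxel_series : ndarray, shape (T, V)
        One column per voxel.
    labels : ndarray, shape (V,)
        Region index of each voxel; every index 0..max(labels) must occur.

    Returns
    -------
    ndarray, shape (T, N) with column r the mean over voxels labelled r.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if voxel_series.ndim != 2 or labels.ndim != 1:
        raise ValueError("voxel_series must be T x V and labels length V")
    if voxel_series.shape[1] != labels.shape[0]:
        raise ValueError(
            f"{voxel_series.shape[1]} voxel columns but "
            f"{labels.shape[0]} labels"
        )
    n_regions = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_regions)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"regions with no voxels: {empty.tolist()}")
    out = np.zeros((voxel_series.shape[0], n_regions))
    for r in range(n_regions):
        out[:, r] = voxel_series[:, labels == r].mean(axis=1)
    return out


def motion_summary_table(summaries: list[MotionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "max_translation_mm": [s.max_translation for s in summaries],
            "max_rotation_deg": [s.max_rotation for s in summaries],
            "excluded": [s.excluded for s in summaries],
        }
    )


def write_viewer_files(
    nodal_results: pd.DataFrame,
    coords: np.ndarray,
    out_prefix: str | Path,
    labels: RegionAtlasLabels | None = None,
    edge_matrix: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` / ``.edge`` files for nodal results.

    ``nodal_results`` needs columns ``node``, ``significant``, ``direction``
    and optionally ``t_value`` (used as node size).  Color codes: 1 for
    patient > control, 2 for patient < control, 0 for no difference.
    """
    coords = np.asarray(coords, dtype=float)
    nodes = nodal_results["node"].to_numpy()
    n = int(nodes.max()) + 1
    if coords.shape != (n, 3):
        raise ValueError(
            f"coords must be {n} x 3 to match {n} nodes, got {coords.shape}"
        )
    if labels is None:
        atlas = default_atlas()
        if len(atlas) == n:
            labels = atlas
        else:
            labels = RegionAtlasLabels(
                names=[f"node{i:02d}" for i in range(n)],
                abbreviations=[f"n{i:02d}" for i in range(n)],
            )
    colors = np.full(n, NODE_COLOR_NONE)
    sizes = np.ones(n)
    for row in nodal_results.itertuples(index=False):
        i = int(row.node)
        if bool(row.significant):
            colors[i] = (NODE_COLOR_PATIENT_GT
                         if row.direction == "patient_gt"
                         else NODE_COLOR_PATIENT_LT)
        if hasattr(row, "t_value") and np.isfinite(row.t_value):
            sizes[i] = abs(float(row.t_value))

    out_prefix = Path(out_prefix)
    node_path = out_prefix.with_suffix(".node")
    edge_path = out_prefix.with_suffix(".edge")
    with open(node_path, "w") as fh:
        for i in range(n):
            fh.write(
                f"{coords[i, 0]:.4f}\t{coords[i, 1]:.4f}\t{coords[i, 2]:.4f}"
                f"\t{colors[i]:g}\t{sizes[i]:.4f}\t{labels.abbreviations[i]}\n"
            )
    if edge_matrix is None:
        edge_matrix = np.zeros((n, n))
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    if edge_matrix.shape != (n, n):
        raise ValueError(
            f"edge matrix must be {n} x {n}, got {edge_matrix.shape}"
        )
    np.savetxt(edge_path, edge_matrix, fmt="%.6g", delimiter="\t")
    return node_path, edge_path


def read_node_file(path: str | Path) -> pd.DataFrame:
    """Read a ``.node`` file back into a table (inverse of the writer)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append(
                {
                    "x": float(parts[0]),
                    "y": float(parts[1]),
                    "z": float(parts[2]),
                    "color": float(parts[3]),
                    "size": float(parts[4]),
                    "label": parts[5] if len(parts) > 5 else "",
                }
            )
    return pd.DataFrame(rows)


def stub_coordinates(n: int, radius: float = 70.0) -> np.ndarray:
    """Deterministic synthetic node coordinates on a sphere.

    These are a layout stub for viewer exports when no anatomical
    coordinates are supplied; they carry no anatomical meaning.
    """
    idx = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (idx + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = golden * idx
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
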
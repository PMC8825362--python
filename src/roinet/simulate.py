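"""Seeded two-group cohort simulation with planted connectivity differences.

The generator draws each subject's ROI time series from a stationary
multivariate Gaussian whose population correlation matrix has block
(community) structure: correlations are ``within_block_r`` inside a block
and ``between_block_r`` elsewhere.  In the patient group, the between-block
correlations of a chosen set of *effect nodes* are shifted by
``effect_delta_r``, which changes those nodes' topological role (degree,
betweenness) after thresholding — the ground truth every downstream stage
is tested against.  Independent Gaussian observation noise with standard
deviation ``noise_sd`` is added on top, attenuating all sample correlations
uniformly by 1/(1 + noise_sd^2).

The model is deliberately stationary and white in time (an optional AR(1)
coefficient adds temporal smoothness for robustness checks): Pearson
correlation and everything downstream depend only on the joint distribution
across regions, not on temporal dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GROUP_CONTROL, GROUP_PATIENT, SubjectRecord

_PD_EIG_FLOOR = 1e-6  # eigenvalue floor used by the positive-definite repair


@dataclass
class SimulationConfig:
    """Parameters of a simulated two-group study.

    Defaults emulate a two-group resting-state study: 27 subjects per
    group, 90 regions, 190 retained time points (200 acquired minus 10
    discarded at the start of the scan).
    """

    n_per_group: int = 27
    n_regions: int = 90
    n_timepoints: int = 190
    n_blocks: int = 6
    within_block_r: float = 0.5
    between_block_r: float = 0.1
    effect_nodes: tuple[int, ...] = (4, 19, 34)
    effect_delta_r: float = 0.3
    noise_sd: float = 0.2
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30 for a stable "
                             "correlation estimate")
        if self.n_regions < 2 or self.n_per_group < 2:
            raise ValueError("need n_regions >= 2 and n_per_group >= 2")
        if not (0 < self.within_block_r < 1):
            raise ValueError("within_block_r must be in (0, 1)")
        if not (0 <= self.between_block_r <= self.within_block_r):
            raise ValueError(
                "between_block_r must be in [0, within_block_r]")
        if not (1 <= self.n_blocks <= self.n_regions):
            raise ValueError("n_blocks must be in [1, n_regions]")
        if not (0 <= abs(self.ar1) < 1):
            raise ValueError("ar1 must have magnitude < 1")
        self.effect_nodes = tuple(int(k) for k in self.effect_nodes)
        for k in self.effect_nodes:
            if not (0 <= k < self.n_regions):
                raise ValueError(f"effect node {k} outside 0..{self.n_regions - 1}")
        # Fail fast if the requested structure cannot yield a usable
        # correlation matrix for either group.
        for group in (GROUP_CONTROL, GROUP_PATIENT):
            build_population_covariance(self, group)

    def block_of(self) -> np.ndarray:
        """Block index of each region (contiguous, nearly equal blocks)."""
        return np.floor(
            np.arange(self.n_regions) * self.n_blocks / self.n_regions
        ).astype(int)


def _nearest_pd_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at a small floor and the diagonal is rescaled
    back to one; target correlations are perturbed slightly when clipping
    is active.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, _PD_EIG_FLOOR, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    if np.min(np.linalg.eigvalsh((repaired + repaired.T) / 2.0)) <= 0:
        raise ValueError("population matrix is not positive definite "
                         "after repair; adjust the configuration")
    return (repaired + repaired.T) / 2.0


def build_population_covariance(config: SimulationConfig,
                                group: str) -> np.ndarray:
    """Population correlation matrix for one group.

    Control: block-constant structure.  Patient: additionally, every
    between-block entry in the rows/columns of ``effect_nodes`` is shifted
    by ``effect_delta_r`` (clipped to ±0.99), then the matrix is projected
    to the nearest positive-definite correlation matrix.
    """
    n = config.n_regions
    block = config.block_of()
    same_block = block[:, None] == block[None, :]
    mat = np.where(same_block, config.within_block_r, config.between_block_r)
    np.fill_diagonal(mat, 1.0)
    if group == GROUP_PATIENT and config.effect_delta_r != 0:
        for k in config.effect_nodes:
            cross = ~same_block[k]
            mat[k, cross] += config.effect_delta_r
            mat[cross, k] = mat[k, cross]
        np.clip(mat, -0.99, 0.99, out=mat)
        np.fill_diagonal(mat, 1.0)
    elif group not in (GROUP_PATIENT, GROUP_CONTROL):
        raise ValueError(f"unknown group {group!r}")
    return _nearest_pd_correlation(mat)


def _draw_timeseries(rng: np.random.Generator, chol: np.ndarray,
                     t: int, noise_sd: float, ar1: float) -> np.ndarray:
    n = chol.shape[0]
    z = rng.standard_normal((t, n))
    if ar1:
        # AR(1) filter with variance-preserving innovations so the
        # stationary cross-sectional covariance is unchanged.
        scale = np.sqrt(1.0 - ar1 * ar1)
        out = np.empty_like(z)
        out[0] = z[0]
        for i in range(1, t):
            out[i] = ar1 * out[i - 1] + scale * z[i]
        z = out
    ts = z @ chol.T
    if noise_sd:
        ts = ts + noise_sd * rng.standard_normal((t, n))
    return ts


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates with realistic dependence: school-age children.

    Age uniform over 5-14 years; gender balanced; education tracks age
    (roughly age minus school-entry age) with one year of noise.
    """
    age = rng.uniform(5.0, 14.0, size=n)
    gender = np.zeros(n)
    gender[rng.permutation(n)[: n // 2]] = 1.0
    education = np.clip(age - 6.0 + rng.normal(0.0, 1.0, size=n), 0.0, None)
    return pd.DataFrame({"age": np.round(age, 2), "gender": gender,
                         "education": np.round(education, 2)})


def simulate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw a full two-group cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    for group, prefix in ((GROUP_CONTROL, "con"), (GROUP_PATIENT, "pat")):
        cov = build_population_covariance(config, group)
        chol = np.linalg.cholesky(cov)
        covs = _draw_covariates(rng, config.n_per_group)
        for i in range(config.n_per_group):
            ts = _draw_timeseries(rng, chol, config.n_timepoints,
                                  config.noise_sd, config.ar1)
            records.append(SubjectRecord(
                subject_id=f"{prefix}{i + 1:02d}",
                group=group,
                timeseries=ts,
                covariates=covs.iloc[i].to_dict(),
            ))
    return records


@dataclass
class GroundTruth:
    """What was planted, for checking recovery downstream."""

    effect_nodes: tuple[int, ...]
    effect_delta_r: float
    population_control: np.ndarray = field(repr=False)
    population_patient: np.ndarray = field(repr=False)


def ground_truth(config: SimulationConfig) -> GroundTruth:
    return GroundTruth(
        effect_nodes=config.effect_nodes,
        effect_delta_r=config.effect_delta_r,
        population_control=build_population_covariance(config, GROUP_CONTROL),
        population_patient=build_population_covariance(config, GROUP_PATIENT),
    )


def write_cohort(records: list[SubjectRecord], out_dir: str | Path,
                 config: SimulationConfig | None = None) -> Path:
    """Write a cohort directory: manifest + one time-series file per subject.

    Returns the manifest path.  When ``config`` is given, the planted
    ground truth is saved alongside (effect nodes and population matrices).
    """
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}_timeseries.txt"
        _io.save_matrix(rec.timeseries, out_dir / fname)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.covariates.get("age"),
            "gender": rec.covariates.get("gender"),
            "education": rec.covariates.get("education"),
            "timeseries_file": fname,
        }
        if rec.motion is not None:
            mname = f"{rec.subject_id}_motion.txt"
            _io.save_matrix(rec.motion, out_dir / mname)
            row["motion_file"] = mname
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    if config is not None:
        truth = ground_truth(config)
        _io.save_matrix(truth.population_control,
                        out_dir / "population_control.txt")
        _io.save_matrix(truth.population_patient,
                        out_dir / "population_patient.txt")
        pd.DataFrame({"effect_node": list(truth.effect_nodes),
                      "effect_delta_r": truth.effect_delta_r}).to_csv(
            out_dir / "ground_truth.csv", index=False)
    return manifest_path
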
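"""Core domain containers shared across the pipeline.

A cohort is a list of :class:`SubjectRecord`; everything downstream
(correlation matrices, thresholded graph stacks, metric tables) is keyed by
``subject_id`` and assumes all subjects share the same parcellation (same
number of regions, same region ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_PATIENT, GROUP_CONTROL)

#: Covariate column order used throughout residualization.
COVARIATE_NAMES = ("age", "gender", "education")


@dataclass
class SubjectRecord:
    """One subject: ROI time series, optional motion trace, group, covariates.

    Parameters
    ----------
    subject_id : str
        Unique identifier within the cohort.
    group : str
        Either ``"patient"`` or ``"control"``.
    timeseries : ndarray, shape (T, N)
        BOLD time series, rows = time points, columns = regions.
    motion : ndarray or None, shape (T, 6)
        Frame-wise realignment parameters: three translations (mm) followed
        by three rotations (degrees).
    covariates : dict
        Keys ``age`` (years), ``gender`` (binary coded 0/1), ``education``
        (years of schooling).
    """

    subject_id: str
    group: str
    timeseries: np.ndarray
    motion: np.ndarray | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}; "
                f"expected one of {VALID_GROUPS}"
            )
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] < 2 or ts.shape[1] < 2:
            raise ValueError(
                f"subject {self.subject_id!r}: time series must be a T x N "
                f"matrix with T >= 2 and N >= 2, got shape {ts.shape}"
            )
        if not np.isfinite(ts).all():
            raise ValueError(
                f"subject {self.subject_id!r}: time series contains "
                "non-finite values"
            )
        self.timeseries = ts
        if self.motion is not None:
            mot = np.asarray(self.motion, dtype=float)
            if mot.ndim != 2 or mot.shape[1] != 6:
                raise ValueError(
                    f"subject {self.subject_id!r}: motion trace must have 6 "
                    f"columns (3 translations mm, 3 rotations deg), got "
                    f"shape {mot.shape}"
                )
            self.motion = mot

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    @property
    def n_regions(self) -> int:
        return self.timeseries.shape[1]


@dataclass
class MotionSummary:
    """Head-motion QC result for one subject."""

    subject_id: str
    max_translation: float  # mm; NaN when no motion trace was provided
    max_rotation: float  # degrees; NaN when no motion trace was provided
    excluded: bool


@dataclass
class RegionAtlasLabels:
    """Ordered region names defining node indices 0..N-1."""

    names: list[str]
    abbreviations: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.abbreviations):
            raise ValueError("names and abbreviations must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")

    def __len__(self) -> int:
        return len(self.names)


def cohort_n_regions(records: list[SubjectRecord]) -> int:
    """Number of regions shared by the cohort; raises on inconsistency."""
    if not records:
        raise ValueError("empty cohort")
    n = records[0].n_regions
    for rec in records[1:]:
        if rec.n_regions != n:
            raise ValueError(
                f"subject {rec.subject_id!r} has {rec.n_regions} regions "
                f"but the cohort has {n}"
            )
    return n
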
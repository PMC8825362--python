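"""Group comparison: AUC over the sparsity sweep, covariate residualization,
permutation tests and Bonferroni correction.

The comparison protocol: every metric curve (global metric, or one nodal
metric at one node) is collapsed to its trapezoidal area under the curve
across the sparsity sweep, giving one threshold-free number per subject.
Those numbers are residualized on age, gender and education by ordinary
least squares, and the residuals are compared between groups with a
pooled-variance two-sample t statistic whose null distribution is built by
randomly reassigning group labels (two-tailed, add-one permutation p).
Bonferroni correction is applied within each family of simultaneous tests
(the seven global metrics form one family; each nodal metric forms a
family of N node-level tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DIRECTION_PATIENT_GT = "patient_gt"
DIRECTION_PATIENT_LT = "patient_lt"
DIRECTION_NONE = "none"


def auc_over_sparsity(sparsities: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a metric curve across the threshold sweep."""
    sparsities = np.asarray(sparsities, dtype=float)
    values = np.asarray(values, dtype=float)
    if sparsities.ndim != 1 or sparsities.shape != values.shape:
        raise ValueError(
            f"sparsities {sparsities.shape} and values {values.shape} "
            "must be equal-length vectors"
        )
    if sparsities.size < 2:
        raise ValueError("need at least 2 sparsity points for an AUC")
    if np.any(np.diff(sparsities) <= 0):
        raise ValueError("sparsities must be strictly increasing")
    return float(np.trapezoid(values, sparsities))


def residualize(values: np.ndarray, covariates: np.ndarray,
                names: tuple[str, ...] = ("age", "gender", "education"),
                ) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept | covariates].

    ``values`` may be a vector (n,) or a matrix (n, k); each column is
    residualized on the same design.  Raises when the design is rank
    deficient, naming the offending columns.
    """
    values = np.asarray(values, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim != 2:
        raise ValueError("covariates must be a subjects x p matrix")
    n = covariates.shape[0]
    if values.shape[0] != n:
        raise ValueError("values and covariates disagree on subject count")
    if n < covariates.shape[1] + 2:
        raise ValueError(
            f"need at least {covariates.shape[1] + 2} subjects for "
            f"{covariates.shape[1]} covariates"
        )
    design = sm.add_constant(covariates, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = [
            names[j] if j < len(names) else f"covariate{j}"
            for j in range(covariates.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1))
            == np.linalg.matrix_rank(design)
        ]
        raise ValueError(f"rank-deficient covariate design; collinear "
                         f"columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _t_from_sums(s1, q1, n1, s2, q2, n2):
    """Pooled-variance two-sample t from per-group sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1 ** 2
    ss2 = q2 - n2 * m2 ** 2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (m1 - m2) / denom, 0.0), denom


def permutation_test_matrix(
    values: np.ndarray,
    is_group_a: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation two-sample t tests on each column of ``values``.

    Group A vs group B pooled-variance t, two-tailed p estimated over
    ``n_perm`` random label reassignments shared across columns, with the
    add-one correction p = (1 + #{|t*| >= |t|}) / (n_perm + 1).

    Returns (t_values, p_values), one per column.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    is_group_a = np.asarray(is_group_a, dtype=bool)
    n = is_group_a.size
    if values.shape[0] != n:
        raise ValueError("values rows must match group-label length")
    n1 = int(is_group_a.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    tot_s = values.sum(axis=0)
    tot_q = (values ** 2).sum(axis=0)
    a = is_group_a.astype(float)
    t_obs, denom_obs = _t_from_sums(
        a @ values, a @ values ** 2, n1,
        tot_s - a @ values, tot_q - a @ values ** 2, n2,
    )
    if np.any(denom_obs == 0):
        raise ValueError("zero pooled variance; permutation t undefined")

    # permuted label matrices: each row a random reassignment of n1 "A" labels
    order = rng.random((n_perm, n)).argsort(axis=1)
    perm_a = np.zeros((n_perm, n))
    np.put_along_axis(perm_a, order[:, :n1], 1.0, axis=1)
    s1 = perm_a @ values
    q1 = perm_a @ values ** 2
    t_perm, _ = _t_from_sums(s1, q1, n1, tot_s - s1, tot_q - q1, n2)
    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return np.asarray(t_obs, dtype=float), p


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sample permutation t test on one variable.

    Returns the observed pooled-variance t (group A minus group B) and the
    two-tailed add-one permutation p-value.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    values = np.concatenate([group_a, group_b])[:, None]
    labels = np.zeros(values.shape[0], dtype=bool)
    labels[: group_a.size] = True
    t, p = permutation_test_matrix(values, labels, n_perm=n_perm, seed=seed)
    return float(t[0]), float(p[0])


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance: p < alpha / m for a family of m tests."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p_values < alpha / p_values.size


@dataclass
class ComparisonFamily:
    """One family of simultaneous tests sharing a Bonferroni correction."""

    name: str
    table: pd.DataFrame  # columns: metric, node, group means, t, p, ...


def compare_family(
    auc: pd.DataFrame,
    is_patient: np.ndarray,
    covariates: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Compare patients vs controls on every column of an AUC table.

    ``auc`` is subjects x variables (columns named); all columns form one
    Bonferroni family.  Residualization on the covariates happens before
    label permutation.  Returns one row per variable.
    """
    vals = auc.to_numpy(dtype=float)
    resid = residualize(vals, covariates)
    t, p = permutation_test_matrix(resid, is_patient, n_perm=n_perm,
                                   seed=seed)
    sig = bonferroni(p, alpha=alpha)
    direction = np.where(
        sig, np.where(t > 0, DIRECTION_PATIENT_GT, DIRECTION_PATIENT_LT),
        DIRECTION_NONE,
    )
    pat = vals[is_patient].mean(axis=0)
    con = vals[~is_patient].mean(axis=0)
    return pd.DataFrame({
        "variable": list(auc.columns),
        "auc_patient_mean": pat,
        "auc_control_mean": con,
        "t_value": t,
        "p_perm": p,
        "p_bonferroni_threshold": alpha / len(auc.columns),
        "significant": sig,
        "direction": direction,
    })
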
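"""Model/Results objects tying the pipeline together.

:class:`ConnectomeGroupModel` is built from a cohort of subject records
(or directly from precomputed AUC tables); :meth:`fit` runs the
residualize-then-permute comparison for every metric family and returns a
:class:`ConnectomeGroupResults` with the full results tables, hub sets per
group, and a text summary.

Typical use::

    from roinet import simulate, model

    cohort = simulate.simulate_cohort(simulate.SimulationConfig(seed=7))
    mdl = model.ConnectomeGroupModel.from_cohort(cohort, seed=7)
    res = mdl.fit(n_perm=10000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity, inference, metrics
from .types import COVARIATE_NAMES, GROUP_PATIENT, SubjectRecord


def _curves_to_auc(table: pd.DataFrame, value_cols: tuple[str, ...],
                   subject_order: list[str],
                   by_node: bool) -> dict[str, pd.DataFrame]:
    """Collapse long-format metric tables to per-subject AUC tables.

    Returns ``{metric: DataFrame}``; columns are metric names (global) or
    node indices (nodal), rows follow ``subject_order``.
    """
    out: dict[str, pd.DataFrame] = {}
    if by_node:
        for m in value_cols:
            wide = table.pivot_table(index=["subject_id", "node"],
                                     columns="sparsity", values=m,
                                     sort=True)
            sparsities = wide.columns.to_numpy(dtype=float)
            auc = np.trapezoid(wide.to_numpy(), sparsities, axis=1)
            df = pd.DataFrame(
                auc.reshape(-1),
                index=wide.index,
                columns=["auc"],
            )["auc"].unstack("node")
            out[m] = df.loc[subject_order]
    else:
        for m in value_cols:
            wide = table.pivot_table(index="subject_id", columns="sparsity",
                                     values=m, sort=True)
            sparsities = wide.columns.to_numpy(dtype=float)
            auc = np.trapezoid(wide.to_numpy(), sparsities, axis=1)
            out[m] = pd.DataFrame({m: auc}, index=wide.index
                                  ).loc[subject_order]
    return out


class ConnectomeGroupModel:
    """Two-group comparison of connectome metrics, AUC over the sweep.

    Parameters
    ----------
    global_auc : DataFrame or None
        Subjects x 7 table of global-metric AUCs (columns Cp..sigma).
    nodal_auc : dict of {metric: DataFrame}
        Each value a subjects x N table of per-node AUCs.
    is_patient : boolean array over subjects (row order of the tables).
    covariates : DataFrame with columns age, gender, education.
    """

    def __init__(self, global_auc: pd.DataFrame | None,
                 nodal_auc: dict[str, pd.DataFrame],
                 is_patient: np.ndarray,
                 covariates: pd.DataFrame,
                 global_table: pd.DataFrame | None = None,
                 nodal_table: pd.DataFrame | None = None):
        self.global_auc = global_auc
        self.nodal_auc = dict(nodal_auc)
        self.is_patient = np.asarray(is_patient, dtype=bool)
        self.covariates = covariates.reset_index(drop=True)
        self.global_table = global_table
        self.nodal_table = nodal_table
        n = self.is_patient.size
        for name, tab in self.nodal_auc.items():
            if tab.shape[0] != n:
                raise ValueError(f"nodal AUC table {name!r} has "
                                 f"{tab.shape[0]} rows for {n} subjects")
        if global_auc is not None and global_auc.shape[0] != n:
            raise ValueError("global AUC table row count mismatch")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate row count mismatch")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        records: list[SubjectRecord],
        sparsities: tuple[float, ...] = connectivity.DEFAULT_SPARSITIES,
        rank: str = connectivity.RANK_SIGNED,
        include_global: bool = True,
        n_random: int = 100,
        seed: int | None = None,
    ) -> "ConnectomeGroupModel":
        """Run connectivity -> thresholding -> metrics for a whole cohort.

        ``n_random`` sets the degree-preserving reference ensemble size
        behind gamma/lambda/sigma; ``seed`` makes those ensembles (the only
        stochastic step) reproducible.  ``include_global=False`` skips the
        global family entirely, which avoids the reference ensembles and is
        much faster when only nodal inference is needed.
        """
        stacks = [
            connectivity.build_graph_stack(
                connectivity.pearson_matrix(rec), sparsities, rank=rank)
            for rec in records
        ]
        nodal_tab = metrics.nodal_metric_table(stacks)
        global_tab = None
        if include_global:
            global_tab = metrics.global_metric_table(
                stacks, n_random=n_random, seed=seed)
        return cls.from_metric_tables(
            records, global_table=global_tab, nodal_table=nodal_tab)

    @classmethod
    def from_metric_tables(
        cls,
        records: list[SubjectRecord],
        global_table: pd.DataFrame | None,
        nodal_table: pd.DataFrame | None,
    ) -> "ConnectomeGroupModel":
        """Build the model from precomputed long-format metric tables."""
        order = [rec.subject_id for rec in records]
        is_patient = np.array([rec.group == GROUP_PATIENT for rec in records])
        covariates = pd.DataFrame(
            [{k: rec.covariates[k] for k in COVARIATE_NAMES}
             for rec in records]
        )
        global_auc = None
        if global_table is not None:
            parts = _curves_to_auc(global_table,
                                   metrics.GLOBAL_METRIC_NAMES, order,
                                   by_node=False)
            global_auc = pd.concat(parts.values(), axis=1)
        nodal_auc = {}
        if nodal_table is not None:
            nodal_auc = _curves_to_auc(nodal_table,
                                       metrics.NODAL_METRIC_NAMES, order,
                                       by_node=True)
        return cls(global_auc, nodal_auc, is_patient, covariates,
                   global_table=global_table, nodal_table=nodal_table)

    # -- estimation -------------------------------------------------------

    def fit(self, n_perm: int = 10000, alpha: float = 0.05,
            seed: int | None = None,
            nodal_family: str = "per_metric") -> "ConnectomeGroupResults":
        """Residualize AUCs on covariates and permutation-test each family.

        ``nodal_family`` controls the Bonferroni family for nodal tests:
        ``"per_metric"`` corrects each nodal metric over its N nodes
        (m = N); ``"pooled"`` corrects over all nodal tests at once
        (m = 3N).
        """
        if nodal_family not in ("per_metric", "pooled"):
            raise ValueError("nodal_family must be 'per_metric' or 'pooled'")
        rng = np.random.default_rng(seed)
        cov = self.covariates.to_numpy(dtype=float)
        families: list[pd.DataFrame] = []

        if self.global_auc is not None:
            tab = inference.compare_family(
                self.global_auc, self.is_patient, cov,
                n_perm=n_perm, alpha=alpha, seed=rng)
            tab.insert(0, "family", "global")
            tab.insert(1, "metric", tab["variable"])
            tab.insert(2, "node", -1)
            families.append(tab.drop(columns="variable"))

        if self.nodal_auc:
            if nodal_family == "pooled":
                joined = pd.concat(
                    {m: t for m, t in self.nodal_auc.items()}, axis=1)
                tab = inference.compare_family(
                    joined, self.is_patient, cov,
                    n_perm=n_perm, alpha=alpha, seed=rng)
                tab.insert(0, "family", "nodal")
                tab.insert(1, "metric", [v[0] for v in tab["variable"]])
                tab.insert(2, "node", [int(v[1]) for v in tab["variable"]])
                families.append(tab.drop(columns="variable"))
            else:
                for m, t in self.nodal_auc.items():
                    tab = inference.compare_family(
                        t, self.is_patient, cov,
                        n_perm=n_perm, alpha=alpha, seed=rng)
                    tab.insert(0, "family", m)
                    tab.insert(1, "metric", m)
                    tab.insert(2, "node", tab["variable"].astype(int))
                    families.append(tab.drop(columns="variable"))

        comparisons = pd.concat(families, ignore_index=True)
        return ConnectomeGroupResults(
            model=self, comparisons=comparisons, alpha=alpha,
            n_perm=n_perm, nodal_family=nodal_family)

    # -- presentation -----------------------------------------------------

    def plot_global_curves(self, ax=None):
        """Group mean +/- SE of each global metric across the sweep."""
        if self.global_table is None:
            raise ValueError("model was built without global metric curves")
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(2, 4, figsize=(14, 6))
            axes = axes.ravel()
        else:
            axes = np.atleast_1d(ax)
        tab = self.global_table.copy()
        pat_ids = set()
        # recover grouping from row order of the AUC covariate table
        subj = tab["subject_id"].unique()
        for sid, isp in zip(subj, self.is_patient):
            if isp:
                pat_ids.add(sid)
        tab["group"] = np.where(tab["subject_id"].isin(pat_ids),
                                "patient", "control")
        for k, m in enumerate(metrics.GLOBAL_METRIC_NAMES):
            if k >= len(axes):
                break
            for grp, sub in tab.groupby("group"):
                agg = sub.groupby("sparsity")[m].agg(["mean", "sem"])
                axes[k].errorbar(agg.index, agg["mean"], yerr=agg["sem"],
                                 label=grp, capsize=2)
            axes[k].set_title(m)
            axes[k].set_xlabel("sparsity")
        axes[0].legend()
        return axes


@dataclass
class ConnectomeGroupResults:
    """Fitted group comparison: full tables, hub sets, and a summary."""

    model: ConnectomeGroupModel
    comparisons: pd.DataFrame
    alpha: float
    n_perm: int
    nodal_family: str
    _hubs: dict = field(default_factory=dict, repr=False)

    def significant(self, family: str | None = None) -> pd.DataFrame:
        tab = self.comparisons
        if family is not None:
            tab = tab[tab["family"] == family]
        return tab[tab["significant"]].reset_index(drop=True)

    def significant_nodes(self, metric: str = "NBi") -> list[int]:
        tab = self.comparisons
        hit = tab[(tab["metric"] == metric) & tab["significant"]
                  & (tab["node"] >= 0)]
        return sorted(int(i) for i in hit["node"])

    def hub_sets(self) -> dict[tuple[str, str], metrics.HubSet]:
        """Hubs per (group, nodal metric) from group-mean nodal AUCs.

        A node is a hub when its group-averaged AUC exceeds the network
        mean by more than one standard deviation.
        """
        if self._hubs:
            return self._hubs
        out: dict[tuple[str, str], metrics.HubSet] = {}
        for m, tab in self.model.nodal_auc.items():
            vals = tab.to_numpy(dtype=float)
            for grp, mask in (("patient", self.model.is_patient),
                              ("control", ~self.model.is_patient)):
                mean_per_node = vals[mask].mean(axis=0)
                out[(grp, m)] = metrics.identify_hubs(mean_per_node,
                                                      metric_name=m)
        self._hubs = out
        return out

    def hub_table(self) -> pd.DataFrame:
        rows = []
        for (grp, m), hs in self.hub_sets().items():
            for node in hs.hub_nodes:
                rows.append({"group": grp, "metric": m, "node": node,
                             "threshold": hs.threshold})
        return pd.DataFrame(rows,
                            columns=["group", "metric", "node", "threshold"])

    def summary(self) -> str:
        lines = [
            "Connectome group comparison (patient vs control)",
            f"  subjects: {int(self.model.is_patient.sum())} patients, "
            f"{int((~self.model.is_patient).sum())} controls",
            f"  permutations: {self.n_perm}; alpha: {self.alpha} "
            f"(Bonferroni per family, nodal family = {self.nodal_family})",
            "",
        ]
        glob = self.comparisons[self.comparisons["family"] == "global"]
        if len(glob):
            lines.append("Global metrics (AUC over sparsity):")
            lines.append(glob.drop(columns=["family", "node"])
                         .to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}"))
            lines.append("")
        nod = self.comparisons[(self.comparisons["node"] >= 0)]
        if len(nod):
            n_sig = int(nod["significant"].sum())
            lines.append(f"Nodal tests: {len(nod)} total, "
                         f"{n_sig} significant after Bonferroni")
            if n_sig:
                lines.append(nod[nod["significant"]]
                             .drop(columns=["family"])
                             .to_string(index=False,
                                        float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_nodal_t(self, metric: str = "NBi", ax=None):
        """Per-node t statistics with the Bonferroni-significant ones marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        tab = self.comparisons
        tab = tab[(tab["metric"] == metric) & (tab["node"] >= 0)]
        ax.bar(tab["node"], tab["t_value"],
               color=np.where(tab["significant"], "crimson", "steelblue"))
        ax.set_xlabel("node")
        ax.set_ylabel(f"t ({metric} AUC)")
        return ax


def compare_groups(records: list[SubjectRecord],
                   sparsities=connectivity.DEFAULT_SPARSITIES,
                   include_global: bool = True,
                   n_random: int = 100,
                   n_perm: int = 10000,
                   alpha: float = 0.05,
                   seed: int | None = None,
                   rank: str = connectivity.RANK_SIGNED,
                   nodal_family: str = "per_metric") -> ConnectomeGroupResults:
    """One-call pipeline: cohort records -> fitted group comparison."""
    mdl = ConnectomeGroupModel.from_cohort(
        records, sparsities=sparsities, rank=rank,
        include_global=include_global, n_random=n_random, seed=seed)
    return mdl.fit(n_perm=n_perm, alpha=alpha, seed=seed,
                   nodal_family=nodal_family)
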
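"""Per-subject metric curves across the sparsity grid and their AUC summary.

For each subject the binarized network at every grid sparsity yields global
metrics (Cp, Lp, Eglob, Eloc and the normalized gamma/lambda/sigma) and the
three nodal centralities per region. Each curve is then collapsed to a
single area-under-curve (AUC) number, giving one row per subject for the
group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, SparsityGrid, sparsity_sweep
from .metrics import distance_matrix, global_metrics, nodal_metrics
from .nulls import normalized_small_world
from .stats import metric_auc

__all__ = ["MetricCurves", "compute_curves", "global_auc_table", "nodal_auc_table"]

GLOBAL_COLUMNS = ("cp", "lp", "e_glob", "e_loc", "gamma", "lam", "sigma")
NODAL_COLUMNS = ("degree", "nodal_efficiency", "betweenness")


@dataclass(frozen=True)
class MetricCurves:
    """All metric values of one subject across the sparsity grid.

    ``global_curves`` has one row per sparsity and one column per global
    metric; ``nodal_curves[metric]`` has one row per sparsity and one column
    per region.
    """

    subject_id: str
    grid: SparsityGrid
    global_curves: pd.DataFrame
    nodal_curves: dict[str, pd.DataFrame]

    def global_auc(self) -> pd.Series:
        return pd.Series(
            {m: metric_auc(self.global_curves[m].to_numpy(), self.grid) for m in self.global_curves},
            name=self.subject_id,
        )

    def nodal_auc(self) -> pd.Series:
        vals = {}
        for metric, df in self.nodal_curves.items():
            for region in df.columns:
                vals[f"{metric}:{region}"] = metric_auc(df[region].to_numpy(), self.grid)
        return pd.Series(vals, name=self.subject_id)


def compute_curves(
    conn: ConnectivityMatrix,
    grid: SparsityGrid,
    subject_id: str = "",
    n_rand: int = 100,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
    with_small_world: bool = True,
) -> MetricCurves:
    """Sweep the grid and evaluate every metric at each sparsity.

    ``n_rand`` degree-preserving surrogates per sparsity feed the normalized
    gamma/lambda/sigma; set ``with_small_world=False`` to skip them (the
    columns are then NaN).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    graphs = sparsity_sweep(conn, grid)
    g_rows = []
    nodal = {m: [] for m in NODAL_COLUMNS}
    for g in graphs:
        dist = distance_matrix(g)
        gm = global_metrics(g, dist)
        row = {"cp": gm.cp, "lp": gm.lp, "e_glob": gm.e_glob, "e_loc": gm.e_loc,
               "gamma": np.nan, "lam": np.nan, "sigma": np.nan}
        if with_small_world:
            try:
                sw = normalized_small_world(
                    g, n_rand=n_rand, seed=rng, n_swaps_per_edge=n_swaps_per_edge
                )
                row.update(gamma=sw.gamma, lam=sw.lam, sigma=sw.sigma)
            except ValueError:
                # degenerate null (zero clustering in every surrogate); the
                # normalized metrics are undefined at this sparsity
                pass
        g_rows.append(row)
        nm = nodal_metrics(g, dist)
        nodal["degree"].append(nm.degree.astype(float))
        nodal["nodal_efficiency"].append(nm.nodal_efficiency)
        nodal["betweenness"].append(nm.betweenness)
    idx = pd.Index(grid.values, name="sparsity")
    return MetricCurves(
        subject_id=subject_id,
        grid=grid,
        global_curves=pd.DataFrame(g_rows, index=idx, columns=list(GLOBAL_COLUMNS)),
        nodal_curves={
            m: pd.DataFrame(np.vstack(v), index=idx, columns=list(conn.region_names))
            for m, v in nodal.items()
        },
    )


def global_auc_table(curves: list[MetricCurves], with_small_world: bool = True) -> pd.DataFrame:
    """One row per subject, one column per global metric AUC."""
    df = pd.DataFrame([c.global_auc() for c in curves])
    if not with_small_world:
        df = df.drop(columns=["gamma", "lam", "sigma"])
    return df


def nodal_auc_table(curves: list[MetricCurves]) -> pd.DataFrame:
    """One row per subject, one column per (metric, region) AUC."""
    return pd.DataFrame([c.nodal_auc() for c in curves])
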
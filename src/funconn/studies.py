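"""Simulation studies validating the pipeline's statistical behavior.

Three self-contained experiments, each run on synthetic cohorts with known
ground truth:

- :func:`null_calibration` — false-positive control: on cohorts with *no*
  group difference, the edge-wise, nodal and global FDR pipelines should
  reject (almost) nothing.
- :func:`planted_recovery` — power: cohorts with a few planted edge-level
  correlation differences; the edge-wise test should recover all of them.
- :func:`correlation_recovery` — scores generated with a nonzero slope on a
  region's nodal-metric AUC should be flagged by the behavior correlation,
  and slope-0 scores should not.

The studies run at a scaled-down problem size (20 regions, 7-point sparsity
grid, 6 null surrogates) so a full calibration fits in minutes on one CPU;
every function takes explicit seeds and is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import SparsityGrid, correlation_matrix
from .curves import compute_curves, nodal_auc_table, global_auc_table
from .stats import (
    SubjectTable,
    behavior_correlation,
    edgewise_group_test,
    global_group_test,
    nodal_group_test,
)
from .synthetic import (
    CohortConfig,
    ScoreSpec,
    SyntheticCohort,
    _table1_score_model,
    make_cohort,
)

__all__ = [
    "STUDY_GRID",
    "STUDY_PLANTED_EDGES",
    "cohort_tables",
    "study_config",
    "null_calibration",
    "planted_recovery",
    "correlation_recovery",
]

#: Sparsity grid used by the calibration studies (same bounds as the
#: analysis default, coarser step so the sweep stays cheap).
STUDY_GRID = SparsityGrid(0.10, 0.34, 0.04)

#: Three cross-module planted edges at |delta| = 0.4 (modules of 5 regions).
STUDY_PLANTED_EDGES = ((0, 7, 0.4), (5, 12, 0.4), (10, 19, -0.4))


def study_config(
    seed: int,
    planted_edges: tuple = (),
    score_model: dict[str, ScoreSpec] | None = None,
) -> CohortConfig:
    """The scaled study cohort: 17 vs 16 subjects, 20 regions in four
    modules, 210 timepoints at TR = 2 s."""
    return CohortConfig(
        n_group_a=17,
        n_group_b=16,
        n_regions=20,
        n_timepoints=210,
        module_sizes=(5, 5, 5, 5),
        planted_edges=planted_edges,
        score_model=score_model or {},
        score_grid=(STUDY_GRID.s_min, STUDY_GRID.s_max, STUDY_GRID.step),
        seed=seed,
    )


def cohort_tables(cohort: SyntheticCohort):
    """(per-subject connectivity dict, SubjectTable) from a synthetic cohort."""
    conns = {
        s.subject_id: correlation_matrix(s.timeseries) for s in cohort.subjects
    }
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "sex": s.sex,
            "education": s.education,
            **s.scores,
        }
        for s in cohort.subjects
    ]
    return conns, SubjectTable(pd.DataFrame(rows))


def _cohort_auc_tables(cohort, grid, n_rand, with_small_world=True):
    conns, subjects = cohort_tables(cohort)
    curves = []
    for k, s in enumerate(cohort.subjects):
        rng = np.random.default_rng([cohort.config.seed, k])
        curves.append(
            compute_curves(
                conns[s.subject_id], grid, subject_id=s.subject_id,
                n_rand=n_rand, seed=rng, with_small_world=with_small_world,
            )
        )
    g_auc = global_auc_table(curves, with_small_world=with_small_world)
    n_auc = nodal_auc_table(curves).reset_index(drop=True)
    return conns, subjects, g_auc.reset_index(drop=True), n_auc


def null_calibration(
    n_replicates: int = 20,
    base_seed: int = 5000,
    n_rand: int = 6,
    grid: SparsityGrid = STUDY_GRID,
    q: float = 0.05,
) -> pd.DataFrame:
    """False-positive counts of all three FDR pipelines on null cohorts.

    One row per replicate: significant edges (of 190 pairs), abnormal
    regions flagged by the nodal test, and significant global-metric AUCs.
    """
    rows = []
    for rep in range(n_replicates):
        seed = base_seed + 17 * rep
        cohort = make_cohort(study_config(seed))
        conns, subjects, g_auc, n_auc = _cohort_auc_tables(cohort, grid, n_rand)
        edges = edgewise_group_test(conns, subjects, q=q)
        nodal, abnormal = nodal_group_test(n_auc, subjects, q=q)
        glob = global_group_test(g_auc, subjects, q=q)
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "n_edge_rejections": int(edges["significant"].sum()),
                "n_abnormal_regions": len(abnormal),
                "n_global_rejections": int(glob["significant"].sum()),
            }
        )
    return pd.DataFrame(rows)


def planted_recovery(
    n_replicates: int = 20,
    base_seed: int = 7000,
    planted_edges: tuple = STUDY_PLANTED_EDGES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise recovery of planted group differences.

    One row per replicate: how many of the planted edges were flagged and
    how many non-planted pairs were flagged alongside them.
    """
    rows = []
    for rep in range(n_replicates):
        seed = base_seed + 17 * rep
        cohort = make_cohort(study_config(seed, planted_edges=planted_edges))
        conns, subjects = cohort_tables(cohort)
        edges = edgewise_group_test(conns, subjects, q=q)
        names = cohort.config.region_names
        truth = {
            (names[min(i, j)], names[max(i, j)]) for i, j, _ in planted_edges
        }
        hits = {
            (r.region_a, r.region_b)
            for r in edges.loc[edges["significant"]].itertuples()
        }
        rows.append(
            {
                "replicate": rep,
                "seed": seed,
                "n_planted": len(truth),
                "n_recovered": len(truth & hits),
                "n_false": len(hits - truth),
            }
        )
    return pd.DataFrame(rows)


def correlation_recovery(
    seeds: tuple[int, ...],
    slope: float,
    metric: str = "nodal_efficiency",
    region: int = 5,
    noise_sd: float = 1.0,
    grid: SparsityGrid = STUDY_GRID,
    q: float = 0.05,
) -> pd.DataFrame:
    """Detection of a planted score–metric coupling by the behavior test.

    The YIAS score is generated with the given slope on one region's
    nodal-metric AUC; one row per seed reports whether that exact
    (region, metric, YIAS) triple was significant, its correlation, and how
    many *other* triples in the FDR family were flagged.
    """
    score_model = dict(_table1_score_model())
    score_model["YIAS"] = ScoreSpec(62.4, 37.0, noise_sd, slope, metric, region)
    region_name = f"R{region:03d}"
    rows = []
    for seed in seeds:
        cohort = make_cohort(study_config(seed, score_model=score_model))
        _, subjects, _, n_auc = _cohort_auc_tables(
            cohort, grid, n_rand=0, with_small_world=False
        )
        res = behavior_correlation(n_auc, subjects, regions=[region_name], q=q)
        probe = res[(res["metric"] == metric) & (res["score"] == "YIAS")]
        detected = bool(probe["significant"].iloc[0])
        rows.append(
            {
                "seed": seed,
                "slope": slope,
                "detected": detected,
                "r": float(probe["r"].iloc[0]),
                "n_other_rejections": int(res["significant"].sum()) - detected,
            }
        )
    return pd.DataFrame(rows)
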
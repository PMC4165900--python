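"""End-to-end orchestration: cohort on disk -> result tables on disk.

Stage order mirrors the analysis design: signal cleaning, connectivity,
edge-wise group tests, sparsity sweep with global/nodal metrics and
degree-preserving nulls, AUC summarization, covariate-adjusted group tests
with FDR, and behavior correlation within the patient group. A JSON
manifest records every default, seed and decision flag of the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import SparsityGrid, correlation_matrix
from .curves import compute_curves, global_auc_table, nodal_auc_table
from .io import read_motion, read_subjects, read_timeseries, write_connectivity
from .preprocess import clean
from .stats import (
    SubjectTable,
    behavior_correlation,
    demographic_table,
    edgewise_group_test,
    global_group_test,
    nodal_group_test,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from a YAML file."""

    data_dir: str = "."
    out_dir: str = "results"
    subjects_file: str = "subjects.tsv"
    patient_group: str = "IAD"
    tr_seconds: float = 2.0
    # preprocessing
    preprocess: bool = True
    use_motion: bool = True
    fd_threshold_mm: float = 0.5
    min_frames: int = 100
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    # network construction
    s_min: float = 0.10
    s_max: float = 0.34
    s_step: float = 0.01
    absolute_threshold: bool = False
    # null models
    n_rand: int = 100
    n_swaps_per_edge: int = 10
    with_small_world: bool = True
    # statistics
    q: float = 0.05
    test: str = "welch"  # or "pooled"
    fisher_z: bool = True
    adjust_covariates: bool = True
    seed: int = 0

    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.s_step)

    def validate(self) -> None:
        self.grid()  # raises on a bad sparsity range
        if self.test not in ("welch", "pooled"):
            raise ValueError(f"unknown test variant {self.test!r}")
        if not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data directory not found: {self.data_dir}")
        subj = Path(self.data_dir) / self.subjects_file
        if not subj.exists():
            raise FileNotFoundError(f"subject table not found: {subj}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the result tables plus a manifest.

    Returns the output directory. All randomness derives from
    ``config.seed``; rerunning with the same config yields byte-identical
    outputs.
    """
    config.validate()
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_subjects(data_dir / config.subjects_file, config.patient_group)
    ids = subjects.data["subject_id"].tolist()
    log.info("loaded %d subjects (%s vs %s)", len(ids), *subjects.groups)

    conns = {}
    kept_counts = {}
    for sid in ids:
        ts_path = data_dir / f"subject_{sid}_ts.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"missing time-series file for subject {sid}: {ts_path}")
        ts = read_timeseries(ts_path, tr_seconds=config.tr_seconds, subject_id=sid)
        if config.preprocess:
            motion = None
            mot_path = data_dir / f"subject_{sid}_motion.tsv"
            if config.use_motion and mot_path.exists():
                motion = read_motion(mot_path, tr_seconds=config.tr_seconds)
                if motion.n_timepoints != ts.n_timepoints:
                    raise ValueError(
                        f"subject {sid}: motion has {motion.n_timepoints} frames, "
                        f"time series has {ts.n_timepoints}"
                    )
            ts, kept = clean(
                ts, motion=motion,
                fd_threshold_mm=config.fd_threshold_mm,
                low_hz=config.bandpass_low_hz, high_hz=config.bandpass_high_hz,
                min_frames=config.min_frames,
            )
            kept_counts[sid] = int(kept.size)
        conns[sid] = correlation_matrix(ts)
        write_connectivity(conns[sid], out / f"connectivity_{sid}.tsv")

    # demographics (Table-1 style) and edge-wise tests
    demo = demographic_table(subjects, test=config.test)
    demo.to_csv(out / "demographics_results.tsv", sep="\t", index=False, float_format="%.6g")
    edges = edgewise_group_test(
        conns, subjects, q=config.q, fisher_z=config.fisher_z,
        test=config.test, adjust_covariates=config.adjust_covariates,
    )
    edges.to_csv(out / "edges_results.tsv", sep="\t", index=False, float_format="%.6g")

    # sparsity sweep, metric curves, AUC
    grid = config.grid()
    curves = []
    for k, sid in enumerate(ids):
        curves.append(
            compute_curves(
                conns[sid], grid, subject_id=sid,
                n_rand=config.n_rand, seed=config.seed + 1000 + k,
                n_swaps_per_edge=config.n_swaps_per_edge,
                with_small_world=config.with_small_world,
            )
        )
        curves[-1].global_curves.to_csv(
            out / f"global_curves_{sid}.tsv", sep="\t", float_format="%.10g"
        )
    g_auc = global_auc_table(curves, with_small_world=config.with_small_world)
    n_auc = nodal_auc_table(curves)
    g_auc.to_csv(out / "global_auc.tsv", sep="\t", float_format="%.10g")
    n_auc.to_csv(out / "nodal_auc.tsv", sep="\t", float_format="%.10g")

    glob = global_group_test(g_auc.reset_index(drop=True), subjects, q=config.q,
                             test=config.test, adjust_covariates=config.adjust_covariates)
    glob.to_csv(out / "global_results.tsv", sep="\t", index=False, float_format="%.6g")
    nodal, abnormal = nodal_group_test(n_auc.reset_index(drop=True), subjects, q=config.q,
                                       test=config.test,
                                       adjust_covariates=config.adjust_covariates)
    nodal.to_csv(out / "nodal_results.tsv", sep="\t", index=False, float_format="%.6g")

    try:
        # plain pairwise Pearson within patients; covariate adjustment applies
        # to the group AUC tests, not the behavior correlations
        behav = behavior_correlation(n_auc.reset_index(drop=True), subjects, abnormal,
                                     q=config.q)
    except ValueError as e:  # e.g. fewer than 3 patients
        log.warning("behavior correlation skipped: %s", e)
        behav = pd.DataFrame(
            columns=["region", "metric", "score", "r", "df", "p", "q", "significant"]
        )
    behav.to_csv(out / "behavior_results.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "funconn_version": __version__,
        "config": dataclasses.asdict(config),
        "sparsity_grid": list(grid.values),
        "n_subjects": len(ids),
        "groups": list(subjects.groups),
        "kept_frames": kept_counts,
        "abnormal_regions": abnormal,
        "conventions": {
            "lp_disconnected": "finite pairs only",
            "betweenness": "normalized by (N-1)(N-2)/2",
            "edge_ranking": "signed r" if not config.absolute_threshold else "absolute r",
            "edge_test_scale": "fisher z" if config.fisher_z else "raw r",
            "fdr_families": {
                "edges": "all pairs",
                "nodal": "per metric across regions",
                "behavior": "all (region, metric, score) triples",
            },
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s (%d abnormal regions)", out, len(abnormal))
    return out
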
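"""Synthetic resting-state cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two demographic groups (17 patients vs 16 controls by default),
region time series drawn from a modular correlation structure that yields
small-world binarized graphs, a small set of planted group-different edges,
head-motion traces with occasional spikes, and clinical scores whose
distributions match the study population (optionally coupled to a nodal
network metric so correlation-recovery can be tested).

Ground truth (true covariances, planted edges, per-subject metric values
used for score generation) is carried alongside the data and written to a
separate ``ground_truth.json``; analysis stages never consume it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import SparsityGrid, binarize_at_sparsity, correlation_matrix
from .metrics import nodal_metrics
from .timeseries import MotionParams, RoiTimeSeries

__all__ = [
    "ScoreSpec",
    "GroupCovariates",
    "MotionModel",
    "CohortConfig",
    "Subject",
    "SyntheticCohort",
    "SCORE_NAMES",
    "default_config",
    "build_group_covariance",
    "simulate_timeseries",
    "make_cohort",
    "write_cohort",
]

SCORE_NAMES = ("YIAS", "BIS-11", "TMDS", "SDQ-P", "SDQ-C", "FAD")

NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


@dataclass(frozen=True)
class ScoreSpec:
    """Linear model for one clinical score.

    score = intercept(group) + slope * nodal_metric_auc(region) + N(0, noise_sd).

    ``metric`` names one of degree / nodal_efficiency / betweenness and
    ``region`` the (0-based) region index it is read from; the metric value
    is the subject's AUC of that nodal metric over ``CohortConfig.score_grid``,
    the same summary the analysis stage correlates with scores. With slope 0
    the metric is irrelevant and the score is pure group-shifted noise.
    """

    intercept_a: float
    intercept_b: float
    noise_sd: float
    slope: float = 0.0
    metric: str = "nodal_efficiency"
    region: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.metric not in NODAL_METRIC_NAMES:
            raise ValueError(f"unknown nodal metric {self.metric!r}")


@dataclass(frozen=True)
class GroupCovariates:
    """Demographic distributions for one group."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    p_female: float


@dataclass(frozen=True)
class MotionModel:
    """Frame-to-frame motion jitter plus occasional large spikes."""

    jitter_sd_mm: float = 0.02
    jitter_sd_rad: float = 0.0002
    spike_probability: float = 0.02
    spike_magnitude_mm: float = 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Subjects 0..n_group_a-1 belong to group A (patients), the rest to
    group B (controls). ``module_sizes`` partitions the regions into
    consecutive blocks with correlation ``r_within`` inside a block and
    ``r_between`` across blocks; ``planted_edges`` lists (i, j, delta)
    triples whose correlation is shifted by delta in group B's covariance.
    One master ``seed`` governs everything; subject k draws from
    ``seed + k`` so adding subjects never reshuffles existing ones.
    """

    n_group_a: int = 17
    n_group_b: int = 16
    n_regions: int = 90
    n_timepoints: int = 210
    tr_seconds: float = 2.0
    module_sizes: tuple[int, ...] = ()
    r_within: float = 0.4
    r_between: float = 0.08
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    score_model: dict[str, ScoreSpec] = field(default_factory=dict)
    covariates_a: GroupCovariates = GroupCovariates(17.3, 2.6, 10.8, 2.6, 2 / 17)
    covariates_b: GroupCovariates = GroupCovariates(17.7, 2.5, 11.6, 2.8, 2 / 16)
    motion_model: MotionModel = MotionModel()
    score_grid: tuple[float, float, float] = (0.10, 0.34, 0.04)
    group_labels: tuple[str, str] = ("IAD", "HC")
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(self.module_sizes) or (self.n_regions,)
        object.__setattr__(self, "module_sizes", sizes)
        if sum(sizes) != self.n_regions:
            raise ValueError("module_sizes must sum to n_regions")
        if any(s <= 0 for s in sizes):
            raise ValueError("module sizes must be positive")
        if not (abs(self.r_within) < 1 and abs(self.r_between) < 1):
            raise ValueError("|r_within| and |r_between| must be < 1")
        planted = tuple((int(i), int(j), float(d)) for i, j, d in self.planted_edges)
        object.__setattr__(self, "planted_edges", planted)
        seen = set()
        for i, j, _ in planted:
            if i == j or not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"planted edge ({i}, {j}) out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)
        if not self.score_model:
            object.__setattr__(self, "score_model", _table1_score_model())
        grid = tuple(float(v) for v in self.score_grid)
        object.__setattr__(self, "score_grid", grid)
        SparsityGrid(*grid)  # validate bounds and step
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups must be nonempty")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(f"R{i:03d}" for i in range(self.n_regions))

    @property
    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


def _table1_score_model() -> dict[str, ScoreSpec]:
    """Score distributions matching the study population (slope 0)."""
    rows = {
        "YIAS": (62.4, 37.0, 17.1),
        "BIS-11": (69.2, 66.8, 12.7),
        "TMDS": (126.5, 124.4, 23.2),
        "SDQ-P": (21.4, 16.5, 3.7),
        "SDQ-C": (37.3, 23.9, 10.7),
        "FAD": (151.4, 137.5, 20.1),
    }
    return {
        name: ScoreSpec(intercept_a=a, intercept_b=b, noise_sd=sd)
        for name, (a, b, sd) in rows.items()
    }


def default_config(seed: int = 0) -> CohortConfig:
    """The study-emulation defaults: 17 vs 16 subjects, 90 regions in six
    modules, 210 usable volumes at TR = 2 s, three planted cross-module
    edges with delta 0.4."""
    return CohortConfig(
        module_sizes=(15,) * 6,
        planted_edges=((0, 45, 0.4), (10, 55, 0.4), (20, 65, -0.4)),
        seed=seed,
    )


@dataclass(frozen=True)
class Subject:
    """One synthetic participant: data plus demographics."""

    subject_id: str
    group: str
    age: int
    sex: str  # "M" / "F"
    education: int
    scores: dict[str, float]
    timeseries: RoiTimeSeries
    motion: MotionParams


@dataclass(frozen=True)
class SyntheticCohort:
    """All subjects plus the ground-truth record (never fed to analysis)."""

    config: CohortConfig
    subjects: tuple[Subject, ...]
    ground_truth: dict


def build_group_covariance(config: CohortConfig, group: str) -> np.ndarray:
    """Modular correlation matrix for one group, repaired to positive-definite.

    Entries are ``r_within`` inside modules and ``r_between`` across; for
    group B the planted edges are additionally shifted by their delta. If the
    smallest eigenvalue is <= 0, (|lambda_min| + 1e-6) is added to the
    diagonal and the matrix rescaled back to unit diagonal.
    """
    if group not in config.group_labels:
        raise ValueError(f"unknown group {group!r}")
    mod = config.module_assignment
    same = mod[:, None] == mod[None, :]
    cov = np.where(same, config.r_within, config.r_between).astype(np.float64)
    np.fill_diagonal(cov, 1.0)
    if group == config.group_labels[1]:
        for i, j, d in config.planted_edges:
            cov[i, j] += d
            cov[j, i] += d
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin <= 0:
        cov = cov + (abs(eigmin) + 1e-6) * np.eye(config.n_regions)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin <= 0:
        raise ValueError("positive-definite repair failed")
    return cov


def simulate_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    seed: int | np.random.Generator,
    tr_seconds: float = 2.0,
    region_names: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> RoiTimeSeries:
    """Draw T iid rows from a zero-mean multivariate normal with the given
    covariance (Cholesky sampling; deterministic for a fixed seed)."""
    cov = np.asarray(cov, dtype=np.float64)
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance must be positive-definite") from e
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    names = region_names or tuple(f"R{i:03d}" for i in range(cov.shape[0]))
    return RoiTimeSeries(
        values=z @ chol.T,
        tr_seconds=tr_seconds,
        region_names=names,
        subject_id=subject_id,
    )


def _simulate_motion(model: MotionModel, t: int, rng: np.random.Generator) -> MotionParams:
    vals = np.empty((t, 6))
    vals[:, :3] = rng.normal(0.0, model.jitter_sd_mm, size=(t, 3))
    vals[:, 3:] = rng.normal(0.0, model.jitter_sd_rad, size=(t, 3))
    spikes = rng.random(t) < model.spike_probability
    spikes[0] = False
    axis = rng.integers(0, 3, size=t)
    for f in np.flatnonzero(spikes):
        vals[f, axis[f]] += model.spike_magnitude_mm
    return MotionParams(values=vals, tr_seconds=2.0)


def _subject_nodal_auc(
    ts: RoiTimeSeries, spec: ScoreSpec, grid: SparsityGrid
) -> float:
    """The subject-level nodal-metric AUC a score is coupled to."""
    conn = correlation_matrix(ts)
    vals = []
    for s in grid.values:
        nm = nodal_metrics(binarize_at_sparsity(conn, s))
        vals.append(float(getattr(nm, spec.metric)[spec.region]))
    return float(np.trapezoid(vals, grid.values))


def make_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort (time series, motion, demographics, scores).

    Subject k is driven entirely by ``config.seed + k``. Scores are linear
    in the subject's own nodal-metric AUC, computed from the simulated
    series over ``score_grid``; the metric values used are recorded in the
    ground truth so recovery tests have a known target.
    """
    la, lb = config.group_labels
    cov = {la: build_group_covariance(config, la), lb: build_group_covariance(config, lb)}
    score_grid = SparsityGrid(*config.score_grid)
    n_total = config.n_group_a + config.n_group_b
    subjects = []
    metric_truth: dict[str, dict[str, float]] = {}
    needs_metric = {s.metric + f"@{s.region}" for s in config.score_model.values() if s.slope != 0}
    for k in range(n_total):
        rng = np.random.default_rng(config.seed + k)
        group = la if k < config.n_group_a else lb
        cv = config.covariates_a if group == la else config.covariates_b
        sid = f"sub-{k:03d}"
        ts = simulate_timeseries(
            cov[group], config.n_timepoints, rng,
            tr_seconds=config.tr_seconds,
            region_names=config.region_names, subject_id=sid,
        )
        motion = _simulate_motion(config.motion_model, config.n_timepoints, rng)
        age = int(np.clip(round(rng.normal(cv.age_mean, cv.age_sd)), 12, 24))
        education = int(np.clip(round(rng.normal(cv.education_mean, cv.education_sd)), 5, 18))
        sex = "F" if rng.random() < cv.p_female else "M"
        # nodal metrics are computed at most once per subject, lazily
        metric_cache: dict[tuple[str, int], float] = {}
        scores = {}
        truth_k: dict[str, float] = {}
        for name, spec in config.score_model.items():
            icpt = spec.intercept_a if group == la else spec.intercept_b
            val = icpt + rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else icpt
            if spec.slope != 0:
                key = (spec.metric, spec.region)
                if key not in metric_cache:
                    metric_cache[key] = _subject_nodal_auc(ts, spec, score_grid)
                val += spec.slope * metric_cache[key]
                truth_k[f"{spec.metric}@{spec.region}"] = metric_cache[key]
            scores[name] = float(val)
        if truth_k:
            metric_truth[sid] = truth_k
        subjects.append(Subject(sid, group, age, sex, education, scores, ts, motion))
    ground_truth = {
        "group_covariance": {g: c.tolist() for g, c in cov.items()},
        "planted_edges": [list(e) for e in config.planted_edges],
        "score_slopes": {n: s.slope for n, s in config.score_model.items()},
        "score_metric_values": metric_truth,
        "needs_metric": sorted(needs_metric),
    }
    return SyntheticCohort(config=config, subjects=tuple(subjects), ground_truth=ground_truth)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write the cohort as TSV files plus ground_truth.json.

    Per subject: ``subject_<id>_ts.tsv`` (T x N, region-name header) and
    ``subject_<id>_motion.tsv`` (T x 6); one ``subjects.tsv`` table; the
    ground truth in its own file that analysis stages must never read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        pd.DataFrame(s.timeseries.values, columns=list(s.timeseries.region_names)).to_csv(
            out / f"subject_{s.subject_id}_ts.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(
            s.motion.values,
            columns=["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"],
        ).to_csv(out / f"subject_{s.subject_id}_motion.tsv", sep="\t", index=False, float_format="%.10g")
        rows.append(
            {"subject_id": s.subject_id, "group": s.group, "age": s.age, "sex": s.sex,
             "education": s.education, **{n: round(v, 6) for n, v in s.scores.items()}}
        )
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
    with open(out / "cohort_config.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=1, sort_keys=True, default=list)
    return out
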
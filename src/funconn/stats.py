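"""Group-level statistics: AUC summaries, covariate removal, mass-univariate
tests with FDR correction, demographic tests, and metric-behavior correlation.

Every network quantity is first summarized per subject as the area under its
curve (AUC) across the sparsity grid, then adjusted for age, sex and
education (and their pairwise interactions) by multiple linear regression,
and finally compared between groups with Welch two-sample t-tests corrected
by Benjamini-Hochberg FDR. Edge-wise tests operate on Fisher z-transformed
correlations. Behavioral correlations are Pearson r between a patient's
adjusted nodal AUCs and clinical scores, within the patient group only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, SparsityGrid

__all__ = [
    "SubjectTable",
    "metric_auc",
    "residualize",
    "welch_ttest",
    "pooled_ttest",
    "chi_square_2x2",
    "bh_fdr",
    "edgewise_group_test",
    "nodal_group_test",
    "global_group_test",
    "behavior_correlation",
    "demographic_table",
    "SCORE_COLUMNS",
]

log = logging.getLogger(__name__)

SCORE_COLUMNS = ("YIAS", "BIS-11", "TMDS", "SDQ-P", "SDQ-C", "FAD")

GLOBAL_METRIC_COLUMNS = ("cp", "lp", "e_glob", "e_loc", "gamma", "lam", "sigma")
NODAL_METRIC_COLUMNS = ("degree", "nodal_efficiency", "betweenness")


@dataclass(frozen=True)
class SubjectTable:
    """Per-subject demographics and clinical scores.

    Wraps a DataFrame with columns subject_id, group, age, sex, education
    and the six score columns; rows are subjects.
    """

    data: pd.DataFrame
    patient_group: str = "IAD"

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "age", "sex", "education"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if self.data["group"].nunique() != 2:
            raise ValueError("subject table must contain exactly two groups")
        object.__setattr__(self, "data", self.data.reset_index(drop=True))

    @property
    def groups(self) -> tuple[str, str]:
        """(patient, control) labels."""
        labels = list(dict.fromkeys(self.data["group"]))
        if self.patient_group not in labels:
            raise ValueError(f"patient group {self.patient_group!r} not present")
        other = labels[0] if labels[1] == self.patient_group else labels[1]
        return self.patient_group, other

    def group_mask(self, group: str) -> np.ndarray:
        return (self.data["group"] == group).to_numpy()

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Covariate design: intercept, age, sex(0/1), education and the
        three pairwise interactions."""
        age = self.data["age"].to_numpy(float)
        sex = (self.data["sex"].astype(str).str.upper().str[0] == "F").to_numpy(float)
        edu = self.data["education"].to_numpy(float)
        cols = np.column_stack(
            (np.ones_like(age), age, sex, edu, age * sex, age * edu, sex * edu)
        )
        names = ["intercept", "age", "sex", "education", "age:sex", "age:education", "sex:education"]
        return cols, names


def metric_auc(curve: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a per-sparsity metric curve."""
    y = np.asarray(curve, dtype=np.float64)
    x = np.asarray(grid.values, dtype=np.float64)
    if y.shape[0] != x.shape[0]:
        raise ValueError("curve length must match the sparsity grid")
    if x.shape[0] < 2:
        raise ValueError("AUC needs at least two grid points")
    return float(np.trapezoid(y, x))


def _clean_design(x: np.ndarray, names: list[str], n_obs: int) -> np.ndarray:
    """Drop collinear columns (logged once) and check determinacy."""
    keep = _independent_columns(x)
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        log.debug("dropping collinear covariate column(s): %s", dropped)
        x = x[:, keep]
    if n_obs < x.shape[1] + 2:
        raise ValueError("under-determined covariate design")
    return x


def _clean_design_reduced(x: np.ndarray, names: list[str], n_obs: int) -> np.ndarray | None:
    """Like :func:`_clean_design` but shrinks the design for tiny cohorts.

    Interaction columns are dropped first, then the main covariates from the
    right; returns None (no adjustment possible beyond the mean) if even the
    intercept-plus-one-covariate design is under-determined.
    """
    for ncols in range(x.shape[1], 1, -1):
        try:
            return _clean_design(x[:, :ncols], names[:ncols], n_obs)
        except ValueError:
            continue
    log.warning("cohort too small for covariate adjustment; values left unadjusted")
    return None


def _residualize_against(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Least-squares residuals of y (vector or matrix of columns) against a
    full-rank design, with each column's mean restored."""
    y = np.asarray(y, dtype=np.float64)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta + y.mean(axis=0)


def residualize(y: np.ndarray, subjects: SubjectTable) -> np.ndarray:
    """Remove covariate effects from a per-subject vector, keeping the mean.

    Fits y on the covariate design (age, sex, education + interactions) by
    least squares and returns residuals plus the grand mean. Collinear design
    columns are dropped with a logged message.
    """
    y = np.asarray(y, dtype=np.float64)
    x, names = subjects.design_matrix()
    if y.shape[0] != x.shape[0]:
        raise ValueError("y length must match the subject table")
    x = _clean_design(x, names, y.shape[0])
    return _residualize_against(y, x)


def _independent_columns(x: np.ndarray) -> np.ndarray:
    """Greedy mask of linearly independent columns (first-come wins)."""
    keep = np.zeros(x.shape[1], dtype=bool)
    basis: list[np.ndarray] = []
    for j in range(x.shape[1]):
        cand = basis + [x[:, j]]
        if np.linalg.matrix_rank(np.column_stack(cand), tol=1e-8) == len(cand):
            basis.append(x[:, j])
            keep[j] = True
    return keep


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test, two-tailed.

    Each argument is either a 1-d sample or a summary triple
    (n, mean, sd). Returns (t, Welch-Satterthwaite df, p).
    """
    n1, m1, s1 = _summary(a)
    n2, m2, s2 = _summary(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pooled_ttest(a, b) -> tuple[float, float, float]:
    """Classic pooled-variance two-sample t-test (alternative to Welch)."""
    n1, m1, s1 = _summary(a)
    n2, m2, s2 = _summary(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0:
        raise ValueError("zero variance in both groups")
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(df), float(2.0 * sps.t.sf(abs(t), df))


def _summary(x) -> tuple[int, float, float]:
    if isinstance(x, tuple) and len(x) == 3:
        n, m, s = x
        return int(n), float(m), float(s)
    arr = np.asarray(x, dtype=np.float64)
    return arr.size, float(arr.mean()), float(arr.std(ddof=1))


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, rejection flags)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _group_welch_table(
    values: pd.DataFrame,
    subjects: SubjectTable,
    test: str = "welch",
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Residualize each column and Welch-test patient vs control.

    The covariate design is built once and all columns are residualized in a
    single least-squares solve.
    """
    patient, control = subjects.groups
    mask_p = subjects.group_mask(patient)
    mask_c = subjects.group_mask(control)
    ttest = welch_ttest if test == "welch" else pooled_ttest
    y = values.to_numpy(float)
    has_nan = np.isnan(y).any(axis=0)
    constant = np.zeros(y.shape[1], dtype=bool)
    constant[~has_nan] = np.ptp(y[:, ~has_nan], axis=0) == 0
    testable = ~(constant | has_nan)
    adj = y.copy()
    if adjust_covariates and testable.any():
        x, names = subjects.design_matrix()
        x = _clean_design_reduced(x, names, y.shape[0])
        if x is not None:
            adj[:, testable] = _residualize_against(y[:, testable], x)
    rows = []
    for j, col in enumerate(values.columns):
        if has_nan[j]:
            log.warning("unit %s has undefined values; not tested", col)
            rows.append((col, np.nan, np.nan, np.nan, "none"))
            continue
        if constant[j]:
            log.warning("unit %s constant across subjects; p set to 1", col)
            rows.append((col, 0.0, np.nan, 1.0, "none"))
            continue
        t, df, p = ttest(adj[mask_p, j], adj[mask_c, j])
        direction = "increased" if t > 0 else ("decreased" if t < 0 else "none")
        rows.append((col, t, df, p, direction))
    return pd.DataFrame(rows, columns=["unit", "t", "df", "p", "direction"])


def _attach_fdr(table: pd.DataFrame, q: float, by: str | None = None) -> pd.DataFrame:
    """Add q-values and significance flags, optionally per family column."""
    table = table.copy()
    table["q"] = np.nan
    table["significant"] = False
    groups = [table.index] if by is None else list(table.groupby(by).groups.values())
    for idx in groups:
        p = table.loc[idx, "p"].to_numpy()
        ok = ~np.isnan(p)  # untestable units are excluded from the family
        if not ok.any():
            continue
        qv, rej = bh_fdr(p[ok], q=q)
        sub = np.asarray(idx)[ok]
        table.loc[sub, "q"] = qv
        table.loc[sub, "significant"] = rej
    return table


def edgewise_group_test(
    conns: dict[str, ConnectivityMatrix],
    subjects: SubjectTable,
    q: float = 0.05,
    fisher_z: bool = True,
    test: str = "welch",
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Mass-univariate group test of every region pair's connectivity.

    Per pair: Fisher z-transform the correlations (variance stabilization,
    unless ``fisher_z=False``), remove covariate effects, Welch-test patient
    vs control, then BH-FDR across all pairs in a single family. Returns a
    tidy table with one row per pair.
    """
    order = subjects.data["subject_id"].tolist()
    mats = [conns[s] for s in order]
    names = mats[0].region_names
    n = mats[0].n_regions
    iu = np.triu_indices(n, k=1)
    r = np.stack([m.r_values[iu] for m in mats])  # subjects x pairs
    vals = np.arctanh(np.clip(r, -0.999999, 0.999999)) if fisher_z else r
    df_vals = pd.DataFrame(
        vals, columns=[f"{names[i]}--{names[j]}" for i, j in zip(*iu)]
    )
    table = _group_welch_table(df_vals, subjects, test=test, adjust_covariates=adjust_covariates)
    table = _attach_fdr(table, q)
    table[["region_a", "region_b"]] = table["unit"].str.split("--", expand=True)
    return table


def nodal_group_test(
    aucs: pd.DataFrame,
    subjects: SubjectTable,
    q: float = 0.05,
    test: str = "welch",
    adjust_covariates: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Group test of every (region, nodal metric) AUC.

    ``aucs`` columns are named ``<metric>:<region>`` for the three nodal
    metrics; rows follow the subject table. FDR is applied within each
    metric family across regions. A region is flagged abnormal when any of
    its three metrics is significant; the second return value lists them.
    """
    table = _group_welch_table(aucs, subjects, test=test, adjust_covariates=adjust_covariates)
    table[["metric", "region"]] = table["unit"].str.split(":", n=1, expand=True)
    table = _attach_fdr(table, q, by="metric")
    abnormal = sorted(table.loc[table["significant"], "region"].unique().tolist())
    return table, abnormal


def global_group_test(
    aucs: pd.DataFrame,
    subjects: SubjectTable,
    q: float = 0.05,
    test: str = "welch",
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Group test of the global-metric AUCs (Cp, Lp, Eglob, Eloc, gamma,
    lambda, sigma), FDR-corrected across the global family."""
    table = _group_welch_table(aucs, subjects, test=test, adjust_covariates=adjust_covariates)
    return _attach_fdr(table, q)


def behavior_correlation(
    aucs: pd.DataFrame,
    subjects: SubjectTable,
    regions: list[str],
    q: float = 0.05,
    adjust_covariates: bool = False,
) -> pd.DataFrame:
    """Pearson correlation between abnormal regions' nodal AUCs and scores.

    Computed within the patient group only as plain pairwise Pearson
    correlation; the FDR family spans all (region, metric, score) triples
    tested. Constant scores are skipped with a warning. Set
    ``adjust_covariates=True`` to residualize the AUCs against the
    demographic design first (one-sided adjustment; with small patient
    groups this costs substantial power).
    """
    patient, _ = subjects.groups
    mask = subjects.group_mask(patient)
    if mask.sum() < 3:
        raise ValueError("need at least 3 patients for correlation")
    x_p = None
    if adjust_covariates:
        x_full, names = subjects.design_matrix()
        try:
            x_p = _clean_design(x_full[mask], names, int(mask.sum()))
        except ValueError:
            log.warning("patient covariate design under-determined; "
                        "correlating unadjusted AUCs")
            x_p = None
    rows = []
    for region in regions:
        for metric in NODAL_METRIC_COLUMNS:
            col = f"{metric}:{region}"
            if col not in aucs.columns:
                continue
            y = aucs.loc[mask, col].to_numpy(float)
            if x_p is not None and np.ptp(y) > 0:
                y = _residualize_against(y, x_p)
            for score in SCORE_COLUMNS:
                if score not in subjects.data.columns:
                    continue
                s = subjects.data.loc[mask, score].to_numpy(float)
                if np.ptp(s) == 0:
                    log.warning("score %s constant within patients; skipped", score)
                    continue
                if np.ptp(y) == 0:
                    r_val, p_val = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r_val, p_val = sps.pearsonr(y, s)
                rows.append((region, metric, score, float(r_val), mask.sum() - 2, float(p_val)))
    table = pd.DataFrame(rows, columns=["region", "metric", "score", "r", "df", "p"])
    if len(table):
        table = _attach_fdr(table, q)
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def demographic_table(subjects: SubjectTable, test: str = "welch") -> pd.DataFrame:
    """Group comparison of demographics and scores (Table-1 style).

    Sex is compared by Pearson chi-square on the 2x2 counts; age, education
    and each score by a two-tailed two-sample t-test (Welch by default).
    """
    patient, control = subjects.groups
    mask_p = subjects.group_mask(patient)
    mask_c = subjects.group_mask(control)
    d = subjects.data
    ttest = welch_ttest if test == "welch" else pooled_ttest
    rows = []
    sex = d["sex"].astype(str).str.upper().str[0]
    counts = np.array(
        [[(sex[mask_p] == "M").sum(), (sex[mask_p] == "F").sum()],
         [(sex[mask_c] == "M").sum(), (sex[mask_c] == "F").sum()]]
    )
    try:
        chi2, p = chi_square_2x2(counts)
    except ValueError:
        log.warning("sex contingency table has a zero margin; test skipped")
        chi2, p = np.nan, np.nan
    rows.append(("sex", "chi2", chi2, np.nan, p))
    for col in ["age", "education", *[c for c in SCORE_COLUMNS if c in d.columns]]:
        t, df, p = ttest(d.loc[mask_p, col].to_numpy(float), d.loc[mask_c, col].to_numpy(float))
        rows.append((col, "t", t, df, p))
    return pd.DataFrame(rows, columns=["variable", "statistic", "value", "df", "p"])
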
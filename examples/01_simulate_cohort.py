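"""Generate a synthetic two-group resting-state cohort and write it to disk.

The generator draws each subject's ROI time series from a modular
correlation structure (optionally with planted group-different edges),
simulates head motion with occasional spikes, and samples demographics and
clinical scores matching the study population. A ground-truth record is
written alongside so that recovery can be checked later — the analysis
stages never read it.
"""

from pathlib import Path

from funconn import CohortConfig, make_cohort, write_cohort

config = CohortConfig(
    n_group_a=5,            # patients ("IAD")
    n_group_b=5,            # controls ("HC")
    n_regions=20,
    n_timepoints=210,       # ~7 min at TR = 2 s
    module_sizes=(5, 5, 5, 5),
    planted_edges=((0, 7, 0.4),),   # group B's r(0,7) shifted by +0.4
    seed=11,
)

cohort = make_cohort(config)
out = write_cohort(cohort, Path("scratch/example_cohort"))

first = cohort.subjects[0]
print(f"wrote {len(cohort.subjects)} subjects to {out}")
print(f"first subject: {first.subject_id}, group {first.group}, "
      f"age {first.age}, {first.timeseries.values.shape} time series")
print(f"scores: { {k: round(v, 1) for k, v in first.scores.items()} }")
print(f"planted edges (ground truth): {cohort.ground_truth['planted_edges']}")
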
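"""Clean one subject's ROI time series before connectivity analysis.

Steps, in order: framewise displacement from the 6 rigid-body motion
parameters (rotations converted on a 50 mm sphere), censoring of frames
with FD > 0.5 mm, regression of the Friston 24-parameter motion expansion,
and zero-phase band-pass filtering to 0.01-0.08 Hz.
"""

from funconn import CohortConfig, clean, compute_fd, make_cohort

cohort = make_cohort(CohortConfig(
    n_group_a=1, n_group_b=1, n_regions=20, n_timepoints=210,
    module_sizes=(10, 10), seed=3,
))
subject = cohort.subjects[0]

fd = compute_fd(subject.motion)
print(f"mean FD {fd.values.mean():.4f} mm, "
      f"{int((fd.values > fd.threshold_mm).sum())} frames above 0.5 mm")

cleaned, kept = clean(subject.timeseries, motion=subject.motion)
print(f"kept {kept.size} of {subject.timeseries.n_timepoints} frames")
print(f"cleaned series: shape {cleaned.values.shape}, "
      f"column means ~ {cleaned.values.mean(axis=0).round(10).max():g} "
      f"(demeaned by the confound regression)")
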
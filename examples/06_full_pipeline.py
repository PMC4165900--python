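"""The end-to-end pipeline: simulated data on disk -> result tables.

Equivalent to the command line:

    funconn simulate --out scratch/pipeline_demo/cohort --seed 12 ...
    funconn run-all --data-dir ... --out ... --seed 1

Every stage is deterministic: rerunning with the same config and seed
reproduces every output byte for byte.
"""

from pathlib import Path

import pandas as pd

from funconn import RunConfig, run_pipeline
from funconn.studies import STUDY_PLANTED_EDGES, study_config
from funconn.synthetic import make_cohort, write_cohort

base = Path("scratch/pipeline_demo")
data = write_cohort(
    make_cohort(study_config(seed=12, planted_edges=STUDY_PLANTED_EDGES)),
    base / "cohort",
)

out = run_pipeline(RunConfig(
    data_dir=str(data), out_dir=str(base / "results"),
    s_step=0.04, n_rand=10, seed=1,
))
print(f"pipeline outputs in {out}:")
for f in sorted(p.name for p in out.iterdir()):
    print(" ", f)

edges = pd.read_csv(out / "edges_results.tsv", sep="\t")
print("\nsignificant edges:")
print(edges.loc[edges["significant"],
                ["region_a", "region_b", "t", "q"]].to_string(index=False))
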
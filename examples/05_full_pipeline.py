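"""Run the whole pipeline from one config and print its summary report.

Equivalent to `wmhlnm run -c config.yaml -o outdir` on the command line.
Every stage writes plain-text/NIfTI artifacts consumed by the next stage,
and the run is byte-reproducible under its master seed.
"""

import tempfile
from pathlib import Path

import wmhlnm as w
from wmhlnm.pipeline import CohortOptions, InferenceOptions, PredictionOptions

cfg = w.RunConfig(
    seed=3,
    cohort=CohortOptions(n_patients=60, n_subjects=8, n_timepoints=60),
    prediction=PredictionOptions(
        domains=("attention_executive", "verbal_memory"),
        feature_sets=("demo", "demo+totalWMH", "demo+fLNM+sLNM"),
        repeats=3,
    ),
    inference=InferenceOptions(domains=("attention_executive",),
                               modalities=("fLNM",), n_perm=500, n_spins=500),
)

outdir = Path(tempfile.mkdtemp()) / "demo_run"
report = w.run_pipeline(cfg, outdir)
print(w.summarize_run(outdir))
print(f"\nartifacts under {outdir}")
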
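"""One-call pipeline: simulate -> condition -> embed -> fit -> metrics/spectra -> PLS.

Everything is driven by a single config with one master seed; each stage gets
a derived seed, and the manifest records content digests so identical configs
reproduce identical artifacts. The same run is available from the shell:

    brainstates run --out scratch/demo --seed 11
    brainstates report scratch/demo
"""

from brainstates.pipeline import PipelineConfig, report, run

cfg = PipelineConfig(
    out_dir="scratch/demo",
    n_subjects=8,
    n_parcels=6,
    n_states=3,
    duration=20.0,
    n_lags=7,
    n_restarts=2,
    max_iter=15,
    n_perm=200,
    n_boot=100,
    top_n_parcels=3,
    seed=11,
)
run_dir = run(cfg)
print(report(run_dir))
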
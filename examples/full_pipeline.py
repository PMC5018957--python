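"""Run the whole chain from one config and list the artifacts it writes.

Equivalent to `popkit run-all --out pipeline_out`; two runs with the same
seed are byte-identical, MCMC stages included.
"""

import json
import tempfile
from pathlib import Path

import popkit as pk

config = pk.PipelineConfig.from_dict(
    {
        "model": {
            "chromosome_lengths": [150_000, 150_000],
            "n_sites": 120,
            "groups": [
                {"name": "occ", "n_accessions": 4, "fst": 0.3},
                {"name": "ori", "n_accessions": 4, "fst": 0.3},
            ],
            "admixed": [
                {"name": "mar_1", "proportions": {"occ": 0.5, "ori": 0.5}},
                {"name": "mar_2", "proportions": {"occ": 0.5, "ori": 0.5}},
            ],
        },
        "window": 50_000,
        "k_range": [1, 3],
        "n_runs": 2,
        "burnin": 50,
        "reps": 100,
        "seed": 1,
    }
)

outdir = Path(tempfile.mkdtemp(prefix="popkit_"))
manifest = pk.run_pipeline(config, outdir)
print(f"pipeline artifacts under {outdir}:")
for stage, meta in manifest["stages"].items():
    print(f"  {stage:15s} -> {', '.join(meta['outputs'][:4])}"
          + (" ..." if len(meta["outputs"]) > 4 else ""))
print(f"\nbest K chosen by delta-K: {manifest['stages']['admixture']['best_k']}")
print(f"bi-allelic sites: {manifest['stages']['matrix']['n_sites']}")
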
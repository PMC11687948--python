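"""One-call pipeline: simulate -> images -> train -> saliency -> analysis.

Writes every artifact (pixel map, model checkpoint, metrics, saliency maps,
taxa importance, metabolite/trait reports, manifest) under ./pipeline_out.
The same thing is available from the shell as
`taximage run --config cfg.yaml --seed 7`.
"""

import json

from taximage.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulate=True,
    sim={
        "n_taxa": 100,
        "n_per_class": 40,
        "da_indices": list(range(20)),
        "fold_change": 3.0,
        "target_sparsity": 0.75,
    },
    similarity_mode="metabolic",
    perplexity=20.0,
    image_height=16,
    image_width=16,
    blocks=[[8, 3, 1], [16, 3, 2]],
    train={"epochs": 25, "patience": 8},
    importance_percentile=90.0,
    seed=7,
    out_dir="pipeline_out",
)
results = run_pipeline(cfg)

print(json.dumps(results["metrics"], indent=2, default=str))
print("important taxa per class:",
      {k: len(v) for k, v in results["important_sets"].items()})
print("artifacts written to ./pipeline_out (see manifest.json for seeds)")
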
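"""A miniature pool-based active-learning run.

Trains on a small annotated pool with corrupted labels, scores the
unannotated pool by mean prediction entropy, lets the simulated annotator
reveal clean labels for the scenes above the threshold, retrains, and
prints the macro-F1 trajectory. The full-size version of this experiment
is lufor.benchmarks.run_al_benchmark.
"""

from lufor import ModelConfig, TrainConfig, CorruptionConfig, SceneConfig, generate_dataset
from lufor.active_learning import ALConfig, run_al_loop, reports_to_frame

pools = generate_dataset(
    10,
    SceneConfig(height=64, width=64),
    CorruptionConfig(mislabel_fraction=0.3, drop_fraction=0.3),
    annotated_fraction=0.4,
    test_fraction=0.34,
    seed=21,
)
print("pools (annotated, unannotated, test):", pools.sizes())

reports = run_al_loop(
    pools,
    ModelConfig(depth=2, base_filters=8, seed=0),
    TrainConfig(epochs=8, batch_size=8, learning_rate=2e-3, patch_size=32, seed=0),
    ALConfig(entropy_threshold=0.6, entropy_scale="nats", n_cycles=2, seed=0),
)
print(reports_to_frame(reports).to_string(index=False))
# n_selected in cycle c counts the scenes whose mean per-pixel prediction
# entropy over forest-loss pixels exceeded 0.6 nats after cycle c-1's
# training; their clean labels enter the training pool for cycle c.
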
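"""Train the attention U-Net on clean synthetic scenes and evaluate.

A small run (6 scenes, 10 epochs) that shows the full supervised path:
dataset -> 7-channel stacks -> focal-loss training -> per-class F1 on
held-out scenes. Expect a macro F1 well below the converged benchmark
value — this is a quick demonstration, not the benchmark itself
(see lufor.benchmarks.run_clean_benchmark for that).
"""

import numpy as np

from lufor import (
    CorruptionConfig,
    ModelConfig,
    SceneConfig,
    TrainConfig,
    build_model,
    generate_dataset,
    train,
)
from lufor.active_learning import evaluate_on_test
from lufor.metrics import f1_scores

pools = generate_dataset(6, SceneConfig(height=128, width=128), CorruptionConfig(),
                         annotated_fraction=0.5, test_fraction=0.5, seed=11)
print("pools (annotated, unannotated, test):", pools.sizes())

model = build_model(ModelConfig(depth=3, base_filters=12, seed=0))
tc = TrainConfig(epochs=10, batch_size=8, learning_rate=2e-3,
                 final_learning_rate=5e-4, patch_size=32, seed=0)
model, history = train(model, pools, tc)
print(f"focal loss: epoch 1 {history[0]:.4f} -> epoch {len(history)} {history[-1]:.4f}")

cm = evaluate_on_test(model, pools)
f1, macro, micro = f1_scores(cm)
print(f"held-out macro F1 {macro:.3f}, micro F1 {micro:.3f}")
print("weakest classes:", np.argsort(f1)[:3], "strongest:", np.argsort(f1)[-3:])
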
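"""Train the Siamese verifier and evaluate held-out pair verification.

Pairs carry label 0 (same class) or 1 (different class); the model's output
d in (0,1) is a dissimilarity, the similarity is s = 1 - d, and a pair is
called "same" when d falls below the 0.5 threshold. Training minimizes the
contrastive loss over the embedding distances; the sigmoid head is then
calibrated on the training pairs so d behaves like a probability of
"different".
"""

from simexplain import (BackboneSpec, SiameseNetwork, SyntheticSpec, TrainConfig,
                        build_pairs, evaluate_pairs, generate_shape_dataset,
                        stratified_split)

SEED = 0
dataset, _ = generate_shape_dataset(SyntheticSpec(seed=SEED))
split = stratified_split(dataset, test_frac=0.2, val_frac=0.1, seed=SEED)
print(f"split: {len(split.train)} train / {len(split.val)} val / {len(split.test)} test")

model = SiameseNetwork(BackboneSpec(), seed=SEED)
model, history = model.train(split, TrainConfig(epochs=10, seed=SEED))
for rec in history:
    print(f"epoch {rec['epoch']}: train_loss={rec['train_loss']:.4f} "
          f"val_accuracy={rec['val_accuracy']:.3f}")

pairs = build_pairs(split.test, seed=SEED)
metrics = evaluate_pairs(model, pairs, threshold=0.5)
print(f"\nheld-out pairs: {metrics.n_similar} similar, {metrics.n_dissimilar} dissimilar")
print(f"accuracy={metrics.accuracy:.3f}  auc={metrics.auc:.3f}  "
      f"precision={metrics.precision:.3f}  recall={metrics.recall:.3f}")
print("(accuracy: fraction of pairs called same/different correctly at d < 0.5;"
      " AUC ranks similarity s = 1 - d)")
model.save("scratch/demo_model.npz", train_config=TrainConfig(seed=SEED))
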
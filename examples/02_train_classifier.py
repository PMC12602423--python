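"""Train the per-pixel spectral classifier and evaluate it.

Samples labeled pixels from the first two dates, splits them 60/20/20,
standardizes by the training partition, trains the 5-20-15-3 feedforward
network with Adam and early stopping, and reports the confusion-matrix
metric suite on the held-out test partition.
"""

import paddycd as p

config = p.SceneConfig(height=128, width=128,
                       initial_fractions=(0.55, 0.35, 0.10), seed=11)
scenes = p.simulate_time_series(config, p.TransitionRates(seed=5),
                                steps_between=3)

counts = {(d, c): 1500 for d in ("34DAS", "41DAS") for c in (0, 1, 2)}
table = p.extract_training_samples(scenes, counts, seed=2)
train_t, val_t, test_t = p.shuffle_split(table, p.SplitSpec(seed=3))
print(f"samples: {len(train_t)} train / {len(val_t)} validation / "
      f"{len(test_t)} test")

scaler = p.fit_scaler(train_t)
model = p.build_model(p.ModelSpec(n_classes=3), seed=4)
print(f"network parameters: {model.spec.parameter_count()}")

fitted = p.train(model, p.apply_scaler(train_t, scaler),
                 p.apply_scaler(val_t, scaler),
                 p.TrainingConfig(seed=6), scaler=scaler)
print(f"stopped after {len(fitted.history)} epochs "
      f"(early stopping on validation loss)")

report = p.evaluate(fitted, test_t)
print(f"\ntest overall accuracy: {report.accuracy:.2f}%")
print(f"test kappa:            {report.kappa:.4f}")
print(f"cross-entropy loss:    {report.cross_entropy:.4f}")
print(f"mean squared error:    {report.mse:.4f}")
print("\nper-class one-vs-all metrics (0 paddy, 1 soil, 2 weed):")
print(report.per_class[["class_index", "precision", "recall", "f1"]]
      .to_string(index=False))
print("\nAccuracy near 1 and kappa near 1 mean the three ground covers are")
print("almost perfectly separable from their 5-band spectra alone.")
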
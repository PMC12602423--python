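"""Classify every date and difference the maps into transition matrices.

The trained network sweeps each date's raster, speckle is removed with a
sieve and a 3×3 majority filter, and pairs of thematic maps are compared
pixel-by-pixel: the 3×3 transition matrix counts pixels moving between
paddy, soil and weed over 7- and 14-day intervals.
"""

import paddycd as p

config = p.SceneConfig(height=128, width=128,
                       initial_fractions=(0.55, 0.35, 0.10), seed=11)
scenes = p.simulate_time_series(config, p.TransitionRates(seed=5),
                                steps_between=3)

counts = {(d, c): 1500 for d in ("34DAS", "41DAS") for c in (0, 1, 2)}
table = p.extract_training_samples(scenes, counts, seed=2)
train_t, val_t, _ = p.shuffle_split(table, p.SplitSpec(seed=3))
scaler = p.fit_scaler(train_t)
fitted = p.train(p.build_model(p.ModelSpec(n_classes=3), seed=4),
                 p.apply_scaler(train_t, scaler),
                 p.apply_scaler(val_t, scaler),
                 p.TrainingConfig(seed=6), scaler=scaler)

pp = p.PostprocessConfig(min_object_pixels=5, majority_kernel=3, passes=1)
classified = [
    p.majority_filter(p.sieve(
        p.classify_raster(fitted, s.reflectance, s.valid_mask,
                          date_tag=s.date_tag), pp), pp)
    for s in scenes
]

for second in (1, 2):
    cmap = p.difference_maps(classified[0], classified[second])
    tm = p.transition_matrix(cmap)
    days = 7 * second
    print(f"\ntransition matrix 34DAS -> {scenes[second].date_tag} "
          f"({days} days), pixel counts:")
    print(tm.to_frame().to_string())
    print(f"pixels that became weed: {p.weed_increase_count(tm)} "
          f"({100 * p.weed_increase_count(tm) / tm.valid_pixel_total:.2f}% "
          f"of the field)")

print("\nRows are the earlier date, columns the later one; the diagonal is")
print("unchanged cover. The paddy->weed and soil->weed cells quantify the")
print("infestation's spread, growing with the interval length.")
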
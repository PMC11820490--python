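"""Fit the prominence threshold and search-region bounds by grid search.

Splits a labeled dataset 80:20 at the trial level and scans a small grid,
minimizing the pooled RMSE of IF/FF frame differences on the training side.
"""

from codseg import GridSpec, generate_dataset, split_dataset, tune_parameters

data = generate_dataset(n_trials=60, seed=3)
train, test = split_dataset(data, train_fraction=0.8, seed=3)
print(f"{len(data)} trials -> {len(train)} training / {len(test)} test "
      f"({train.n_events()} / {test.n_events()} CODs)")

grid = GridSpec(prominences=(1.0, 1.5, 2.0),
                region_befores=(20, 40),
                region_afters=(15, 25))
best, table = tune_parameters(train, grid)
print(table.sort_values("rmse").to_string(index=False))
print(f"\nbest: prominence={best.prominence} "
      f"region=-{best.region_before}/+{best.region_after} frames")

# Cells whose region contains every true contact edge reach RMSE 0; ties
# break toward the smallest prominence and narrowest region.
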
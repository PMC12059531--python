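"""Fit the vertical EA model and predict efflux for every QSM cylinder.

Simulates climbs of 13 trees (4-7 measurement heights each, stem /
buttress / above-branch positions), fits the mixed model
EA ~ log(height) + position + (1 | tree) by REML, and applies it to one
tree's cylinders.
"""

import warnings

import stemflux as sf

cfg = sf.SyntheticConfig(seed=11)
census, trees = sf.generate_plot(cfg)
records = sf.census_records(census)

tags = sf.select_vertical_trees(census, cfg)
obs = sf.generate_vertical_observations([records[t] for t in tags],
                                        cfg.vertical_truth, cfg, rng=11)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = sf.fit_vertical_model(obs)

print(f"n = {fit.n_obs} observations on {fit.n_trees} trees")
print(f"intercept          : {fit.intercept:7.2f} +/- {fit.intercept_se:.2f}")
print(f"log(height) slope  : {fit.log_height_slope:7.2f} +/- "
      f"{fit.log_height_slope_se:.2f}")
print(f"buttress effect    : {fit.buttress_effect:7.2f} +/- "
      f"{fit.buttress_effect_se:.2f}")
print(f"above-branch effect: {fit.above_branch_effect:7.2f} +/- "
      f"{fit.above_branch_effect_se:.2f}")
print(f"tree sd / resid sd : {fit.random_intercept_sd:.2f} / {fit.residual_sd:.2f}")
print(f"(generating truth: 95.77 / 0 / +40 / +30, sd 10 / 5)")

tree = trees[0]
pred = sf.predict_tree_ea(fit, tree, records[tree.tag])
print(f"\ncylinder predictions for tree {tree.tag} "
      f"(dbh {records[tree.tag].dbh:.0f} cm):")
print(pred.groupby("position")[["area_m2", "ea_mgc_m2_h"]]
      .agg({"area_m2": "sum", "ea_mgc_m2_h": "mean"}).round(2))
# Effects are offsets from the stem reference class in mg C m-2 h-1;
# predictions are population-level (random intercept 0) because upscaling
# covers trees that were never climbed.
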
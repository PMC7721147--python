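"""Time-resolved association of expression with group differences.

Simulates genes whose spatial gradient switches on late in gestation, fits
region-specific trajectory smooths, averages them within ten age windows over
the late-gestation period, and correlates each gene's regional profile with
an anatomy-fixed group-difference vector per window.
"""

import logging

import pandas as pd

from natalaxis import syndata, trajectories as traj, windowed as win

logging.disable(logging.WARNING)

expr, truth = syndata.generate_expression_atlas(
    n_specimens=16, age_range=(84, 266), n_genes=30,
    n_planted_pos=5, n_planted_neg=5, target_tau=0.45, noise_sd=0.3,
    spatial_window=(215.0, 400.0), seed=33)
pre = traj.preprocess_expression(expr, min_obs=10)

fits = {}
for gene, grp in pre.groupby("gene"):
    f = traj.fit_gene_trajectory(grp, fit_linear=False)
    f.region_fit = traj.fit_region_trajectories(grp)
    fits[gene] = f

grids = traj.trajectory_grids(fits, (160, 260), n_points=100)
windows = win.make_age_windows(160, 260, 10)
window_means = win.window_mean_expression(grids, windows)

scores = pd.Series(truth.axis_region_scores)
diff = -scores  # stand-in regional difference profile aligned to the axis
assoc = win.window_gene_association(window_means, diff, alpha=0.05)
sets = win.significant_window_sets(assoc)

print("significant genes per 10-day window (160-260 pc days):")
for w in windows:
    bar = "#" * len(sets.get(w.index, []))
    print(f"  window {w.index:2d} [{w.start:.0f}, {w.end:.0f}): "
          f"{len(sets.get(w.index, [])):2d} {bar}")
print(f"\ngenes associated in >= 1 window: "
      f"{len(win.associated_in_any_window(sets))}")
# The planted gradient only switches on after ~day 215, so discoveries
# concentrate in the late windows - the temporal localisation the
# window analysis is designed to resolve.
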
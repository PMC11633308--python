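"""Estimate RNA half-lives from SLAM-seq conversion counts and test a
knockdown-induced stabilization of target transcripts.
"""

import numpy as np

from zfpkit import kinetics, simulate as sim

rng = np.random.default_rng(1)
half_lives = {f"g{i}": float(h) for i, h in enumerate(rng.uniform(2, 8, 100))}

cfg = sim.SimConfig(seed=1)
ctrl_df, _ = sim.simulate_slam(cfg, half_lives, condition="ctrl")
kd_df, _ = sim.simulate_slam(cfg, {g: 1.5 * h for g, h in half_lives.items()},
                             condition="kd")

fit = {}
for name, df in (("ctrl", ctrl_df), ("kd", kd_df)):
    series = kinetics.filter_slam_genes(kinetics.read_slam_table(df))
    fit[name] = kinetics.fit_all(series)
    passed = [f for f in fit[name].values() if f.passed]
    print(f"{name}: {len(passed)} genes pass (R^2 > 0.6); "
          f"median half-life {np.median([f.half_life for f in passed]):.2f} h")

res = kinetics.half_life_shift_test(fit["kd"], fit["ctrl"], set(half_lives))
print(f"\nhalf-life shift (targets, KD vs ctrl): +{res.median_shift_h:.2f} h, "
      f"Mann-Whitney p = {res.p_value:.2e}")
# The planted 1.5x stabilization appears as a positive median shift with
# a strongly significant two-sided Mann-Whitney U test.
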
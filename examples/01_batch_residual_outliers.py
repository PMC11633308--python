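"""Flag knockdowns with more significant events than their batch predicts.

Simulates two experimental batches of knockdown datasets whose baseline
significant-event counts differ 10-fold, plants one knockdown with +50%
excess differential genes, and recovers it with the batch-residual
outlier test.
"""

from zfpkit import kd_events, simulate as sim

cfg = sim.SimConfig(seed=1)
matrix, _, truth = sim.simulate_kd_tables(
    cfg, batch_means={"A": 100.0, "B": 1000.0},
    outlier_zfps={"ZNF_HOT": ("B", 0.5)}, tables=False)

results = kd_events.fit_batch_residuals(matrix, "DEG")
print(f"{'zfp':10s} {'batch':5s} {'obs':>6s} {'pred':>8s} {'res%':>7s} {'p':>8s}")
for r in sorted(results, key=lambda r: r.p_value)[:5]:
    batch = truth.batch_of[r.zfp_id]
    print(f"{r.zfp_id:10s} {batch:5s} {r.observed:6.0f} {r.predicted:8.1f} "
          f"{r.residual_pct_fc:7.1f} {r.p_value:8.4f}")

flagged = kd_events.flag_high_residual(results)
print("\nflagged (p < 0.05 and residual > +20%):",
      [f.zfp_id for f in flagged])
# The planted outlier is the only knockdown exceeding its batch mean by
# more than 20% with a significant studentized residual.
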
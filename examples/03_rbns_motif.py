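"""Derive an in vitro binding motif from RBNS pulldown/input pools.

Plants a GAAGA consensus in 30% of pulldown reads, then runs pentamer
counting, enrichment, priority alignment of the top 20 k-mers, and the
enrichment-weighted PWM.
"""

from zfpkit import rbns, simulate as sim

cfg = sim.SimConfig(seed=1)
pulldown, input_pool, truth = sim.simulate_rbns(
    cfg, sim.consensus_pwm("GAAGA"), planted_fraction=0.3, n_reads=50_000)

enrichment, groups, pwms = rbns.derive_motif(pulldown, input_pool, k=5, top_n=20)

print("top 5 enriched pentamers (R = pulldown freq / input freq):")
print(enrichment.head(5)[["kmer", "count_pd", "count_in", "R"]].to_string(index=False))

g = groups[0]
print(f"\ngroup 1 anchor: {g.anchor}; alignments of the next members:")
for m in g.members[1:6]:
    print(f"  {m.kmer}  offset {m.offset:+d}, {m.n_mismatch} mismatch -> {m.category}")

pwm = pwms[0]
print(f"\nweighted PWM consensus: {pwm.consensus} "
      f"(planted consensus {truth.consensus} appears as the core)")
print("per-position support (total enrichment weight):",
      [round(float(s), 1) for s in pwm.support])
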
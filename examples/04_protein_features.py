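"""Call ARM-like loci, disordered regions, and occlusion-derived RBDs on a
protein, then tabulate which feature classes the predicted RBD overlaps.
"""

from zfpkit import proteins as prot, simulate as sim

cfg = sim.SimConfig(seed=1)
records, truth = sim.simulate_proteins(
    cfg, n_proteins=1, length=300,
    planted_arm_loci={"P00": [(40, 46)]},
    planted_rbd_intervals={"P00": [(30, 60)]},
    planted_idr_intervals={"P00": [(25, 80)]})

p = records["P00"]
arm = prot.scan_arm_loci(p.sequence)
idrs = prot.call_idr_regions(p.disorder_score)
rbds = prot.call_rbd_intervals(p.occlusion_z)

print(f"protein {p.protein_id}, {len(p.sequence)} aa")
print("ARM-like loci (window K/R freq > 0.5):", sorted(arm))
print("  as merged intervals:", prot.merge_centers(arm))
print("disordered regions (score > 0.4):", idrs)
print("putative RBDs (occlusion Z < -1):", rbds)

p.domains = [("C2H2", 50, 75)]
row = prot.overlap_feature_classes(p, rbds, idrs, arm)
print(f"\nRBD present: {row.has_rbd}; overlapped feature classes: "
      f"{sorted(row.overlapped_classes)}")
# The planted RBD [30,60) overlaps the IDR, the ARM run, and the ZF domain.
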
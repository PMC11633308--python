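"""Classify a dual DNA/RNA binder and profile its binding geometry.

Simulates Cut&Run peaks concentrated near TSSs together with eCLIP
windows, classifies the binding mode, computes signed DNA-to-RNA peak
distances, and bins RNA binding along the metagene.
"""

import numpy as np

from zfpkit import colocalization as coloc, simulate as sim

cfg = sim.SimConfig(seed=1, n_genes=100)
genes = sim.make_annotation(cfg)
rna, _, dna, _ = sim.simulate_binding(cfg, genes, planted_tss_bias=3.0,
                                      n_windows=3000, n_peaks=800)

call = coloc.classify_binding_mode(dna, rna, genes)
print(f"DNA genes: {call.n_dna_genes}, RNA genes: {call.n_rna_genes} "
      f"-> mode: {call.mode}")

dists = coloc.peak_distance_profile(dna, rna, genes)
downstream = np.mean([d > 0 for d in dists])
print(f"peak-to-nearest-window distances: n={len(dists)}, "
      f"{100 * downstream:.0f}% have the RNA window downstream of the DNA peak")

prof = coloc.metagene_density(rna, genes)
print(f"metagene density, TSS-proximal bins 0-2: {prof.density[:3].sum():.3f} "
      f"(uniform expectation {3 / 101:.3f})")
# A TSS-proximal density about 3x the uniform expectation reflects the
# planted co-transcriptional binding bias near the start site.
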
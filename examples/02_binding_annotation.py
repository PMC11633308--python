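"""Annotate eCLIP windows with transcript feature classes and measure
3'UTR enrichment.

Plants an 8-fold 3'UTR binding preference in simulated enriched windows
and recovers it as a log2 odds ratio near 3 against a uniform background
window set.
"""

from collections import Counter

from zfpkit import binding, simulate as sim

cfg = sim.SimConfig(seed=1, n_genes=100)
genes = sim.make_annotation(cfg)
ip, background, _, truth = sim.simulate_binding(
    cfg, genes, planted_feature="3'UTR", planted_or=8.0, n_windows=5000)

binding.annotate_windows(ip, genes)
binding.annotate_windows(background, genes)

print("window feature classes (IP):")
for cls, n in Counter(w.feature_class for w in ip).most_common():
    print(f"  {cls:10s} {n:5d}  ({100 * n / len(ip):.1f}%)")

enr = binding.feature_enrichment_odds(ip, background, "3'UTR")
print(f"\n3'UTR enrichment: OR = {enr.odds_ratio:.2f}, "
      f"log2(OR) = {enr.log2_or:.2f}, one-sided Fisher p = {enr.fisher_p:.2e}")
print(f"planted odds ratio was {truth.planted_or:.0f} (log2 = 3.0)")

breadth = binding.binding_breadth(ip)
print(f"unique transcripts bound: {breadth.n_unique_transcripts} "
      f"-> widespread binder: {breadth.widespread}")
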
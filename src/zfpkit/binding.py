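"""eCLIP window annotation: transcript feature classes, feature enrichment
odds ratios, and binding breadth.

A window is assigned to exactly one feature class by the position of its
midpoint. Splice-site classes take precedence over plain exon/intron
classes: ADJ (within 50 bp of a splice site) beats PROX (within 300 bp),
and when both a donor (5') and an acceptor (3') site qualify at the same
level the nearer wins, ties broken toward the acceptor. Otherwise the
class is the feature containing the midpoint (5'UTR/CDS/3'UTR/intron, or
``noncoding`` for genes without a CDS). Windows overlapping no gene are
``intergenic``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import EnrichedWindow, GeneModel

SS_ADJ_DIST = 50
SS_PROX_DIST = 300

SPLICE_CLASSES = ("SS5_ADJ", "SS5_PROX", "SS3_ADJ", "SS3_PROX")


@dataclass
class FeatureEnrichment:
    zfp_id: str
    feature_class: str
    ip_in: int
    ip_out: int
    bg_in: int
    bg_out: int
    odds_ratio: float
    log2_or: float
    fisher_p: float


@dataclass
class BindingBreadth:
    zfp_id: str
    n_unique_transcripts: int
    widespread: bool


def _containment_class(mid: float, gene: GeneModel) -> str:
    for cls, ivs in (("5'UTR", gene.utr5), ("CDS", gene.cds), ("3'UTR", gene.utr3)):
        if any(s <= mid < e for s, e in ivs):
            return cls
    if any(s <= mid < e for s, e in gene.exons):
        # exonic but outside the UTR/CDS partition: noncoding transcript
        return "noncoding"
    return "intron"


def classify_feature(window: EnrichedWindow, gene: GeneModel | None) -> str:
    """Assign a single transcript feature class to a window."""
    if gene is None:
        return "intergenic"
    mid = window.midpoint
    if not gene.start <= mid < gene.end:
        return "intergenic"
    donors, acceptors = gene.splice_sites()
    d5 = min((abs(mid - c) for c in donors), default=np.inf)
    d3 = min((abs(mid - c) for c in acceptors), default=np.inf)
    for cutoff, suffix in ((SS_ADJ_DIST, "ADJ"), (SS_PROX_DIST, "PROX")):
        if d5 <= cutoff or d3 <= cutoff:
            # nearer site wins; exact tie goes to the 3' (acceptor) site
            if d3 <= cutoff and (d3 <= d5 or d5 > cutoff):
                return f"SS3_{suffix}"
            return f"SS5_{suffix}"
    return _containment_class(mid, gene)


def annotate_windows(windows: list[EnrichedWindow],
                     genes: dict[str, GeneModel]) -> list[EnrichedWindow]:
    """Set ``feature_class`` on each window in place (and return the list).

    Windows are matched to genes by their ``gene_id``; windows naming an
    unknown gene are classed intergenic.
    """
    for w in windows:
        w.feature_class = classify_feature(w, genes.get(w.gene_id))
    return windows


def feature_enrichment_odds(ip_windows: list[EnrichedWindow],
                            background_windows: list[EnrichedWindow],
                            feature_class: str,
                            zfp_id: str = "") -> FeatureEnrichment:
    """2x2 feature enrichment of IP windows against a background window set.

    Odds ratio is (ip_in/ip_out)/(bg_in/bg_out); a Haldane-Anscombe 0.5
    correction is applied to all cells only when some cell is zero. The
    Fisher p-value is one-sided (greater) on the uncorrected table.
    """
    if not ip_windows:
        raise ValueError("empty IP window set")
    if not background_windows:
        raise ValueError("empty background window set")
    if any(w.feature_class is None for w in ip_windows + background_windows):
        raise ValueError("windows must be annotated before computing enrichment")
    ip_in = sum(w.feature_class == feature_class for w in ip_windows)
    bg_in = sum(w.feature_class == feature_class for w in background_windows)
    ip_out = len(ip_windows) - ip_in
    bg_out = len(background_windows) - bg_in
    a, b, c, d = ip_in, ip_out, bg_in, bg_out
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a / b) / (c / d)
    _, p = stats.fisher_exact([[ip_in, ip_out], [bg_in, bg_out]], alternative="greater")
    return FeatureEnrichment(zfp_id, feature_class, ip_in, ip_out, bg_in, bg_out,
                             odds_ratio, float(np.log2(odds_ratio)), float(p))


def binding_breadth(windows: list[EnrichedWindow], threshold: int = 500,
                    strict: bool = False, zfp_id: str = "") -> BindingBreadth:
    """Count unique bound transcripts; ``strict`` uses > (dual-binder rule)."""
    n = len({w.gene_id for w in windows if w.gene_id and w.gene_id != "."})
    widespread = n > threshold if strict else n >= threshold
    return BindingBreadth(zfp_id, n, widespread)
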
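"""Dual DNA/RNA binder classification and DNA↔RNA binding-site geometry.

A protein is called a dual DNA/RNA binder (DRBP) when it binds more than
500 unique genes at both the DNA level (Cut&Run peaks, excluding
intergenic peaks more than 100 kb from the nearest gene) and the RNA
level (eCLIP windows). Geometry is characterized by signed
peak-to-nearest-window distances (positive = window transcriptionally
downstream of the peak), metagene density over percent-of-transcript
bins 0..100, and a Mann-Whitney U comparison of TSS-/TTS-proximal
density between profile groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import DnaPeak, EnrichedWindow, GeneModel

DRBP_MIN_GENES = 500         # strict >
MAX_INTERGENIC_DIST = 100_000
N_BINS = 101                 # integer percent bins 0..100 inclusive
PROXIMAL_PCT = 2             # "within 2% of transcript length"


@dataclass
class BindingModeCall:
    zfp_id: str
    n_dna_genes: int
    n_rna_genes: int
    mode: str  # DRBP | DNA_only | RNA_only | neither


@dataclass
class MetageneProfile:
    zfp_id: str
    density: np.ndarray  # length 101, sums to 1 when n_windows > 0
    n_windows: int


@dataclass
class ProximalEnrichmentResult:
    end: str  # TSS | TTS
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float


def assign_nearest_gene(peak: DnaPeak, genes: dict[str, GeneModel]) -> tuple[str | None, int | None]:
    """Nearest gene (by gap to the gene body; 0 when overlapping) and the
    signed distance from the peak midpoint to that gene's TSS."""
    best_id, best_gap = None, None
    mid = peak.midpoint
    for g in genes.values():
        if g.chrom != peak.chrom:
            continue
        gap = max(g.start - peak.end, peak.start - g.end, 0)
        if best_gap is None or gap < best_gap:
            best_id, best_gap = g.gene_id, gap
    if best_id is None:
        return None, None
    g = genes[best_id]
    dist = int(mid - g.tss) if g.strand == "+" else int(g.tss - mid)
    peak.gene_id = best_id
    peak.dist_to_tss = dist
    return best_id, best_gap


def classify_binding_mode(dna_peaks: list[DnaPeak], rna_windows: list[EnrichedWindow],
                          genes: dict[str, GeneModel],
                          max_intergenic: int = MAX_INTERGENIC_DIST,
                          zfp_id: str = "") -> BindingModeCall:
    """DRBP / DNA_only / RNA_only / neither by unique-gene counts.

    Peaks lacking a gene assignment are assigned to their nearest gene;
    peaks farther than ``max_intergenic`` bp from any gene are excluded
    from the DNA gene count.
    """
    if not genes:
        raise ValueError("empty annotation")
    dna_genes: set[str] = set()
    for p in dna_peaks:
        if p.gene_id is not None and p.gene_id in genes:
            g = genes[p.gene_id]
            gap = max(g.start - p.end, p.start - g.end, 0)
            gid = p.gene_id
        else:
            gid, gap = assign_nearest_gene(p, genes)
        if gid is not None and gap is not None and gap <= max_intergenic:
            dna_genes.add(gid)
    rna_genes = {w.gene_id for w in rna_windows if w.gene_id and w.gene_id != "."}
    n_dna, n_rna = len(dna_genes), len(rna_genes)
    if n_dna > DRBP_MIN_GENES and n_rna > DRBP_MIN_GENES:
        mode = "DRBP"
    elif n_dna > DRBP_MIN_GENES:
        mode = "DNA_only"
    elif n_rna > DRBP_MIN_GENES:
        mode = "RNA_only"
    else:
        mode = "neither"
    return BindingModeCall(zfp_id, n_dna, n_rna, mode)


def peak_distance_profile(dna_peaks: list[DnaPeak], rna_windows: list[EnrichedWindow],
                          genes: dict[str, GeneModel]) -> list[float]:
    """Per-peak signed midpoint distance to the nearest same-gene window.

    Positive when the window midpoint lies transcriptionally 3' of the
    peak midpoint. Nearest = smallest |distance|, ties broken toward the
    positive (downstream) side. Peaks on genes without windows are
    omitted.
    """
    windows_by_gene: dict[str, list[EnrichedWindow]] = {}
    for w in rna_windows:
        windows_by_gene.setdefault(w.gene_id, []).append(w)
    distances: list[float] = []
    for p in dna_peaks:
        if p.gene_id is None or p.gene_id not in genes:
            continue
        gene = genes[p.gene_id]
        cands = windows_by_gene.get(p.gene_id)
        if not cands:
            continue
        signed = []
        for w in cands:
            d = w.midpoint - p.midpoint
            if gene.strand == "-":
                d = -d
            signed.append(d)
        # nearest by magnitude; on a tie prefer the downstream (positive) one
        distances.append(min(signed, key=lambda d: (abs(d), 0 if d > 0 else 1)))
    return distances


def metagene_density(rna_windows: list[EnrichedWindow], genes: dict[str, GeneModel],
                     n_bins: int = N_BINS, zfp_id: str = "") -> MetageneProfile:
    """Window density over percent-of-transcript-length bins (0 = TSS,
    100 = TTS), normalized to sum 1."""
    counts = np.zeros(n_bins)
    n = 0
    for w in rna_windows:
        gene = genes.get(w.gene_id)
        if gene is None:
            continue
        if gene.length <= 0:
            raise ValueError(f"gene {gene.gene_id}: zero length")
        if gene.strand == "+":
            pos = 100.0 * (w.midpoint - gene.start) / gene.length
        else:
            pos = 100.0 * (gene.end - w.midpoint) / gene.length
        pos = min(max(pos, 0.0), 100.0)
        counts[min(int(pos), n_bins - 1)] += 1
        n += 1
    density = counts / n if n else counts
    return MetageneProfile(zfp_id, density, n)


def tss_tts_enrichment_test(profiles_a: list[MetageneProfile],
                            profiles_b: list[MetageneProfile],
                            proximal_pct: int = PROXIMAL_PCT) -> dict[str, ProximalEnrichmentResult]:
    """Two-sided Mann-Whitney U on TSS- and TTS-proximal density per group.

    Per profile, the TSS-proximal density is the summed density of bins
    0..proximal_pct and the TTS-proximal density that of the mirrored
    bins at the 3' end.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("each group needs at least 2 profiles")
    out = {}
    for end in ("TSS", "TTS"):
        if end == "TSS":
            va = [p.density[: proximal_pct + 1].sum() for p in profiles_a]
            vb = [p.density[: proximal_pct + 1].sum() for p in profiles_b]
        else:
            va = [p.density[-(proximal_pct + 1):].sum() for p in profiles_a]
            vb = [p.density[-(proximal_pct + 1):].sum() for p in profiles_b]
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        out[end] = ProximalEnrichmentResult(end, float(u), float(p),
                                            float(np.median(va)), float(np.median(vb)))
    return out
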
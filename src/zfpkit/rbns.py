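"""RNA Bind-n-Seq motif derivation.

k-mers are counted with a sliding window over the full reads of the
pulldown and input pools; per-pool frequencies give an enrichment ratio
R = freq_pulldown / freq_input per k-mer. The top-N enriched k-mers are
aligned to the single most enriched k-mer (the anchor), allowing one
mismatch and/or one offset, or two mismatches; among multiple feasible
alignments the priority is exact > 1 mismatch > 1 offset > 1 offset + 1
mismatch > 2 mismatches. k-mers admitting no alignment seed a new group,
recursively. Each group yields a position matrix in which every aligned
k-mer contributes its R value to the matching base at each covered
position; edge columns with little support are trimmed.

Sequences are handled in RNA space: T is read as U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

RNA_ALPHABET = ("A", "C", "G", "U")

#: alignment categories in priority order (best first)
CATEGORY_PRIORITY = ("exact", "1mm", "1off", "1off1mm", "2mm")


@dataclass
class AlignedKmer:
    kmer: str
    offset: int
    n_mismatch: int
    category: str


@dataclass
class KmerGroup:
    anchor: str
    members: list[AlignedKmer]  # anchor itself is members[0] (exact, offset 0)


@dataclass
class WeightedPWM:
    """Enrichment-weighted position matrix over the RNA alphabet.

    ``counts`` holds the raw accumulated R weights (positions x 4);
    ``support`` the per-position totals; ``matrix`` the column-normalized
    probabilities. ``offset_of_first_column`` locates the retained columns
    relative to the anchor's position 0.
    """
    counts: np.ndarray
    support: np.ndarray
    matrix: np.ndarray
    offset_of_first_column: int

    @property
    def consensus(self) -> str:
        return "".join(RNA_ALPHABET[i] for i in self.matrix.argmax(axis=1))


def _clean(read: str) -> str | None:
    seq = read.upper().replace("T", "U")
    if any(c not in "ACGU" for c in seq):
        return None
    return seq


def count_kmers(reads: Iterable[str], k: int = 5) -> dict[str, int]:
    """Sliding-window k-mer counts over the full reads (flanks included).

    Reads containing a non-ACGU(T) symbol are skipped; the skip tally is
    exposed as ``count_kmers.n_skipped`` after the call.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts: dict[str, int] = {}
    skipped = 0
    for read in reads:
        seq = _clean(read)
        if seq is None:
            skipped += 1
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    count_kmers.n_skipped = skipped
    return counts


count_kmers.n_skipped = 0


def kmer_enrichment(counts_pd: dict[str, int], counts_in: dict[str, int],
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-k-mer enrichment R = freq_pulldown / freq_input.

    A pseudocount is added to every k-mer count (union of both pools)
    before frequencies so that R stays finite for k-mers absent from the
    input pool. Sorted by R descending, ties broken lexicographically.
    """
    ks = {len(x) for x in counts_pd} | {len(x) for x in counts_in}
    if len(ks) > 1:
        raise ValueError(f"mismatched k-mer lengths across pools: {sorted(ks)}")
    kmers = sorted(set(counts_pd) | set(counts_in))
    c_pd = np.array([counts_pd.get(x, 0) for x in kmers], dtype=float) + pseudocount
    c_in = np.array([counts_in.get(x, 0) for x in kmers], dtype=float) + pseudocount
    freq_pd = c_pd / c_pd.sum()
    freq_in = c_in / c_in.sum()
    df = pd.DataFrame({
        "kmer": kmers,
        "count_pd": [counts_pd.get(x, 0) for x in kmers],
        "count_in": [counts_in.get(x, 0) for x in kmers],
        "freq_pd": freq_pd,
        "freq_in": freq_in,
        "R": freq_pd / freq_in,
    })
    return (df.sort_values(["R", "kmer"], ascending=[False, True])
              .reset_index(drop=True))


def align_pair(anchor: str, candidate: str) -> AlignedKmer | None:
    """Best alignment of a candidate k-mer to the anchor, or None.

    Offsets are restricted to {-1, 0, +1}; offset o aligns candidate
    position i with anchor position i + o (so +1 slides the candidate
    right along the anchor). Mismatches are counted over the overlap.
    Budget: (0 offsets, <=2 mismatches) or (1 offset, <=1 mismatch).
    Within a category, the tie-break is smaller |offset|, then the
    negative offset first.
    """
    k = len(anchor)
    options: list[tuple[int, int, AlignedKmer]] = []
    for offset in (-1, 0, 1):
        if offset == 0:
            mism = sum(a != b for a, b in zip(candidate, anchor))
        elif offset == 1:
            mism = sum(a != b for a, b in zip(candidate[: k - 1], anchor[1:]))
        else:
            mism = sum(a != b for a, b in zip(candidate[1:], anchor[: k - 1]))
        if offset == 0 and mism == 0:
            cat = "exact"
        elif offset == 0 and mism == 1:
            cat = "1mm"
        elif offset == 0 and mism == 2:
            cat = "2mm"
        elif offset != 0 and mism == 0:
            cat = "1off"
        elif offset != 0 and mism == 1:
            cat = "1off1mm"
        else:
            continue
        rank = CATEGORY_PRIORITY.index(cat)
        # tie-break key: category rank, |offset|, negative offset first
        options.append(((rank, abs(offset), 0 if offset < 0 else 1),
                        mism, AlignedKmer(candidate, offset, mism, cat)))
    if not options:
        return None
    options.sort(key=lambda t: t[0])
    return options[0][2]


def align_top_kmers(enrichment: pd.DataFrame, top_n: int = 20) -> list[KmerGroup]:
    """Group the top-N enriched k-mers by alignability to a shared anchor.

    The most enriched k-mer anchors the first group; unalignable k-mers
    (preserving their enrichment order) recursively seed further groups.
    ``enrichment`` must be sorted by R descending (as ``kmer_enrichment``
    returns it).
    """
    if top_n < 2:
        raise ValueError("top_n must be at least 2")
    queue = list(enrichment["kmer"].head(top_n))
    groups: list[KmerGroup] = []
    while queue:
        anchor = queue[0]
        members = [AlignedKmer(anchor, 0, 0, "exact")]
        leftovers: list[str] = []
        for cand in queue[1:]:
            aln = align_pair(anchor, cand)
            if aln is None:
                leftovers.append(cand)
            else:
                members.append(aln)
        groups.append(KmerGroup(anchor, members))
        queue = leftovers
    return groups


def build_weighted_pwm(group: KmerGroup, enrichment: pd.DataFrame,
                       trim_frac: float = 0.25) -> WeightedPWM:
    """Accumulate R-weighted base counts over the aligned group, then trim.

    Each aligned k-mer adds its enrichment R to the matching base at every
    position it covers (in anchor coordinates, extended by the offsets).
    Edge columns whose total support falls below ``trim_frac`` times the
    maximum column support are removed iteratively from both ends; inner
    columns are never removed.
    """
    if not group.members:
        raise ValueError("empty k-mer group")
    r_of = dict(zip(enrichment["kmer"], enrichment["R"]))
    k = len(group.anchor)
    offsets = [m.offset for m in group.members]
    lo = min(0, min(offsets))
    hi = max(0, max(offsets))
    width = k + (hi - lo)
    counts = np.zeros((width, 4))
    base_idx = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for m in group.members:
        r = float(r_of[m.kmer])
        col0 = m.offset - lo
        for j, base in enumerate(m.kmer):
            counts[col0 + j, base_idx[base]] += r
    support = counts.sum(axis=1)
    left, right = 0, width
    threshold = trim_frac * support.max()
    while left < right and support[left] < threshold:
        left += 1
    while right > left and support[right - 1] < threshold:
        right -= 1
    if left >= right:
        raise ValueError("degenerate group: all PWM columns trimmed")
    counts = counts[left:right]
    support = support[left:right]
    matrix = counts / support[:, None]
    return WeightedPWM(counts, support, matrix, offset_of_first_column=lo + left)


def derive_motif(pulldown_reads: Iterable[str], input_reads: Iterable[str],
                 k: int = 5, top_n: int = 20, trim_frac: float = 0.25,
                 pseudocount: float = 1.0) -> tuple[pd.DataFrame, list[KmerGroup], list[WeightedPWM]]:
    """End-to-end RBNS motif call: enrichment table, groups, one PWM per group."""
    enr = kmer_enrichment(count_kmers(pulldown_reads, k),
                          count_kmers(input_reads, k), pseudocount)
    groups = align_top_kmers(enr, top_n)
    pwms = [build_weighted_pwm(g, enr, trim_frac) for g in groups]
    return enr, groups, pwms
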
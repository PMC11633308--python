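"""Protein feature calling: ARM-like loci, disordered regions, and
occlusion-derived RNA-binding domains (RBDs).

ARM-like (arginine/lysine-rich) loci are residue centers whose 5-aa
window contains K/R at a frequency strictly greater than 0.5 (>=3 of 5),
excluding centers within 2 residues of either terminus. Disordered
regions are maximal runs of residues with disorder score > 0.4; putative
RBDs are maximal runs with occlusion Z score < -1. All intervals are
0-based half-open in residue units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Interval = tuple[int, int]

ZF_LABELS_DEFAULT = frozenset({
    "C2H2", "CCCH", "CCHC", "RING", "PHD", "LIM", "MYND", "ZF", "ZnF",
})


@dataclass
class ProteinRecord:
    protein_id: str
    sequence: str
    occlusion_z: np.ndarray | None = None
    disorder_score: np.ndarray | None = None
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("occlusion_z", "disorder_score"):
            track = getattr(self, name)
            if track is not None:
                track = np.asarray(track, dtype=float)
                setattr(self, name, track)
                if len(track) != len(self.sequence):
                    raise ValueError(
                        f"{self.protein_id}: {name} length {len(track)} != "
                        f"sequence length {len(self.sequence)}")


@dataclass
class FeatureOverlapRow:
    protein_id: str
    has_rbd: bool
    overlapped_classes: set[str]


def scan_arm_loci(sequence: str, window: int = 5, min_frac: float = 0.5,
                  edge_skip: int = 2) -> set[int]:
    """Residue centers of K/R-rich sliding windows (ARM-like loci)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if len(sequence) < window:
        return set()
    half = window // 2
    is_kr = [c in "KR" for c in sequence.upper()]
    loci = set()
    lo = max(half, edge_skip)
    hi = min(len(sequence) - 1 - half, len(sequence) - 1 - edge_skip)
    for c in range(lo, hi + 1):
        if sum(is_kr[c - half:c + half + 1]) > min_frac * window:
            loci.add(c)
    return loci


def _runs(mask: np.ndarray, min_len: int = 1) -> list[Interval]:
    """Maximal True runs as half-open intervals, length-filtered."""
    intervals: list[Interval] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(mask)))
    return [(s, e) for s, e in intervals if e - s >= min_len]


def call_idr_regions(disorder_score, threshold: float = 0.4) -> list[Interval]:
    """Maximal runs with disorder score strictly above the threshold."""
    track = np.asarray(disorder_score, dtype=float)
    return _runs(track > threshold)


def call_rbd_intervals(occlusion_z, z_cut: float = -1.0,
                       min_len: int = 1) -> list[Interval]:
    """Maximal runs with occlusion Z strictly below the cut (putative RBDs)."""
    track = np.asarray(occlusion_z, dtype=float)
    return _runs(track < z_cut, min_len=min_len)


def merge_centers(centers: set[int]) -> list[Interval]:
    """Merge consecutive residue centers into half-open intervals."""
    if not centers:
        return []
    ordered = sorted(centers)
    intervals = []
    start = prev = ordered[0]
    for c in ordered[1:]:
        if c == prev + 1:
            prev = c
        else:
            intervals.append((start, prev + 1))
            start = prev = c
    intervals.append((start, prev + 1))
    return intervals


def _intersects(a: Interval, b: Interval) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def overlap_feature_classes(protein: ProteinRecord, rbds: list[Interval],
                            idrs: list[Interval], arm_loci: set[int],
                            zf_labels: frozenset[str] = ZF_LABELS_DEFAULT) -> FeatureOverlapRow:
    """Which feature classes the protein's predicted RBDs touch.

    A class is overlapped when any RBD shares at least one residue with
    any interval of that class; ARM loci count as width-1 intervals at
    their centers. Domains with a label in ``zf_labels`` are ZF_domain,
    the rest other_domain.
    """
    if not rbds:
        return FeatureOverlapRow(protein.protein_id, False, set())
    classes: set[str] = set()
    arm_ivs = [(c, c + 1) for c in arm_loci]
    for rbd in rbds:
        if any(_intersects(rbd, iv) for iv in idrs):
            classes.add("IDR")
        if any(_intersects(rbd, iv) for iv in arm_ivs):
            classes.add("ARM_like")
        for label, s, e in protein.domains:
            if _intersects(rbd, (s, e)):
                classes.add("ZF_domain" if label in zf_labels else "other_domain")
    return FeatureOverlapRow(protein.protein_id, True, classes)
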
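"""Generic set-overlap machinery for integrating binding targets with
knockdown-responsive gene sets, plus cassette-exon proximity counting.

The workhorse is a 2x2 contingency test of two gene sets against an
explicit universe: Fisher's exact test (one-sided greater by default,
matching an enrichment question) or the equivalent hypergeometric upper
tail. The regulated-cassette counter joins binding windows to significant
skipped-exon events by distance between the window interval and the
event's junction coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io_formats import EnrichedWindow, SpliceEventRecord

TESTS = ("fisher_greater", "fisher_two_sided", "hypergeom_ge")


@dataclass
class ContingencyResult:
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |universe \ (A ∪ B)|
    odds_ratio: float
    p_value: float
    test: str
    universe_size: int


@dataclass
class RegulatedCassetteCount:
    zfp_id: str
    n_genes: int
    supporting: list[tuple[str, str, EnrichedWindow]]  # (gene_id, event_id, window)


def set_overlap_test(set_a: set[str], set_b: set[str], universe: set[str],
                     test: str = "fisher_greater") -> ContingencyResult:
    """Overlap of two gene sets against a universe, with exact p-value."""
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    for name, s in (("setA", set_a), ("setB", set_b)):
        stray = s - universe
        if stray:
            raise ValueError(f"{name} element(s) outside universe: {sorted(stray)[:5]}")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    if test == "fisher_two_sided":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    else:
        # one-sided greater == hypergeometric upper tail P(X >= a)
        p = stats.hypergeom.sf(a - 1, len(universe), a + b, a + c)
    aa, bb, cc, dd = (a, b, c, d)
    if min(aa, bb, cc, dd) == 0:
        aa, bb, cc, dd = aa + 0.5, bb + 0.5, cc + 0.5, dd + 0.5
    return ContingencyResult(a, b, c, d, (aa * dd) / (bb * cc), float(p),
                             test, len(universe))


def jaccard(set_a: set[str], set_b: set[str]) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def _gap_to_point(start: int, end: int, point: int) -> int:
    """Distance from a half-open interval to a boundary coordinate."""
    if start <= point <= end:
        return 0
    return min(abs(point - start), abs(point - end))


def count_regulated_cassettes(windows: list[EnrichedWindow],
                              se_events: list[SpliceEventRecord],
                              max_dist: int = 50,
                              zfp_id: str = "") -> RegulatedCassetteCount:
    """Genes with a binding window within ``max_dist`` bp of a significant
    cassette-exon junction; each gene counted once.

    Only windows and events sharing a gene_id are compared. Events without
    junction coordinates are skipped and tallied on the result attribute
    ``n_skipped_events``.
    """
    by_gene: dict[str, list[EnrichedWindow]] = {}
    for w in windows:
        by_gene.setdefault(w.gene_id, []).append(w)
    supporting = []
    n_skipped = 0
    for ev in se_events:
        if not ev.junction_coords:
            n_skipped += 1
            continue
        for w in by_gene.get(ev.gene_id, []):
            gap = min(_gap_to_point(w.start, w.end, j) for j in ev.junction_coords)
            if gap <= max_dist:
                supporting.append((ev.gene_id, ev.event_id, w))
    result = RegulatedCassetteCount(zfp_id, len({g for g, _, _ in supporting}), supporting)
    result.n_skipped_events = n_skipped
    return result


def build_target_sets(windows: list[EnrichedWindow],
                      feature_filter: set[str] | None = None) -> set[str]:
    """Unique gene ids of windows, optionally restricted to feature classes."""
    if feature_filter is not None:
        if any(w.feature_class is None for w in windows):
            raise ValueError("windows must be annotated to filter by feature class")
        return {w.gene_id for w in windows if w.feature_class in feature_filter}
    return {w.gene_id for w in windows}
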
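"""Readers and writers for the file formats the pipeline consumes.

All interval types are 0-based half-open (BED convention) throughout the
package. GTF input (1-based closed) is converted on read. TSV dialect:
tab-separated, ``#`` comment lines ignored, UTF-8.

The central coordinate frame is :class:`GeneModel`: a gene with strand-aware
TSS/TTS, exon structure, a 5'UTR/CDS/3'UTR partition of exonic space, and
derived splice-site coordinates. Every downstream interval operation
(window classification, metagene binning, peak-to-gene assignment) works in
this frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

Interval = tuple[int, int]

FEATURE_CLASSES = (
    "5'UTR", "CDS", "3'UTR", "intron",
    "SS5_ADJ", "SS5_PROX", "SS3_ADJ", "SS3_PROX",
    "noncoding", "intergenic",
)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


class FormatError(ValueError):
    """Malformed input file; message names the offending line or column."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene locus with exon structure and a UTR/CDS partition.

    Coordinates are 0-based half-open. ``tss``/``tts`` are single base
    coordinates derived from strand: ``tss == start`` on '+', ``end - 1``
    on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        for name, ivs in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
            for s, e in ivs:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise ValueError(
                        f"gene {self.gene_id}: {name} interval ({s},{e}) not contained in an exon")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def splice_sites(self) -> tuple[list[int], list[int]]:
        """Return (donor, acceptor) boundary coordinates, strand-aware.

        The donor (5' splice site) is the exon/intron boundary at the
        transcriptionally upstream end of each intron; the acceptor (3'
        splice site) the downstream end. Single-exon genes have none.
        """
        donors: list[int] = []
        acceptors: list[int] = []
        for left, right in zip(self.exons[:-1], self.exons[1:]):
            if self.strand == "+":
                donors.append(left[1])
                acceptors.append(right[0])
            else:
                donors.append(right[0])
                acceptors.append(left[1])
        return donors, acceptors


@dataclass
class EnrichedWindow:
    """A significantly enriched eCLIP RNA-binding window (Skipper-style)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    odds_ratio: float
    fdr: float
    feature_class: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"window {self.chrom}:{self.start}-{self.end}: end must exceed start")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"window {self.chrom}:{self.start}: fdr {self.fdr} outside [0,1]")
        if self.odds_ratio < 0:
            raise ValueError(f"window {self.chrom}:{self.start}: negative odds ratio")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class DnaPeak:
    """A Cut&Run DNA peak (MACS2 narrowPeak) with optional gene assignment."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue: float = -1.0
    qvalue: float = -1.0
    summit_offset: int | None = None
    gene_id: str | None = None
    dist_to_tss: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError(
                f"peak {self.chrom}:{self.start}: summit offset {self.summit_offset} outside peak")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class DiffExprRecord:
    gene_id: str
    log2fc: float
    fdr: float


@dataclass
class SpliceEventRecord:
    event_id: str
    gene_id: str
    event_type: str
    junction_coords: list[int]
    delta_psi: float
    fdr: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event {self.event_id}: unknown event type {self.event_type!r}")
        if abs(self.delta_psi) > 1:
            raise ValueError(f"event {self.event_id}: |delta_psi| > 1")


@dataclass
class ApaEventRecord:
    gene_id: str
    delta_psi: float
    fdr: float


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def _lines(path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            yield i, line


def _int(value: str, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {value!r}") from None


def _partition_exons(exons: Sequence[Interval], thick_start: int, thick_end: int,
                     strand: str) -> tuple[list[Interval], list[Interval], list[Interval]]:
    """Split exonic space at the thick (CDS) boundaries into UTR5/CDS/UTR3."""
    left: list[Interval] = []
    cds: list[Interval] = []
    right: list[Interval] = []
    if thick_start >= thick_end:  # noncoding
        return [], [], []
    for s, e in exons:
        if e <= thick_start:
            left.append((s, e))
        elif s >= thick_end:
            right.append((s, e))
        else:
            if s < thick_start:
                left.append((s, thick_start))
            cds.append((max(s, thick_start), min(e, thick_end)))
            if e > thick_end:
                right.append((thick_end, e))
    if strand == "+":
        return left, cds, right
    return right, cds, left


def read_annotation(path, dialect: str = "bed12") -> dict[str, GeneModel]:
    """Read a gene annotation into GeneModels keyed by gene_id.

    ``dialect='bed12'`` expects standard 12-column BED with thickStart/
    thickEnd marking the CDS span; ``'gtf_lite'`` a minimal GTF whose
    exon/CDS features carry a ``gene_id "..."`` attribute.
    """
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gtf_lite":
        return _read_gtf_lite(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed12(path) -> dict[str, GeneModel]:
    genes: dict[str, GeneModel] = {}
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 12:
            raise FormatError(f"line {lineno}: expected 12 BED columns, got {len(f)}")
        chrom = f[0]
        start = _int(f[1], lineno, "start")
        end = _int(f[2], lineno, "end")
        gene_id = f[3]
        strand = f[5]
        thick_start = _int(f[6], lineno, "thickStart")
        thick_end = _int(f[7], lineno, "thickEnd")
        n_blocks = _int(f[9], lineno, "blockCount")
        sizes = [_int(x, lineno, "blockSize") for x in f[10].rstrip(",").split(",")]
        offsets = [_int(x, lineno, "blockStart") for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(f"line {lineno}: blockCount disagrees with block lists")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise FormatError(f"line {lineno}: blockStarts out of order")
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        if exons[-1][1] != end:
            raise FormatError(f"line {lineno}: blocks do not span chromEnd")
        if gene_id in genes:
            raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
        utr5, cds, utr3 = _partition_exons(exons, thick_start, thick_end, strand)
        genes[gene_id] = GeneModel(gene_id, chrom, strand, start, end, exons,
                                   utr5=utr5, cds=cds, utr3=utr3)
    return genes


def _gtf_attr(attrs: str, key: str, lineno: int) -> str:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip('"')
    raise FormatError(f"line {lineno}: missing attribute {key!r}")


def _read_gtf_lite(path) -> dict[str, GeneModel]:
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) != 9:
            raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(f)}")
        chrom, _, feature, start1, end1, _, strand, _, attrs = f
        start = _int(start1, lineno, "start") - 1  # GTF is 1-based closed
        end = _int(end1, lineno, "end")
        gid = _gtf_attr(attrs, "gene_id", lineno)
        if gid in meta and meta[gid] != (chrom, strand):
            raise FormatError(f"line {lineno}: gene {gid!r} changes chrom/strand")
        meta[gid] = (chrom, strand)
        if feature == "exon":
            exons.setdefault(gid, []).append((start, end))
        elif feature == "CDS":
            cds.setdefault(gid, []).append((start, end))
    genes: dict[str, GeneModel] = {}
    for gid, (chrom, strand) in meta.items():
        ivs = sorted(exons.get(gid, []))
        if not ivs:
            raise FormatError(f"gene {gid!r}: no exon features")
        cds_ivs = sorted(cds.get(gid, []))
        if cds_ivs:
            u5, c, u3 = _partition_exons(ivs, cds_ivs[0][0], cds_ivs[-1][1], strand)
        else:
            u5, c, u3 = [], [], []
        genes[gid] = GeneModel(gid, chrom, strand, ivs[0][0], ivs[-1][1], ivs,
                               utr5=u5, cds=c, utr3=u3)
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, _ in g.exons)
            if g.cds:
                thick_start, thick_end = g.cds[0][0], g.cds[-1][1]
            else:
                thick_start = thick_end = g.start
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                str(thick_start), str(thick_end), "0", str(len(g.exons)),
                sizes, offsets,
            ]) + "\n")


# ---------------------------------------------------------------------------
# window / peak readers
# ---------------------------------------------------------------------------

#: BED6+ layout for enriched windows: name column carries the gene id, then
#: odds_ratio and fdr; any further columns are carried through verbatim.
def read_windows(path) -> list[EnrichedWindow]:
    windows: list[EnrichedWindow] = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 8:
            raise FormatError(f"line {lineno}: expected ≥8 columns (BED6 + odds_ratio, fdr)")
        if f[5] not in ("+", "-", "."):
            raise FormatError(f"line {lineno}: missing or invalid strand {f[5]!r}")
        strand = f[5]
        if strand == ".":
            warnings.warn(f"line {lineno}: unstranded window treated as '+'")
            strand = "+"
        try:
            odds_ratio = float(f[6])
            fdr = float(f[7])
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric odds_ratio/fdr") from None
        extra = {"_score": f[4]}
        if len(f) > 8:
            extra["_extra_cols"] = f[8:]
        windows.append(EnrichedWindow(
            chrom=f[0], start=_int(f[1], lineno, "start"), end=_int(f[2], lineno, "end"),
            strand=strand, gene_id=f[3], odds_ratio=odds_ratio, fdr=fdr, extra=extra))
    return windows


def write_windows(windows: Iterable[EnrichedWindow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in windows:
            # score column (BED6 slot 5): preserve the input's, else mirror the OR
            score = w.extra.get("_score", _fmt(w.odds_ratio))
            row = [w.chrom, str(w.start), str(w.end), w.gene_id,
                   score, w.strand, _fmt(w.odds_ratio), _fmt(w.fdr)]
            row += w.extra.get("_extra_cols", [])
            fh.write("\t".join(row) + "\n")


def _fmt(x: float) -> str:
    """Render a float the way the fixtures print it: no trailing zeros."""
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def read_narrowpeak(path) -> list[DnaPeak]:
    peaks: list[DnaPeak] = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if len(f) < 10:
            raise FormatError(f"line {lineno}: expected 10 narrowPeak columns, got {len(f)}")
        start = _int(f[1], lineno, "start")
        end = _int(f[2], lineno, "end")
        summit = _int(f[9], lineno, "summit")
        peaks.append(DnaPeak(
            chrom=f[0], start=start, end=end, name=f[3], score=float(f[4]),
            strand=f[5], signal=float(f[6]), pvalue=float(f[7]), qvalue=float(f[8]),
            summit_offset=None if summit == -1 else summit))
    return peaks


def write_narrowpeak(peaks: Iterable[DnaPeak], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write("\t".join([
                p.chrom, str(p.start), str(p.end), p.name, _fmt(p.score), p.strand,
                _fmt(p.signal), _fmt(p.pvalue), _fmt(p.qvalue), str(summit),
            ]) + "\n")


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

#: named column contracts: schema name -> {record field: accepted column names}
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, ...]]] = {
    "deseq2": {
        "gene_id": ("gene_id", "gene"),
        "log2fc": ("log2FoldChange", "log2fc"),
        "fdr": ("padj", "fdr"),
    },
    "rmats": {
        "event_id": ("event_id", "ID"),
        "gene_id": ("gene_id", "GeneID"),
        "event_type": ("event_type",),
        "junction_coords": ("junction_coords",),
        "delta_psi": ("delta_psi", "IncLevelDifference"),
        "fdr": ("fdr", "FDR"),
    },
    "labrat": {
        "gene_id": ("gene_id", "Gene"),
        "delta_psi": ("delta_psi", "deltapsi"),
        "fdr": ("fdr", "FDR"),
    },
}


def read_table(path, schema: str) -> list:
    """Read a TSV differential table under a named column contract.

    Returns ``DiffExprRecord`` (schema 'deseq2'), ``SpliceEventRecord``
    ('rmats') or ``ApaEventRecord`` ('labrat') lists. Unknown columns are
    preserved on the returned frame attribute ``read_table.last_frame``.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    contract = TABLE_SCHEMAS[schema]
    resolved: dict[str, str] = {}
    for fieldname, candidates in contract.items():
        hit = next((c for c in candidates if c in df.columns), None)
        if hit is None:
            raise FormatError(f"missing required column {candidates[0]!r} for schema {schema!r}")
        resolved[fieldname] = hit
    read_table.last_frame = df

    def num(row_idx, col):
        v = df.at[row_idx, col]
        if pd.isna(v) or v in ("NA", ""):
            return float("nan")
        try:
            return float(v)
        except ValueError:
            raise FormatError(f"row {row_idx}: unparseable numeric in column {col!r}: {v!r}") from None

    records = []
    for i in df.index:
        if schema == "deseq2":
            records.append(DiffExprRecord(
                gene_id=str(df.at[i, resolved["gene_id"]]),
                log2fc=num(i, resolved["log2fc"]), fdr=num(i, resolved["fdr"])))
        elif schema == "rmats":
            raw = df.at[i, resolved["junction_coords"]]
            coords = [] if pd.isna(raw) or raw == "" else [int(x) for x in str(raw).split(",")]
            records.append(SpliceEventRecord(
                event_id=str(df.at[i, resolved["event_id"]]),
                gene_id=str(df.at[i, resolved["gene_id"]]),
                event_type=str(df.at[i, resolved["event_type"]]),
                junction_coords=coords,
                delta_psi=num(i, resolved["delta_psi"]), fdr=num(i, resolved["fdr"])))
        else:
            records.append(ApaEventRecord(
                gene_id=str(df.at[i, resolved["gene_id"]]),
                delta_psi=num(i, resolved["delta_psi"]), fdr=num(i, resolved["fdr"])))
    return records


read_table.last_frame = None
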
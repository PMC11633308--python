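"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the shape of one upstream data type — gene
annotation, eCLIP enriched windows and Cut&Run peaks, knockdown
differential tables, SLAM-seq conversion counts, RBNS read pools,
Ribo-STAMP edit counts, tethering luminescence, and protein feature
tracks — with known planted parameters returned alongside the data so
downstream estimators can be scored.

Noise models are the simplest consistent with each data type's support:
Poisson for counts, lognormal for luminescence, per-window Bernoulli
placement for binding. Every generator draws from its own RNG stream,
derived from the master seed by a stable label, so adding one generator
never perturbs another's output; a fixed seed gives byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (ApaEventRecord, DiffExprRecord, DnaPeak, EnrichedWindow,
                         GeneModel, SpliceEventRecord)
from .proteins import ProteinRecord

AA_BACKGROUND = "ACDEFGHILMNPQSTVWY"  # background residues: no K/R


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    n_chroms: int = 4
    intergenic_gap: tuple[int, int] = (5_000, 50_000)
    max_exons: int = 10


def _rng(cfg_seed: int, label: str) -> np.random.Generator:
    """Independent stream per generator: master seed + stable label hash."""
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(cfg_seed), spawn_key=(zlib.crc32(label.encode()),)))


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def make_annotation(cfg: SimConfig) -> dict[str, GeneModel]:
    """Random non-overlapping genes with 1-10 exons on both strands.

    Exon architecture follows the shape of typical protein-coding genes:
    a long terminal (transcription-order last) exon hosting the 3'UTR,
    shorter internal exons, and introns filling the rest. Exonic space is
    partitioned into 5'UTR / CDS / 3'UTR (roughly 15% / 70% / 15% in
    transcription order).
    """
    rng = _rng(cfg.seed, "annotation")
    lo, hi = cfg.gene_length_range
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    # feasibility at the shortest gene: internal exons need >= 80 bp of the
    # non-terminal exonic space, introns >= 150 bp of the intronic space
    exonic_lo, intronic_lo = int(0.55 * lo), lo - int(0.55 * lo)
    rest_lo = exonic_lo - int(0.45 * exonic_lo)
    if (cfg.max_exons - 1) * 80 > rest_lo or (cfg.max_exons - 1) * 150 > intronic_lo:
        raise ValueError(
            f"gene_length_range lower bound {lo} too small to host "
            f"{cfg.max_exons} exons")
    genes: dict[str, GeneModel] = {}
    cursors = {f"chr{i + 1}": 10_000 for i in range(cfg.n_chroms)}
    for i in range(cfg.n_genes):
        chrom = f"chr{1 + i % cfg.n_chroms}"
        length = int(rng.integers(lo, hi + 1))
        n_exons = int(rng.integers(1, cfg.max_exons + 1))
        exonic = int(0.55 * length)
        start = cursors[chrom] + int(rng.integers(*cfg.intergenic_gap))
        strand = "+" if rng.random() < 0.5 else "-"
        # exon widths in transcription order: terminal exon is long
        term_w = int(0.45 * exonic) if n_exons > 1 else exonic
        rest = exonic - term_w
        if n_exons > 1:
            # guarantee the 80 bp minimum, split the slack by Dirichlet
            slack = rest - 80 * (n_exons - 1)
            widths = 80 + (rng.dirichlet(np.ones(n_exons - 1)) * slack).astype(int)
            widths[-1] += rest - widths.sum()  # absorb rounding
            exon_widths = widths.tolist() + [term_w]
        else:
            exon_widths = [term_w]
        intronic = length - sum(exon_widths)
        if n_exons > 1:
            slack = intronic - 150 * (n_exons - 1)
            iw = 150 + (rng.dirichlet(np.ones(n_exons - 1)) * slack).astype(int)
            iw[-1] += intronic - iw.sum()
            intron_widths = iw.tolist()
        else:
            intron_widths = []
        # assemble genomic blocks; '-' strand reverses transcription order
        tx_widths = exon_widths if strand == "+" else exon_widths[::-1]
        tx_introns = intron_widths if strand == "+" else intron_widths[::-1]
        blocks = []
        pos = 0
        for j, w in enumerate(tx_widths):
            blocks.append((pos, pos + w))
            pos += w
            if j < len(tx_introns):
                pos += tx_introns[j]
        exons = [(start + s, start + e) for s, e in blocks]
        gene_id = f"G{i:04d}"
        exonic = sum(e - s for s, e in exons)
        u5_len = max(int(0.15 * exonic), 1)
        u3_len = max(int(0.15 * exonic), 1)
        utr5, cds, utr3 = _partition_transcript(exons, strand, u5_len, u3_len)
        genes[gene_id] = GeneModel(gene_id, chrom, strand, exons[0][0], exons[-1][1],
                                   exons, utr5=utr5, cds=cds, utr3=utr3)
        cursors[chrom] = exons[-1][1]
    return genes


def _partition_transcript(exons, strand, u5_len, u3_len):
    """Carve 5'UTR/CDS/3'UTR out of exonic space in transcription order."""
    # walk exonic bases in transcription order and label each base range
    order = exons if strand == "+" else exons[::-1]
    exonic = sum(e - s for s, e in exons)
    cds_len = exonic - u5_len - u3_len
    if cds_len <= 0:
        return [], [], []
    labels = [("utr5", u5_len), ("cds", cds_len), ("utr3", u3_len)]
    out = {"utr5": [], "cds": [], "utr3": []}
    tx = order
    pos = 0  # transcription-order offset
    bounds = np.cumsum([n for _, n in labels])
    for s, e in tx:
        for name, bound_start, bound_end in (
                ("utr5", 0, bounds[0]), ("cds", bounds[0], bounds[1]),
                ("utr3", bounds[1], bounds[2])):
            lo = max(pos, bound_start)
            hi = min(pos + (e - s), bound_end)
            if lo < hi:
                if strand == "+":
                    out[name].append((s + (lo - pos), s + (hi - pos)))
                else:
                    out[name].append((e - (hi - pos), e - (lo - pos)))
        pos += e - s
    for name in out:
        out[name] = sorted(out[name])
    return out["utr5"], out["cds"], out["utr3"]


# ---------------------------------------------------------------------------
# binding (eCLIP windows + Cut&Run peaks)
# ---------------------------------------------------------------------------

@dataclass
class BindingTruth:
    planted_feature: str
    planted_or: float
    planted_tss_bias: float
    tss_fraction: float
    base_feature_fraction: float
    p_in_ip: float


def _feature_intervals(gene: GeneModel, feature: str) -> list[tuple[int, int]]:
    return {"5'UTR": gene.utr5, "CDS": gene.cds, "3'UTR": gene.utr3}.get(feature, [])


def _interval_complement(gene: GeneModel, feature_ivs) -> list[tuple[int, int]]:
    """Gene-body intervals outside the feature."""
    out = []
    cursor = gene.start
    for s, e in sorted(feature_ivs):
        if cursor < s:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < gene.end:
        out.append((cursor, gene.end))
    return out


def _sample_position(rng, intervals) -> int:
    widths = np.array([e - s for s, e in intervals], dtype=float)
    i = rng.choice(len(intervals), p=widths / widths.sum())
    s, e = intervals[i]
    return int(rng.integers(s, e))


def simulate_binding(cfg: SimConfig, genes: dict[str, GeneModel],
                     planted_feature: str = "3'UTR", planted_or: float = 1.0,
                     planted_tss_bias: float = 1.0, n_windows: int = 2_000,
                     n_background: int | None = None, n_peaks: int = 600,
                     window_len: int = 50, tss_fraction: float = 0.5,
                     ) -> tuple[list[EnrichedWindow], list[EnrichedWindow],
                                list[DnaPeak], BindingTruth]:
    """Plant feature-class enrichment in eCLIP windows and TSS-proximal
    Cut&Run peaks.

    Window placement: background windows land uniformly over gene bodies;
    IP windows land inside the planted feature with in/out odds equal to
    ``planted_or`` times the background odds, so the 2x2 odds ratio of the
    planted feature equals ``planted_or`` in expectation. A TSS bias > 1
    instead multiplies the placement density of the first
    ``100/planted_tss_bias``-independent 3 percent of each transcript.
    Peaks: ``tss_fraction`` of peaks are centered within 1 kb of a TSS,
    the rest uniform over gene bodies.
    """
    if planted_or < 1:
        raise ValueError("planted_or must be >= 1")
    rng = _rng(cfg.seed, "binding")
    gene_list = list(genes.values())
    gene_weights = np.array([g.length for g in gene_list], dtype=float)
    gene_weights /= gene_weights.sum()

    feat_ivs = {g.gene_id: _feature_intervals(g, planted_feature) for g in gene_list}
    if planted_feature not in ("5'UTR", "CDS", "3'UTR"):
        raise ValueError(f"cannot plant into feature {planted_feature!r}")
    if not any(feat_ivs.values()):
        raise ValueError(f"planted feature {planted_feature!r} absent from annotation")
    total_feat = sum(e - s for ivs in feat_ivs.values() for s, e in ivs)
    total_len = float(sum(g.length for g in gene_list))
    f = total_feat / total_len  # base genomic fraction of the feature
    odds_bg = f / (1 - f)
    odds_ip = planted_or * odds_bg
    p_in = odds_ip / (1 + odds_ip)

    all_feat = [(g, iv) for g in gene_list for iv in feat_ivs[g.gene_id]]
    feat_w = np.array([e - s for _, (s, e) in all_feat], dtype=float)
    feat_w /= feat_w.sum()

    def uniform_window(bias: float) -> EnrichedWindow:
        # with TSS bias b, mass on the first 3% of the transcript is b*0.03
        g = gene_list[rng.choice(len(gene_list), p=gene_weights)]
        if rng.random() < bias * 0.03:
            frac = rng.random() * 0.03
        else:
            frac = 0.03 + rng.random() * 0.97
        if g.strand == "+":
            mid = g.start + frac * g.length
        else:
            mid = g.end - frac * g.length
        s = int(mid) - window_len // 2
        return EnrichedWindow(g.chrom, s, s + window_len, g.strand, g.gene_id,
                              odds_ratio=float(8 + rng.random() * 8),
                              fdr=float(rng.random() * 0.05))

    ip: list[EnrichedWindow] = []
    truth_in = 0
    for _ in range(n_windows):
        if rng.random() < p_in:
            truth_in += 1
            gi = rng.choice(len(all_feat), p=feat_w)
            g, (s, e) = all_feat[gi]
            mid = int(rng.integers(s, e))
            ws = mid - window_len // 2
            ip.append(EnrichedWindow(g.chrom, ws, ws + window_len, g.strand, g.gene_id,
                                     odds_ratio=float(8 + rng.random() * 8),
                                     fdr=float(rng.random() * 0.05)))
        else:
            g = gene_list[rng.choice(len(gene_list), p=gene_weights)]
            comp = _interval_complement(g, feat_ivs[g.gene_id])
            mid = _sample_position(rng, comp)
            ws = mid - window_len // 2
            ip.append(EnrichedWindow(g.chrom, ws, ws + window_len, g.strand, g.gene_id,
                                     odds_ratio=float(8 + rng.random() * 8),
                                     fdr=float(rng.random() * 0.05)))

    n_bg = n_background if n_background is not None else n_windows
    background = [uniform_window(1.0) for _ in range(n_bg)]
    if planted_tss_bias > 1:
        ip = [uniform_window(planted_tss_bias) for _ in range(n_windows)]

    peaks: list[DnaPeak] = []
    for j in range(n_peaks):
        g = gene_list[rng.choice(len(gene_list), p=gene_weights)]
        if rng.random() < tss_fraction:
            center = g.tss + int(rng.integers(-1_000, 1_001))
        else:
            center = int(rng.integers(g.start, g.end))
        s = max(center - 150, 0)
        peaks.append(DnaPeak(g.chrom, s, s + 300, name=f"peak{j}", score=100.0,
                             signal=float(5 + rng.random() * 10), pvalue=5.0, qvalue=3.0,
                             summit_offset=150, gene_id=g.gene_id,
                             dist_to_tss=int(center - g.tss) if g.strand == "+"
                             else int(g.tss - center)))
    truth = BindingTruth(planted_feature, planted_or, planted_tss_bias,
                         tss_fraction, f, p_in)
    return ip, background, peaks, truth


# ---------------------------------------------------------------------------
# knockdown differential tables + event-count matrix
# ---------------------------------------------------------------------------

@dataclass
class KdTruth:
    batch_of: dict[str, str]
    planted_counts: dict[str, dict[str, int]]       # zfp -> event_type -> count
    outlier_excess: dict[str, float]                # zfp -> planted excess fraction


def simulate_kd_tables(cfg: SimConfig, batch_means: dict[str, float],
                       datasets_per_batch: int = 8,
                       outlier_zfps: dict[str, tuple[str, float]] | None = None,
                       event_types: tuple[str, ...] = ("DEG", "ASE", "APAE"),
                       tables: bool = True,
                       ) -> tuple[pd.DataFrame, dict[str, dict], KdTruth]:
    """Per-ZFP differential tables plus the significant-event count matrix.

    Non-outlier ZFPs draw their per-event-type significant counts from
    Poisson(batch mean); an outlier's mean is inflated by its planted
    excess fraction. ``outlier_zfps`` maps a zfp id to (batch label,
    excess fraction). Returns (event-count matrix, per-zfp record tables,
    ground truth).
    """
    rng = _rng(cfg.seed, "kd_tables")
    outlier_zfps = outlier_zfps or {}
    for zfp, (batch, excess) in outlier_zfps.items():
        if batch not in batch_means:
            raise ValueError(f"unknown batch label {batch!r} for outlier {zfp!r}")
        if excess <= -1:
            raise ValueError("excess fraction must be > -1")
    rows = []
    out_tables: dict[str, dict] = {}
    batch_of: dict[str, str] = {}
    planted: dict[str, dict[str, int]] = {}
    excess_of: dict[str, float] = {}
    idx = 0
    placed_outliers = {batch: [(z, e) for z, (b, e) in outlier_zfps.items() if b == batch]
                       for batch in batch_means}
    for batch, mean in batch_means.items():
        specials = dict(placed_outliers[batch])
        names = list(specials)
        n_fill = datasets_per_batch - len(names)
        names += [f"ZFP{idx + j:03d}" for j in range(n_fill)]
        idx += n_fill
        for zfp in names:
            excess = specials.get(zfp, 0.0)
            lam = mean * (1 + excess)
            counts = {et: int(rng.poisson(lam)) for et in event_types}
            batch_of[zfp] = batch
            planted[zfp] = counts
            excess_of[zfp] = excess
            rows.append({"zfp_id": zfp, "batch": batch, **counts})
            if tables:
                out_tables[zfp] = _make_diff_tables(rng, cfg.n_genes, counts)
    truth = KdTruth(batch_of, planted, excess_of)
    return pd.DataFrame(rows), out_tables, truth


def _make_diff_tables(rng, n_genes, counts):
    """Differential tables whose significant rows number exactly ``counts``."""
    def expr_table(n_sig):
        recs = []
        sig = set(rng.choice(n_genes, size=min(n_sig, n_genes), replace=False))
        for g in range(n_genes):
            if g in sig:
                fdr = float(rng.uniform(1e-6, 0.049))
                lfc = float(rng.choice([-1, 1]) * rng.uniform(np.log2(1.3), 2.5))
            else:
                fdr = float(rng.uniform(0.05, 1.0))
                lfc = float(rng.normal(0, 0.1))
            recs.append(DiffExprRecord(f"G{g:04d}", lfc, fdr))
        return recs

    def splice_table(n_sig):
        recs = []
        sig = set(rng.choice(n_genes, size=min(n_sig, n_genes), replace=False))
        for g in range(n_genes):
            is_sig = g in sig
            fdr = float(rng.uniform(1e-6, 0.049)) if is_sig else float(rng.uniform(0.05, 1.0))
            dpsi = float(rng.choice([-1, 1]) * rng.uniform(0.25, 0.8)) if is_sig \
                else float(rng.uniform(-0.15, 0.15))
            j = int(rng.integers(1_000, 100_000))
            recs.append(SpliceEventRecord(f"SE{g:05d}", f"G{g:04d}", "SE",
                                          [j, j + 150], dpsi, fdr))
        return recs

    def apa_table(n_sig):
        recs = []
        sig = set(rng.choice(n_genes, size=min(n_sig, n_genes), replace=False))
        for g in range(n_genes):
            is_sig = g in sig
            fdr = float(rng.uniform(1e-6, 0.049)) if is_sig else float(rng.uniform(0.05, 1.0))
            dpsi = float(rng.choice([-1, 1]) * rng.uniform(0.25, 0.8)) if is_sig \
                else float(rng.uniform(-0.15, 0.15))
            recs.append(ApaEventRecord(f"G{g:04d}", dpsi, fdr))
        return recs

    return {"expr": expr_table(counts.get("DEG", 0)),
            "splice": splice_table(counts.get("ASE", 0)),
            "apa": apa_table(counts.get("APAE", 0))}


# ---------------------------------------------------------------------------
# SLAM-seq
# ---------------------------------------------------------------------------

@dataclass
class SlamTruth:
    half_lives: dict[str, float]
    depth: float
    library_total: float
    filter_fail_genes: set[str]


def simulate_slam(cfg: SimConfig, half_lives: dict[str, float], reps: int = 3,
                  timepoints: tuple = (0.0, 2.0, 4.0, 8.0), depth: float = 1_000.0,
                  library_total: float = 2e6, condition: str = "ctrl",
                  noise: bool = True) -> tuple[pd.DataFrame, SlamTruth]:
    """Per-gene T>C conversion counts decaying with the planted half-life.

    Counts are Poisson(depth * 2^(-t/hl)) (exact in no-noise mode);
    ``library_total`` is emitted per replicate for CPM computation. Genes
    whose expected CPM falls at or below the filter at any timepoint are
    recorded as filter-fail in the ground truth.
    """
    if any(hl <= 0 for hl in half_lives.values()):
        raise ValueError("half-lives must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(cfg.seed, f"slam:{condition}")
    rows = []
    fail = set()
    for gid, hl in half_lives.items():
        for t in timepoints:
            mu = depth * 2 ** (-t / hl)
            if mu * 1e6 / library_total <= 5.0:
                fail.add(gid)
            for r in range(1, reps + 1):
                conv = rng.poisson(mu) if noise else mu
                rows.append({"gene_id": gid, "condition": condition,
                             "timepoint_h": t, "replicate": r,
                             "tc_conversions": float(conv),
                             "library_total": library_total})
    return pd.DataFrame(rows), SlamTruth(dict(half_lives), depth, library_total, fail)


# ---------------------------------------------------------------------------
# RBNS pools
# ---------------------------------------------------------------------------

@dataclass
class RbnsTruth:
    pwm: np.ndarray
    consensus: str
    planted_fraction: float


def simulate_rbns(cfg: SimConfig, pwm: np.ndarray, planted_fraction: float = 0.3,
                  n_reads: int = 50_000, read_len: int = 20,
                  ) -> tuple[list[str], list[str], RbnsTruth]:
    """Uniform input pool; pulldown pool with a PWM draw planted in a
    fraction of reads at a uniform internal position. Sequences are RNA
    (ACGU)."""
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0,1]")
    motif_len = pwm.shape[0]
    if motif_len > read_len:
        raise ValueError("motif longer than read length")
    rng = _rng(cfg.seed, "rbns")
    bases = np.array(list("ACGU"))
    pwm = np.asarray(pwm, dtype=float)
    pwm = pwm / pwm.sum(axis=1, keepdims=True)

    def random_reads(n):
        idx = rng.integers(0, 4, size=(n, read_len))
        return ["".join(r) for r in bases[idx]]

    input_pool = random_reads(n_reads)
    pulldown = random_reads(n_reads)
    n_plant = int(round(planted_fraction * n_reads))
    plant_at = rng.choice(n_reads, size=n_plant, replace=False)
    for i in plant_at:
        pos = int(rng.integers(0, read_len - motif_len + 1))
        draw = "".join(bases[rng.choice(4, p=pwm[j])] for j in range(motif_len))
        read = pulldown[i]
        pulldown[i] = read[:pos] + draw + read[pos + motif_len:]
    consensus = "".join("ACGU"[i] for i in pwm.argmax(axis=1))
    return pulldown, input_pool, RbnsTruth(pwm, consensus, planted_fraction)


def consensus_pwm(consensus: str, strength: float = 0.9) -> np.ndarray:
    """One-hot-ish PWM for a consensus string (off-consensus mass split)."""
    pwm = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, b in enumerate(consensus.replace("T", "U")):
        pwm[i, "ACGU".index(b)] = strength
    return pwm


# ---------------------------------------------------------------------------
# Ribo-STAMP EPR and tethering
# ---------------------------------------------------------------------------

@dataclass
class EprTruth:
    effect_genes: dict[str, float]
    baseline_epr: dict[str, float]


def simulate_epr(cfg: SimConfig, n_genes: int = 1_000,
                 effect_genes: dict[str, float] | None = None, reps: int = 2,
                 mean_exon_reads: float = 20_000.0, baseline_epr: float = 0.05,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, EprTruth]:
    """Per-gene edit and exonic read counts for 2 KD + 2 control samples.

    Edits ~ Poisson(epr_g * exon_reads), with the KD epr scaled by the
    planted ratio for effect genes.
    """
    if reps < 2:
        raise ValueError("need >= 2 replicates per condition")
    effect_genes = effect_genes or {}
    if any(r <= 0 for r in effect_genes.values()):
        raise ValueError("planted EPR ratios must be positive")
    rng = _rng(cfg.seed, "epr")
    samples = [f"kd_{r}" for r in range(1, reps + 1)] + \
              [f"ctrl_{r}" for r in range(1, reps + 1)]
    base = {}
    edit_rows, count_rows = [], []
    for g in range(n_genes):
        gid = f"G{g:04d}"
        epr_g = float(baseline_epr * rng.lognormal(0, 0.5))
        base[gid] = epr_g
        ratio = effect_genes.get(gid, 1.0)
        for s in samples:
            reads = float(rng.poisson(mean_exon_reads))
            rate = epr_g * (ratio if s.startswith("kd") else 1.0)
            edits = float(rng.poisson(rate * max(reads, 1.0)))
            edit_rows.append({"gene_id": gid, "sample": s, "edits": edits})
            count_rows.append({"gene_id": gid, "sample": s, "exon_reads": reads})
    return (pd.DataFrame(edit_rows), pd.DataFrame(count_rows),
            EprTruth(dict(effect_genes), base))


@dataclass
class TetheringTruth:
    effect_constructs: dict[str, float]


def simulate_tethering(cfg: SimConfig, effect_constructs: dict[str, float] | None = None,
                       n_null_constructs: int = 0, reps: int = 3,
                       cv: float = 0.1) -> tuple[pd.DataFrame, TetheringTruth]:
    """Firefly/Renilla luminescence wells, lognormal around construct means.

    ``effect_constructs`` maps construct id to its true mean ratio relative
    to the control construct (which is always emitted, at ratio 1).
    """
    effect_constructs = effect_constructs or {}
    if any(r <= 0 for r in effect_constructs.values()):
        raise ValueError("planted ratios must be positive")
    rng = _rng(cfg.seed, "tethering")
    sigma = np.sqrt(np.log(1 + cv ** 2))
    constructs = {"control": 1.0, **effect_constructs,
                  **{f"null{i:03d}": 1.0 for i in range(n_null_constructs)}}
    rows = []
    for cid, ratio in constructs.items():
        for r in range(1, reps + 1):
            renilla = float(rng.lognormal(np.log(1_000), sigma))
            firefly = float(ratio * renilla * rng.lognormal(0, sigma))
            rows.append({"construct_id": cid, "replicate": r,
                         "firefly": firefly, "renilla": renilla,
                         "reporter": "stability"})
    return pd.DataFrame(rows), TetheringTruth(dict(effect_constructs))


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

@dataclass
class ProteinTruth:
    arm_loci: dict[str, set[int]]
    rbd_intervals: dict[str, list[tuple[int, int]]]
    idr_intervals: dict[str, list[tuple[int, int]]]


def simulate_proteins(cfg: SimConfig, n_proteins: int = 5, length: int = 400,
                      planted_arm_loci: dict[str, list[tuple[int, int]]] | None = None,
                      planted_rbd_intervals: dict[str, list[tuple[int, int]]] | None = None,
                      planted_idr_intervals: dict[str, list[tuple[int, int]]] | None = None,
                      ) -> tuple[dict[str, ProteinRecord], ProteinTruth]:
    """Random protein sequences with planted ARM runs, occlusion-Z dips,
    and disorder stretches.

    ``planted_arm_loci`` maps protein id to [start, end) center ranges:
    a solid K/R run is written over each range (padded by K/R-free
    flanks), so the qualifying window centers are exactly that range.
    ``planted_rbd_intervals`` get occlusion Z drawn below -1 (background
    stays >= -1); ``planted_idr_intervals`` get disorder > 0.4
    (background below).
    """
    planted_arm_loci = planted_arm_loci or {}
    planted_rbd_intervals = planted_rbd_intervals or {}
    planted_idr_intervals = planted_idr_intervals or {}
    rng = _rng(cfg.seed, "proteins")
    bg = np.array(list(AA_BACKGROUND))
    proteins: dict[str, ProteinRecord] = {}
    truth = ProteinTruth({}, {}, {})
    for i in range(n_proteins):
        pid = f"P{i:02d}"
        seq = list(bg[rng.integers(0, len(bg), size=length)])
        arms = sorted(planted_arm_loci.get(pid, []))
        for (s1, e1), (s2, e2) in zip(arms, arms[1:]):
            if s2 - e1 < 5:
                raise ValueError(f"{pid}: planted ARM runs closer than 5 residues conflict")
        for s, e in arms:
            if e - s < 3:
                raise ValueError(f"{pid}: ARM center range [{s},{e}) shorter than 3 residues")
            if not (2 <= s and e <= length - 2):
                raise ValueError(f"{pid}: ARM center range [{s},{e}) too close to a terminus")
            for j in range(s, e):
                seq[j] = "K" if (j - s) % 2 == 0 else "R"
        # occlusion Z: background in (-0.9, 0.9), dips in (-2.5, -1.1)
        occ = rng.uniform(-0.9, 0.9, size=length)
        rbds = planted_rbd_intervals.get(pid, [])
        for s, e in rbds:
            if not (0 <= s < e <= length):
                raise ValueError(f"{pid}: RBD interval [{s},{e}) outside sequence")
            occ[s:e] = rng.uniform(-2.5, -1.1, size=e - s)
        dis = rng.uniform(0.0, 0.35, size=length)
        idrs = planted_idr_intervals.get(pid, [])
        for s, e in idrs:
            dis[s:e] = rng.uniform(0.45, 0.95, size=e - s)
        proteins[pid] = ProteinRecord(pid, "".join(seq), occ, dis)
        truth.arm_loci[pid] = {c for s, e in arms for c in range(s, e)}
        truth.rbd_intervals[pid] = sorted(rbds)
        truth.idr_intervals[pid] = sorted(idrs)
    return proteins, truth
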
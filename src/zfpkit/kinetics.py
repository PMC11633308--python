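"""SLAM-seq decay kinetics and Ribo-STAMP edits-per-read statistics.

SLAM-seq: per gene, T>C conversion counts at chase timepoints 0/2/4/8 h
are filtered (CPM > 5 in at least 2 replicates at every timepoint),
averaged over the retained replicates, normalized to t=0, and fitted with
a first-order decay y(t) = exp(-k t) by nonlinear least squares. Genes
with R^2 > 0.6 (and k > 0) pass; half-life = ln 2 / k. Half-life shifts
between knockdown and control are tested per target set with a two-sided
Mann-Whitney U.

Ribo-STAMP: EPR = edits / exonic read count per gene and sample; genes
with zero edits in any of the four samples (2 knockdown + 2 control) are
excluded; a two-tailed independent t-test per gene with Benjamini-
Hochberg correction calls differential ribosome association at FDR < 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

TIMEPOINTS = (0.0, 2.0, 4.0, 8.0)
CPM_MIN = 5.0
MIN_REPS = 2
R2_MIN = 0.6
EPR_FDR = 0.1


@dataclass
class SlamGeneSeries:
    """Per-gene conversion counts over (timepoint, replicate)."""
    gene_id: str
    condition: str
    # maps (timepoint, replicate) -> (tc_conversions, library_total)
    counts: dict[tuple[float, int], tuple[float, float]] = field(default_factory=dict)

    def cpm(self, t: float, rep: int) -> float:
        conv, total = self.counts[(t, rep)]
        return conv * 1e6 / total

    def replicates(self) -> list[int]:
        return sorted({rep for _, rep in self.counts})


@dataclass
class DecayFit:
    gene_id: str
    condition: str
    k: float
    half_life: float
    r_squared: float
    passed: bool
    reason: str = ""


@dataclass
class EprRecord:
    gene_id: str
    sample: str
    edits: float
    exon_reads: float

    @property
    def epr(self) -> float:
        return self.edits / self.exon_reads


def read_slam_table(df: pd.DataFrame) -> dict[str, SlamGeneSeries]:
    """Build per-gene series from a long TSV frame with columns gene_id,
    condition, timepoint_h, replicate, tc_conversions, library_total."""
    series: dict[str, SlamGeneSeries] = {}
    for row in df.itertuples(index=False):
        key = row.gene_id
        s = series.setdefault(key, SlamGeneSeries(row.gene_id, row.condition))
        s.counts[(float(row.timepoint_h), int(row.replicate))] = (
            float(row.tc_conversions), float(row.library_total))
    return series


def filter_slam_genes(series: dict[str, SlamGeneSeries], cpm_min: float = CPM_MIN,
                      min_reps: int = MIN_REPS,
                      timepoints: tuple = TIMEPOINTS) -> dict[str, SlamGeneSeries]:
    """Retain genes with >= min_reps replicates passing CPM > cpm_min at
    every timepoint; retained replicates are exactly those passing at all
    timepoints. Genes with a missing timepoint are dropped (tallied on
    ``filter_slam_genes.n_incomplete``)."""
    kept: dict[str, SlamGeneSeries] = {}
    n_incomplete = 0
    for gid, s in series.items():
        reps = s.replicates()
        if not all((t, r) in s.counts for t in timepoints for r in reps):
            n_incomplete += 1
            continue
        passing = [r for r in reps
                   if all(s.cpm(t, r) > cpm_min for t in timepoints)]
        if len(passing) >= min_reps:
            trimmed = SlamGeneSeries(s.gene_id, s.condition, {
                (t, r): s.counts[(t, r)] for t in timepoints for r in passing})
            kept[gid] = trimmed
    filter_slam_genes.n_incomplete = n_incomplete
    return kept


filter_slam_genes.n_incomplete = 0


def fit_decay(series: SlamGeneSeries, timepoints: tuple = TIMEPOINTS,
              r2_min: float = R2_MIN, k_tol: float = 1e-9) -> DecayFit:
    """First-order decay fit on replicate-averaged, t0-normalized CPM."""
    reps = series.replicates()
    t = np.asarray(timepoints, dtype=float)
    y_mean = np.array([np.mean([series.cpm(tp, r) for r in reps]) for tp in t])
    if y_mean[0] <= 0:
        return DecayFit(series.gene_id, series.condition, math.nan, math.nan,
                        math.nan, False, reason="zero signal at t=0")
    y = y_mean / y_mean[0]

    # log-linear initial guess, refined by nonlinear least squares
    with np.errstate(divide="ignore"):
        pos = y > 0
        k0 = 0.1
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
            k0 = max(-slope, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            (k,), _ = optimize.curve_fit(lambda tt, k: np.exp(-k * tt), t, y,
                                         p0=[k0], maxfev=10_000)
    except RuntimeError:
        return DecayFit(series.gene_id, series.condition, math.nan, math.nan,
                        math.nan, False, reason="fit did not converge")
    resid = y - np.exp(-k * t)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if k <= k_tol:
        return DecayFit(series.gene_id, series.condition, float(k), math.inf, r2,
                        False, reason="no decay (k <= 0)")
    hl = math.log(2) / k
    return DecayFit(series.gene_id, series.condition, float(k), hl, r2,
                    passed=r2 > r2_min)


def fit_all(series: dict[str, SlamGeneSeries], **kwargs) -> dict[str, DecayFit]:
    return {gid: fit_decay(s, **kwargs) for gid, s in series.items()}


@dataclass
class HalfLifeShiftResult:
    n_targets_kd: int
    n_targets_ctrl: int
    u_statistic: float
    p_value: float
    median_shift_h: float
    nontarget_p_value: float | None


def half_life_shift_test(fits_kd: dict[str, DecayFit], fits_ctrl: dict[str, DecayFit],
                         target_genes: set[str], min_genes: int = 5) -> HalfLifeShiftResult:
    """Two-sided Mann-Whitney U on passed target half-lives, KD vs control.

    Also reports the same test on non-target genes as a specificity
    control (None when too few non-targets pass).
    """
    def passed_hl(fits, genes):
        return [f.half_life for g, f in fits.items()
                if g in genes and f.passed and math.isfinite(f.half_life)]

    hl_kd = passed_hl(fits_kd, target_genes)
    hl_ctrl = passed_hl(fits_ctrl, target_genes)
    if len(hl_kd) < min_genes or len(hl_ctrl) < min_genes:
        raise ValueError(
            f"insufficient passed target fits: {len(hl_kd)} KD, {len(hl_ctrl)} control "
            f"(need {min_genes} per side)")
    u, p = stats.mannwhitneyu(hl_kd, hl_ctrl, alternative="two-sided")
    shift = float(np.median(hl_kd) - np.median(hl_ctrl))
    nontargets = (set(fits_kd) | set(fits_ctrl)) - target_genes
    nt_kd = passed_hl(fits_kd, nontargets)
    nt_ctrl = passed_hl(fits_ctrl, nontargets)
    nt_p = None
    if len(nt_kd) >= min_genes and len(nt_ctrl) >= min_genes:
        nt_p = float(stats.mannwhitneyu(nt_kd, nt_ctrl, alternative="two-sided").pvalue)
    return HalfLifeShiftResult(len(hl_kd), len(hl_ctrl), float(u), float(p), shift, nt_p)


# ---------------------------------------------------------------------------
# Ribo-STAMP EPR
# ---------------------------------------------------------------------------

def compute_epr(edits: pd.DataFrame, exon_counts: pd.DataFrame) -> list[EprRecord]:
    """Join per-gene edit and exonic read counts into EPR records.

    Both frames need columns gene_id, sample plus ``edits`` /
    ``exon_reads``. Genes with zero exonic reads in a sample are excluded
    (tallied on ``compute_epr.n_zero_exon``).
    """
    merged = edits.merge(exon_counts, on=["gene_id", "sample"], how="inner")
    records = []
    n_zero = 0
    for row in merged.itertuples(index=False):
        if row.exon_reads <= 0:
            n_zero += 1
            continue
        records.append(EprRecord(row.gene_id, row.sample,
                                 float(row.edits), float(row.exon_reads)))
    compute_epr.n_zero_exon = n_zero
    return records


compute_epr.n_zero_exon = 0


def differential_epr(records: list[EprRecord], kd_samples: list[str],
                     ctrl_samples: list[str], fdr_cut: float = EPR_FDR) -> pd.DataFrame:
    """Per-gene two-tailed t-test on EPR (KD vs control) with BH correction.

    Genes must have nonzero edits in all four samples to be tested.
    Returns a frame with epr means, log2 ratio, p, q and a significance
    flag at FDR < ``fdr_cut``.
    """
    if len(kd_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("need at least 2 samples per condition")
    samples = list(kd_samples) + list(ctrl_samples)
    by_gene: dict[str, dict[str, EprRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.sample] = r
    rows = []
    for gid, per_sample in sorted(by_gene.items()):
        if not all(s in per_sample and per_sample[s].edits > 0 for s in samples):
            continue
        kd = [per_sample[s].epr for s in kd_samples]
        ctrl = [per_sample[s].epr for s in ctrl_samples]
        t, p = stats.ttest_ind(kd, ctrl, equal_var=True)
        rows.append({"gene_id": gid, "epr_kd": np.mean(kd), "epr_ctrl": np.mean(ctrl),
                     "log2_ratio": float(np.log2(np.mean(kd) / np.mean(ctrl))),
                     "p_value": float(p)})
    df = pd.DataFrame(rows, columns=["gene_id", "epr_kd", "epr_ctrl", "log2_ratio", "p_value"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["q_value"] < fdr_cut
    else:
        df["q_value"] = []
        df["significant"] = []
    return df
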
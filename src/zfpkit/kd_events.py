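"""Significant-event calling per knockdown and batch-residual outlier
detection.

Each knockdown dataset yields counts of significant differential expression
(DEG), splicing (ASE) and polyadenylation (APAE) events. Because knockdowns
were processed in experimental batches whose baseline event counts differ by
an order of magnitude, a knockdown is only called "high-residual" relative
to a least-squares fit of counts on batch membership: with batch indicator
covariates (cell-means coding) the fitted value is the batch mean, and the
per-dataset outlier test is the externally studentized residual referred to
a t distribution. A dataset is flagged when the (two-sided by default)
p-value is below 0.05 *and* its residual exceeds +20% of the predicted
count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ApaEventRecord, DiffExprRecord, SpliceEventRecord

DEG_FDR = 0.05
DEG_MIN_FC = 1.2          # |FC| > 20%  <=>  |log2fc| > log2(1.2)
PSI_FDR = 0.05
PSI_MIN_DELTA = 0.2       # |delta PSI| > 20%
RESIDUAL_P = 0.05
RESIDUAL_MIN_PCT = 20.0


@dataclass
class SignificantEvents:
    degs: set[str]
    ases: set[str]
    apaes: set[str]
    n_nan_excluded: int

    @property
    def counts(self) -> dict[str, int]:
        return {"DEG": len(self.degs), "ASE": len(self.ases), "APAE": len(self.apaes)}


@dataclass
class ResidualResult:
    zfp_id: str
    event_type: str
    observed: float
    predicted: float
    residual_pct_fc: float
    p_value: float
    flagged: bool


def call_significant_events(expr: list[DiffExprRecord],
                            splice: list[SpliceEventRecord],
                            apa: list[ApaEventRecord]) -> SignificantEvents:
    """Apply the significance thresholds to each differential table.

    DEG: FDR < 0.05 and |log2FC| > log2(1.2). ASE/APAE: FDR < 0.05 and
    |dPSI| > 0.2. Records with NaN FDR are excluded and tallied.
    """
    n_nan = 0
    degs, ases, apaes = set(), set(), set()
    for r in expr:
        if math.isnan(r.fdr):
            n_nan += 1
        elif r.fdr < DEG_FDR and abs(r.log2fc) > math.log2(DEG_MIN_FC):
            degs.add(r.gene_id)
    for s in splice:
        if math.isnan(s.fdr):
            n_nan += 1
        elif s.fdr < PSI_FDR and abs(s.delta_psi) > PSI_MIN_DELTA:
            ases.add(s.event_id)
    for a in apa:
        if math.isnan(a.fdr):
            n_nan += 1
        elif a.fdr < PSI_FDR and abs(a.delta_psi) > PSI_MIN_DELTA:
            apaes.add(a.gene_id)
    if n_nan:
        warnings.warn(f"{n_nan} records with NaN FDR excluded")
    return SignificantEvents(degs, ases, apaes, n_nan)


def fit_batch_residuals(matrix: pd.DataFrame, event_type: str,
                        two_sided: bool = True) -> list[ResidualResult]:
    """Fit counts ~ batch (OLS, cell-means coding) and test each dataset.

    ``matrix`` needs columns zfp_id, batch, and one column per event type
    holding the significant-event count. The fitted value for a dataset is
    its batch mean; the p-value comes from the externally studentized
    residual against t(n - k - 1) where k is the number of batches.
    """
    required = {"zfp_id", "batch", event_type}
    missing = required - set(matrix.columns)
    if missing:
        raise ValueError(f"event-count matrix missing columns {sorted(missing)}")
    counts = matrix[event_type].to_numpy(dtype=float)
    batches = matrix["batch"].to_numpy()
    labels = pd.unique(batches)
    if len(labels) < 2:
        raise ValueError("need at least 2 batches to fit a batch model")
    sizes = {lab: int((batches == lab).sum()) for lab in labels}
    singletons = [lab for lab, n in sizes.items() if n < 2]
    if singletons:
        raise ValueError(f"batches with a single dataset (no within-batch variance): {singletons}")

    n = len(counts)
    k = len(labels)
    means = {lab: counts[batches == lab].mean() for lab in labels}
    predicted = np.array([means[lab] for lab in batches])
    if np.any(predicted <= 0):
        raise ValueError("non-positive predicted count; batch means must be positive")
    resid = counts - predicted
    # residual variance of the cell-means OLS fit
    df_resid = n - k
    s2 = float(resid @ resid) / df_resid
    leverage = np.array([1.0 / sizes[lab] for lab in batches])
    results: list[ResidualResult] = []
    for i, (zfp, lab) in enumerate(zip(matrix["zfp_id"], batches)):
        # externally studentized residual: leave-one-out variance estimate
        s2_i = (s2 * df_resid - resid[i] ** 2 / (1 - leverage[i])) / (df_resid - 1)
        t_i = resid[i] / math.sqrt(s2_i * (1 - leverage[i])) if s2_i > 0 else 0.0
        if two_sided:
            p = 2 * stats.t.sf(abs(t_i), df_resid - 1)
        else:
            p = stats.t.sf(t_i, df_resid - 1)
        pct = 100.0 * resid[i] / predicted[i]
        flagged = (p < RESIDUAL_P) and (pct > RESIDUAL_MIN_PCT)
        results.append(ResidualResult(str(zfp), event_type, counts[i], predicted[i],
                                      pct, float(p), flagged))
    return results


def flag_high_residual(results: list[ResidualResult]) -> list[ResidualResult]:
    """Subset of results with p < 0.05 and residual percent FC > 20."""
    return [r for r in results
            if r.p_value < RESIDUAL_P and r.residual_pct_fc > RESIDUAL_MIN_PCT]


def model_fit_pvalue(matrix: pd.DataFrame, event_type: str) -> float:
    """Overall F-test p-value of the batch model (reported, not used to flag)."""
    counts = matrix[event_type].to_numpy(dtype=float)
    batches = matrix["batch"].to_numpy()
    labels = pd.unique(batches)
    groups = [counts[batches == lab] for lab in labels]
    return float(stats.f_oneway(*groups).pvalue)
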
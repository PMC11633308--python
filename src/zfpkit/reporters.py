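"""Tethering-reporter statistics for the stability/translation reporter
and the splicing minigene reporters.

Wells report firefly and Renilla luminescence; the per-well ratio is
normalized to the mean ratio of a control construct, and a construct is a
hit when a one-tailed independent t-test in the expected direction gives
p < 0.05. For the splicing minigenes the tested quantity is an inclusion
proxy, 100 * firefly / (firefly + renilla).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

HIT_P = 0.05
MIN_REPS = 3


@dataclass
class LuminescenceWell:
    construct_id: str
    replicate: int
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.renilla <= 0:
            raise ValueError(
                f"well {self.construct_id}/{self.replicate}: renilla must be positive")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla

    @property
    def inclusion_proxy(self) -> float:
        return 100.0 * self.firefly / (self.firefly + self.renilla)


@dataclass
class TetheringResult:
    construct_id: str
    direction: str
    t_statistic: float
    p_value: float
    hit: bool


def normalize_ratios(wells: list[LuminescenceWell],
                     control_construct: str = "control") -> dict[str, list[float]]:
    """Per-construct firefly/Renilla ratios normalized to the control mean."""
    control = [w.ratio for w in wells if w.construct_id == control_construct]
    if len(control) < 2:
        raise ValueError(f"control construct {control_construct!r} needs >= 2 wells, "
                         f"found {len(control)}")
    baseline = float(np.mean(control))
    out: dict[str, list[float]] = {}
    for w in wells:
        out.setdefault(w.construct_id, []).append(w.ratio / baseline)
    return out


def tethering_test(normalized_test: list[float], normalized_control: list[float],
                   direction: str = "increase",
                   construct_id: str = "") -> TetheringResult:
    """One-tailed independent t-test of test vs control values.

    ``direction`` 'increase' (or 'psi_increase') tests for larger values
    in the test construct, 'decrease' for smaller.
    """
    if direction not in ("increase", "decrease", "psi_increase"):
        raise ValueError(f"unknown direction {direction!r}")
    if len(normalized_test) < MIN_REPS or len(normalized_control) < MIN_REPS:
        raise ValueError("need at least 3 replicates per side")
    alternative = "less" if direction == "decrease" else "greater"
    t, p = stats.ttest_ind(normalized_test, normalized_control,
                           equal_var=True, alternative=alternative)
    return TetheringResult(construct_id, direction, float(t), float(p), bool(p < HIT_P))


def splice_reporter_test(test_wells: list[LuminescenceWell],
                         control_wells: list[LuminescenceWell],
                         direction: str = "psi_increase",
                         construct_id: str = "") -> TetheringResult:
    """Tethering test on the minigene inclusion proxy instead of the ratio."""
    return tethering_test([w.inclusion_proxy for w in test_wells],
                          [w.inclusion_proxy for w in control_wells],
                          direction=direction, construct_id=construct_id)
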
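"""Triplicate spot-reliability filter.

Intra-array consistency of each substrate's replicate spots is assessed with
two indexes: SD/A (sample standard deviation over mean, i.e. the replicate
coefficient of variation) and A/M (mean over median; values far from 1 flag
an outlier replicate skewing the mean). A substrate passes a chip only if
SD/A < 0.20 and 0.80 < A/M < 1.20 (strict inequalities); a substrate that
fails on ANY chip in the experiment is rejected from further analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ConsistencyError, DegenerateInputError


@dataclass(frozen=True)
class QCThresholds:
    """Reliability cut-offs; defaults are the pipeline's standard constants."""

    sd_over_avg_max: float = 0.20
    am_low: float = 0.80
    am_high: float = 1.20
    strict: bool = True  # strict inequalities at every boundary

    def __post_init__(self) -> None:
        if self.sd_over_avg_max <= 0 or not 0 < self.am_low < self.am_high:
            raise ValueError("invalid QC thresholds")


@dataclass(frozen=True)
class ChipQC:
    chip_id: str
    sd_over_avg: float
    avg_over_median: float
    passed: bool
    reason: str  # ok | sd_fail | am_low | am_high | degenerate


@dataclass(frozen=True)
class QCVerdict:
    substrate_id: str
    per_chip: tuple[ChipQC, ...]
    rejected: bool


def qc_stats(replicates: Sequence[float]) -> tuple[float, float]:
    """Return (SD/A, A/M) for one substrate's replicate spots on one chip.

    SD uses the sample (n-1) estimator; median of an even count is the mean
    of the two central values. Raises DegenerateInputError when mean <= 0 or
    median == 0 (the ratios are undefined; callers auto-reject).
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 replicates")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite replicate intensity")
    mean = float(x.mean())
    median = float(np.median(x))
    if mean <= 0 or median == 0:
        raise DegenerateInputError("mean <= 0 or median == 0")
    sd = float(x.std(ddof=1))
    return sd / mean, mean / median


def _judge(sd_a: float, a_m: float, th: QCThresholds) -> tuple[bool, str]:
    if th.strict:
        sd_ok = sd_a < th.sd_over_avg_max
        am_low_ok = a_m > th.am_low
        am_high_ok = a_m < th.am_high
    else:
        sd_ok = sd_a <= th.sd_over_avg_max
        am_low_ok = a_m >= th.am_low
        am_high_ok = a_m <= th.am_high
    if not sd_ok:
        return False, "sd_fail"
    if not am_low_ok:
        return False, "am_low"
    if not am_high_ok:
        return False, "am_high"
    return True, "ok"


def apply_filter(
    chips: Mapping[str, pd.DataFrame],
    thresholds: QCThresholds = QCThresholds(),
) -> list[QCVerdict]:
    """Apply the reliability filter across chips; reject on any failure.

    ``chips`` maps chip_id -> replicate matrix (substrate x replicate
    columns, as produced by IntensitySet.replicate_matrix). All chips must
    cover the same substrates.
    """
    if not chips:
        raise ConsistencyError("no chips supplied")
    items = list(chips.items())
    reference = list(items[0][1].index)
    for chip_id, mat in items[1:]:
        if set(mat.index) != set(reference):
            raise ConsistencyError(f"chip {chip_id!r} covers a different substrate set")

    verdicts = []
    for substrate in reference:
        per_chip = []
        for chip_id, mat in items:
            reps = mat.loc[substrate].to_numpy(dtype=float)
            reps = reps[~np.isnan(reps)]
            try:
                sd_a, a_m = qc_stats(reps)
            except DegenerateInputError:
                per_chip.append(ChipQC(chip_id, float("nan"), float("nan"),
                                       False, "degenerate"))
                continue
            passed, reason = _judge(sd_a, a_m, thresholds)
            per_chip.append(ChipQC(chip_id, sd_a, a_m, passed, reason))
        rejected = any(not c.passed for c in per_chip)
        verdicts.append(QCVerdict(substrate, tuple(per_chip), rejected))
    return verdicts


def passing_substrates(verdicts: Sequence[QCVerdict]) -> list[str]:
    return [v.substrate_id for v in verdicts if not v.rejected]


def verdicts_table(verdicts: Sequence[QCVerdict]) -> pd.DataFrame:
    """Long-format audit table: one row per substrate x chip."""
    rows = []
    for v in verdicts:
        for c in v.per_chip:
            rows.append((v.substrate_id, c.chip_id, c.sd_over_avg,
                         c.avg_over_median, c.passed, c.reason, v.rejected))
    return pd.DataFrame(rows, columns=["substrate_id", "chip_id", "sd_over_avg",
                                       "avg_over_median", "passed", "reason",
                                       "rejected"])
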
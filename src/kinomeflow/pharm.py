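"""Companion pharmacology computations.

IC50 from MTT dose-response data via the logarithmic trend line (ordinary
least squares of mean viability on log10 concentration), chemosensitization
comparison by Welch t-test, and annexin-V/7-AAD quadrant classification of
flow-cytometry events. Viability values are expected as percent of the
drug-free control; normalization is the caller's responsibility.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import InvalidParameterError, UndefinedIC50Error
from .differential import welch_t_test

QUADRANT_NAMES = ("live", "early_apoptosis", "late_apoptosis",
                  "non_apoptotic_death")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Concentration series (uM) with replicate viabilities (% of control)."""

    concentrations: np.ndarray          # shape (n_conc,)
    viabilities: np.ndarray             # shape (n_conc, n_reps)
    ic50: float | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viabilities, dtype=float))
        if np.any(conc <= 0):
            raise InvalidParameterError("concentrations must be positive")
        if viab.shape[0] != conc.size:
            raise InvalidParameterError("one viability row per concentration")
        if np.any(viab < 0):
            raise InvalidParameterError("viabilities must be >= 0")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "viabilities", viab)

    def mean_viability(self) -> np.ndarray:
        return self.viabilities.mean(axis=1)

    def to_tsv(self, path) -> None:
        rows = []
        for c, reps in zip(self.concentrations, self.viabilities):
            for j, v in enumerate(reps):
                rows.append((c, j, v))
        pd.DataFrame(rows, columns=["concentration_uM", "replicate",
                                    "viability_pct"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DoseResponseCurve":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="concentration_uM", columns="replicate",
                        values="viability_pct").sort_index()
        return cls(wide.index.to_numpy(), wide.to_numpy())


@dataclass(frozen=True)
class IC50Fit:
    ic50: float          # uM
    slope: float         # viability % per decade of concentration
    intercept: float     # viability % at 1 uM
    extrapolated: bool   # IC50 outside the tested concentration range


def estimate_ic50(
    curve: DoseResponseCurve, allow_extrapolation: bool = True
) -> IC50Fit:
    """IC50 from the logarithmic trend line of the cytotoxicity graph.

    Fits mean viability = a + b * log10(concentration) by least squares and
    solves for 50% viability: IC50 = 10 ** ((50 - a) / b). A flat or rising
    trend (b >= 0) admits no IC50 and raises UndefinedIC50Error. A solution
    outside the tested concentration range is flagged ``extrapolated`` (and
    raises instead when ``allow_extrapolation`` is False).
    """
    conc = curve.concentrations
    if np.unique(conc).size < 2:
        raise InvalidParameterError("need at least 2 distinct concentrations")
    y = curve.mean_viability()
    if np.ptp(y) == 0:
        raise UndefinedIC50Error("flat curve: mean viabilities are all equal")
    x = np.log10(conc)
    b, a = np.polyfit(x, y, 1)
    if b >= 0:
        raise UndefinedIC50Error(
            "viability does not decrease with concentration (slope >= 0)"
        )
    ic50 = float(10.0 ** ((50.0 - a) / b))
    extrapolated = not (float(conc.min()) <= ic50 <= float(conc.max()))
    if extrapolated and not allow_extrapolation:
        raise UndefinedIC50Error(
            f"IC50 {ic50:.3g} uM falls outside the tested range"
        )
    return IC50Fit(ic50=ic50, slope=float(b), intercept=float(a),
                   extrapolated=extrapolated)


def fit_four_param_logistic(curve: DoseResponseCurve) -> dict:
    """Alternative 4PL estimator (not the trend-line method; offered for
    comparison). Returns dict with top, bottom, ic50, hill."""
    from scipy.optimize import curve_fit

    def fourpl(logc, top, bottom, logic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - logic50)))

    x = np.log10(curve.concentrations)
    y = curve.mean_viability()
    p0 = (float(y.max()), float(y.min()), float(np.median(x)), 1.0)
    popt, _ = curve_fit(fourpl, x, y, p0=p0, maxfev=20000)
    top, bottom, logic50, hill = popt
    return {"top": float(top), "bottom": float(bottom),
            "ic50": float(10.0 ** logic50), "hill": float(hill)}


@dataclass(frozen=True)
class SensitizationResult:
    mean_difference: float   # mean(drug alone) - mean(pretreat + drug)
    p_value: float
    sensitized: bool


def sensitization_test(
    viability_drug_alone: Sequence[float],
    viability_pretreat_plus_drug: Sequence[float],
    alpha: float = 0.05,
) -> SensitizationResult:
    """Did inhibitor pretreatment sensitize cells to the drug?

    Two-tailed Welch t-test on the viability replicates; sensitized requires
    both a lower mean viability in the pretreated arm and p < alpha.
    """
    alone = np.asarray(viability_drug_alone, dtype=float)
    pre = np.asarray(viability_pretreat_plus_drug, dtype=float)
    _, _, p = welch_t_test(alone, pre)
    diff = float(alone.mean() - pre.mean())
    return SensitizationResult(
        mean_difference=diff, p_value=p,
        sensitized=bool(diff > 0 and p < alpha),
    )


@dataclass(frozen=True)
class QuadrantResult:
    counts: Mapping[str, int]
    percentages: Mapping[str, float] | None  # None when no events

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_events(
    events: pd.DataFrame,
    gates: tuple[float, float],
) -> QuadrantResult:
    """Assign each event to an annexin-V/7-AAD quadrant.

    Quadrants: live (double-negative), early apoptosis (annexin-V positive,
    7-AAD negative), late apoptosis (double-positive), non-apoptotic death
    (annexin-V negative, 7-AAD positive). Positive means signal strictly
    greater than its gate threshold.
    """
    gx, gy = gates
    if not (np.isfinite(gx) and np.isfinite(gy)):
        raise InvalidParameterError("gates must be finite")
    ann = events["annexin"].to_numpy(dtype=float)
    aad = events["aad7"].to_numpy(dtype=float)
    if len(ann) and not (np.all(np.isfinite(ann)) and np.all(np.isfinite(aad))):
        raise InvalidParameterError("non-finite event signals")
    ann_pos = ann > gx
    aad_pos = aad > gy
    counts = {
        "live": int(np.sum(~ann_pos & ~aad_pos)),
        "early_apoptosis": int(np.sum(ann_pos & ~aad_pos)),
        "late_apoptosis": int(np.sum(ann_pos & aad_pos)),
        "non_apoptotic_death": int(np.sum(~ann_pos & aad_pos)),
    }
    total = len(ann)
    percentages = (
        {k: 100.0 * v / total for k, v in counts.items()} if total else None
    )
    return QuadrantResult(counts=counts, percentages=percentages)
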
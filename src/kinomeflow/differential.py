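"""Differential phosphorylation between two conditions.

For every substrate that survives the reliability filter, the fold change is
the ratio of replicate medians (experimental / control) and significance
comes from a two-tailed heteroscedastic (Welch) t-test on the replicate
intensities. Classes follow the standard volcano coloring: up if FC > 1.5
and p < 0.05, down if FC < 0.75 and p < 0.05.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ChipLayout, ConsistencyError, InvalidParameterError
from .reliability_qc import QCVerdict

#: Fold-change reference lines drawn on volcano-style plots.
VOLCANO_REFERENCE_FCS = (0.5, 1.0, 2.0)

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_NOT_SIGNIFICANT = "not_significant"


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sample unequal-variance t-test (two-tailed).

    Returns (t statistic, Welch-Satterthwaite degrees of freedom, p-value)
    with t computed as (mean_a - mean_b) / sqrt(va/na + vb/nb) using sample
    (n-1) variances.

    Degenerate conventions: if both variances are zero the test is decided
    by the means alone — p = 1 when they are equal, p = 0 when they differ
    (t is +/-inf, df is nan).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidParameterError("non-finite values in test input")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, float("nan"), 1.0
        return math.copysign(float("inf"), diff), float("nan"), 0.0
    se2 = va / na + vb / nb
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


@dataclass(frozen=True)
class DifferentialParams:
    alpha: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.75
    log_transform: bool = False  # run the t-test on log-intensities
    bh_qvalues: bool = False     # report Benjamini-Hochberg q as an extra column

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.fc_up <= self.fc_down:
            raise InvalidParameterError("fc_up must exceed fc_down")
        if self.fc_down <= 0:
            raise InvalidParameterError("fc_down must be positive")


@dataclass(frozen=True)
class DifferentialRecord:
    substrate_id: str
    median_control: float
    median_experimental: float
    fold_change: float
    t_statistic: float
    p_value: float
    class_label: str
    q_value: float | None = None


@dataclass(frozen=True)
class DifferentialResult:
    records: tuple[DifferentialRecord, ...]
    excluded: Mapping[str, str]  # substrate_id -> reason (rejected_qc | zero_median)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _classify(fc: float, p: float, params: DifferentialParams) -> str:
    if p >= params.alpha:
        return CLASS_NOT_SIGNIFICANT
    if fc > params.fc_up:
        return CLASS_UP
    if fc < params.fc_down:
        return CLASS_DOWN
    return CLASS_UNCHANGED


def call_differential(
    control: Mapping[str, Sequence[float]] | pd.DataFrame,
    experimental: Mapping[str, Sequence[float]] | pd.DataFrame,
    qc: Sequence[QCVerdict],
    params: DifferentialParams = DifferentialParams(),
) -> DifferentialResult:
    """Call per-substrate differential phosphorylation on QC-passing substrates.

    ``control`` and ``experimental`` give replicate intensities per substrate
    (a mapping or a substrate x replicate DataFrame). Substrates rejected by
    QC carry no class and are listed in ``excluded`` with reason
    ``rejected_qc``; a zero control median makes the fold change undefined
    and the substrate is excluded with reason ``zero_median``.
    """
    ctrl = _as_mapping(control)
    expt = _as_mapping(experimental)
    missing = {v.substrate_id for v in qc} - (set(ctrl) & set(expt))
    if missing:
        raise ConsistencyError(
            f"{len(missing)} substrates missing from a condition"
        )

    records: list[DifferentialRecord] = []
    excluded: dict[str, str] = {}
    for verdict in qc:
        sid = verdict.substrate_id
        if verdict.rejected:
            excluded[sid] = "rejected_qc"
            continue
        c = np.asarray(ctrl[sid], dtype=float)
        e = np.asarray(expt[sid], dtype=float)
        med_c, med_e = float(np.median(c)), float(np.median(e))
        if med_c == 0.0:
            excluded[sid] = "zero_median"
            continue
        fc = med_e / med_c
        if params.log_transform:
            t, _, p = welch_t_test(np.log(e), np.log(c))
        else:
            t, _, p = welch_t_test(e, c)
        records.append(DifferentialRecord(
            substrate_id=sid, median_control=med_c, median_experimental=med_e,
            fold_change=fc, t_statistic=t, p_value=p,
            class_label=_classify(fc, p, params),
        ))

    if params.bh_qvalues and records:
        from statsmodels.stats.multitest import multipletests

        q = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        records = [
            DifferentialRecord(
                r.substrate_id, r.median_control, r.median_experimental,
                r.fold_change, r.t_statistic, r.p_value, r.class_label,
                q_value=float(qi),
            )
            for r, qi in zip(records, q)
        ]
    return DifferentialResult(tuple(records), excluded)


def _as_mapping(data) -> Mapping[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return {sid: row.to_numpy(dtype=float) for sid, row in data.iterrows()}
    return data


def export_volcano_table(
    records: Sequence[DifferentialRecord],
    layout: ChipLayout | None = None,
) -> pd.DataFrame:
    """Tabulate records for a volcano-style view, sorted by p ascending.

    Columns: substrate_id, median_control, median_experimental, fold_change,
    log2_fc, p_value, neg_log10_p, class, kinase (from the layout annotation
    when available). Reference lines at FC 0.5 / 1 / 2 are exposed as
    VOLCANO_REFERENCE_FCS for plotting.
    """
    kinases = layout.kinase_map() if layout is not None else {}
    rows = []
    for r in records:
        rows.append({
            "substrate_id": r.substrate_id,
            "median_control": r.median_control,
            "median_experimental": r.median_experimental,
            "fold_change": r.fold_change,
            "log2_fc": math.log2(r.fold_change) if r.fold_change > 0 else float("nan"),
            "p_value": r.p_value,
            "neg_log10_p": -math.log10(r.p_value) if r.p_value > 0 else float("inf"),
            "class": r.class_label,
            "kinase": kinases.get(r.substrate_id, ""),
            **({"q_value": r.q_value} if r.q_value is not None else {}),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["p_value", "substrate_id"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def plot_volcano(table: pd.DataFrame, path) -> None:
    """Optional PNG volcano plot (log2 FC vs -log10 p) with FC guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {CLASS_UP: "green", CLASS_DOWN: "red"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, sub in table.groupby("class"):
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=8,
                   c=colors.get(cls, "0.6"), label=cls)
    for fc in VOLCANO_REFERENCE_FCS:
        ax.axvline(math.log2(fc), color="0.8", lw=0.8)
    ax.set_xlabel("log2 fold change (experimental / control)")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
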
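"""End-to-end pipeline: (optional) quantify -> QC -> differential -> network.

A run is driven by a PipelineConfig whose defaults are the analysis
constants used throughout the package (SD/A < 0.20, 0.80 < A/M < 1.20,
alpha 0.05, FC cut-offs 1.5 / 0.75, 1,024 substrates in triplicate). Every
run writes a machine-readable manifest (config + seed + package version) so
any output is regenerable; outputs are byte-identical under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .containers import GroundTruth, InvalidParameterError, pooled_replicates
from .differential import (
    DifferentialParams,
    call_differential,
    export_volcano_table,
)
from .network import build_edges, kinase_summary, write_sif
from .reliability_qc import QCThresholds, apply_filter, verdicts_table
from .synthetic_data import make_layout, simulate_intensities

log = logging.getLogger("kinomeflow")


@dataclass(frozen=True)
class SyntheticDesign:
    """Planted experiment used when the pipeline runs in synthetic mode."""

    n_substrates: int = 1024
    n_replicates: int = 3
    n_up: int = 50
    fc_up_true: float = 3.0
    n_down: int = 50
    fc_down_true: float = 1.0 / 3.0
    n_unreliable: int = 10
    noise_cv: float = 0.10
    baseline: float = 1000.0
    n_chips_per_condition: int = 1
    kinase_annotation_density: float = 0.8

    def ground_truth(self, seed: int) -> GroundTruth:
        if self.n_up + self.n_down + self.n_unreliable > self.n_substrates:
            raise InvalidParameterError("planted sets exceed substrate count")
        ids = [f"pep{i:04d}" for i in range(self.n_substrates)]
        effects = {s: self.fc_up_true for s in ids[: self.n_up]}
        effects.update(
            {s: self.fc_down_true for s in ids[self.n_up: self.n_up + self.n_down]}
        )
        unreliable = frozenset(ids[-self.n_unreliable:]) if self.n_unreliable else frozenset()
        return GroundTruth(
            substrate_effects=effects,
            unreliable_substrates=unreliable,
            noise_cv=self.noise_cv,
            seed=seed,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and flags of one analysis run; defaults are standard."""

    sd_over_avg_max: float = 0.20
    am_low: float = 0.80
    am_high: float = 1.20
    alpha: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 0.75
    strict_qc: bool = True
    log_transform: bool = False
    bh_qvalues: bool = False
    seed: int = 0
    synthetic: SyntheticDesign = field(default_factory=SyntheticDesign)

    def __post_init__(self) -> None:
        # Delegate cross-field validation to the stage parameter objects.
        self.qc_thresholds()
        self.differential_params()

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(self.sd_over_avg_max, self.am_low, self.am_high,
                            self.strict_qc)

    def differential_params(self) -> DifferentialParams:
        return DifferentialParams(self.alpha, self.fc_up, self.fc_down,
                                  self.log_transform, self.bh_qvalues)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        syn = doc.pop("synthetic", {})
        return cls(synthetic=SyntheticDesign(**syn), **doc)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RunCounts:
    substrates_in: int
    qc_passed: int
    qc_rejected: int
    colored: int       # up + down calls
    uncolored: int     # unchanged + not_significant
    n_edges: int
    n_orphans: int


def planted_recovery(truth: GroundTruth, verdicts, records) -> dict:
    """Score a QC + differential run against the planted ground truth.

    Returns sensitivity (fraction of planted reliable effect substrates
    called in the correct direction), the fraction of null substrates
    colored at all, and the fraction of planted-unreliable substrates the
    QC filter rejected.
    """
    rejected = {v.substrate_id for v in verdicts if v.rejected}
    calls = {r.substrate_id: r.class_label for r in records}
    planted = {
        s: ("up" if fc > 1 else "down")
        for s, fc in truth.substrate_effects.items()
        if fc != 1 and s not in truth.unreliable_substrates
    }
    nulls = [
        v.substrate_id for v in verdicts
        if v.substrate_id not in truth.substrate_effects
        and v.substrate_id not in truth.unreliable_substrates
    ]
    hit = sum(calls.get(s) == direction for s, direction in planted.items())
    null_colored = sum(calls.get(s) in ("up", "down") for s in nulls)
    unreliable = truth.unreliable_substrates
    return {
        "sensitivity": hit / len(planted) if planted else float("nan"),
        "null_colored_fraction": null_colored / len(nulls) if nulls else float("nan"),
        "unreliable_rejected_fraction": (
            sum(s in rejected for s in unreliable) / len(unreliable)
            if unreliable else float("nan")
        ),
    }


def run_pipeline(config: PipelineConfig, out_dir) -> RunCounts:
    """Run the synthetic end-to-end pipeline and write all outputs.

    Writes layout.tsv, per-chip intensity TSVs, truth.yaml, qc.tsv,
    diff.tsv, edges.sif, summary.tsv and manifest.yaml into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = config.synthetic
    layout = make_layout(design.n_substrates, design.n_replicates,
                         design.kinase_annotation_density, seed=config.seed)
    truth = design.ground_truth(config.seed)
    controls, experimentals = simulate_intensities(
        layout, truth, baseline=design.baseline,
        n_chips_per_condition=design.n_chips_per_condition,
    )

    layout.to_tsv(out / "layout.tsv")
    truth.to_yaml(out / "truth.yaml")
    for chip in (*controls, *experimentals):
        chip.to_tsv(out / f"intensities_{chip.chip_id}.tsv")

    chips = {
        chip.chip_id: chip.replicate_matrix(layout)
        for chip in (*controls, *experimentals)
    }
    verdicts = apply_filter(chips, config.qc_thresholds())
    verdicts_table(verdicts).to_csv(out / "qc.tsv", sep="\t", index=False)
    n_rejected = sum(v.rejected for v in verdicts)
    log.info("QC: %d substrates in, %d passed, %d rejected",
             len(verdicts), len(verdicts) - n_rejected, n_rejected)

    result = call_differential(
        pooled_replicates(layout, controls),
        pooled_replicates(layout, experimentals),
        verdicts, config.differential_params(),
    )
    table = export_volcano_table(result.records, layout)
    table.to_csv(out / "diff.tsv", sep="\t", index=False)
    colored = sum(r.class_label in ("up", "down") for r in result.records)
    log.info("Differential: %d called, %d colored", len(result), colored)

    edges, orphans = build_edges(result.records, layout)
    write_sif(edges, out / "edges.sif")
    kinase_summary(edges).to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "orphans.txt").write_text("".join(f"{s}\n" for s in sorted(orphans)))
    log.info("Network: %d edges, %d orphan substrates", len(edges), len(orphans))

    counts = RunCounts(
        substrates_in=len(verdicts),
        qc_passed=len(verdicts) - n_rejected,
        qc_rejected=n_rejected,
        colored=colored,
        uncolored=len(result) - colored,
        n_edges=len(edges),
        n_orphans=len(orphans),
    )
    manifest = {
        "kinomeflow_version": __version__,
        "config": config.to_dict(),
        "counts": dataclasses.asdict(counts),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return counts
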
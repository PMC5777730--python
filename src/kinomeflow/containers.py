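"""Shared data containers for peptide-array kinome profiling.

A PepChip-style array carries up to ~1,024 peptide substrates spotted in
triplicate; each hybridization of one lysate to one chip yields a per-spot
density table. These containers tie spot-level measurements back to
substrates and their putative-kinase annotations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class KinomeflowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KinomeflowError, ValueError):
    """A parameter violates its documented domain."""


class ConsistencyError(KinomeflowError, ValueError):
    """Companion objects disagree (e.g. truth references unknown substrates)."""


class GeometryError(KinomeflowError, ValueError):
    """Spot geometry is impossible for the given image or pitch."""


class FormatError(KinomeflowError, ValueError):
    """An input file or array has the wrong shape/type."""


class DegenerateInputError(KinomeflowError, ValueError):
    """Statistics are undefined for this input (e.g. zero mean intensity)."""


class UndefinedIC50Error(KinomeflowError, ValueError):
    """The dose-response fit admits no IC50 (flat or rising trend)."""


LAYOUT_COLUMNS = ("spot_id", "row", "col", "substrate_id", "replicate_index", "kinase")


@dataclass(frozen=True)
class ChipLayout:
    """Array design: spot grid positions, substrate identity, kinase annotation.

    ``spots`` has one row per physical spot with columns
    ``spot_id, row, col, substrate_id, replicate_index, kinase``
    (``kinase`` may be empty for unannotated substrates).
    """

    spots: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(LAYOUT_COLUMNS) - set(self.spots.columns)
        if missing:
            raise FormatError(f"layout missing columns: {sorted(missing)}")
        if self.spots["spot_id"].duplicated().any():
            raise FormatError("duplicate spot_id in layout")
        if self.spots.duplicated(subset=["row", "col"]).any():
            raise GeometryError("duplicate grid position in layout")

    @property
    def substrate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.spots["substrate_id"]))

    @property
    def n_substrates(self) -> int:
        return self.spots["substrate_id"].nunique()

    @property
    def n_replicates(self) -> int:
        return int(self.spots.groupby("substrate_id").size().max())

    def kinase_map(self) -> dict[str, str]:
        """substrate_id -> kinase gene name, for annotated substrates only."""
        sub = self.spots.drop_duplicates("substrate_id")
        out = {}
        for sid, kin in zip(sub["substrate_id"], sub["kinase"]):
            if isinstance(kin, str) and kin:
                out[sid] = kin
        return out

    def to_tsv(self, path) -> None:
        self.spots.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChipLayout":
        df = pd.read_csv(path, sep="\t", dtype={"kinase": str}, keep_default_na=False)
        df["kinase"] = df["kinase"].replace({"nan": ""})
        return cls(df)


@dataclass(frozen=True)
class IntensitySet:
    """Per-spot integrated densities for one chip hybridization."""

    chip_id: str
    intensities: pd.Series  # index spot_id -> density

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise FormatError("duplicate spot_id in intensity set")

    def replicate_matrix(self, layout: ChipLayout) -> pd.DataFrame:
        """Pivot to substrate x replicate_index, preserving layout order.

        Raises ConsistencyError if any layout spot lacks a measurement.
        """
        spots = layout.spots
        missing = set(spots["spot_id"]) - set(self.intensities.index)
        if missing:
            raise ConsistencyError(
                f"chip {self.chip_id!r} missing intensities for {len(missing)} spots"
            )
        values = self.intensities.reindex(spots["spot_id"]).to_numpy()
        wide = pd.DataFrame(
            {
                "substrate_id": spots["substrate_id"].to_numpy(),
                "replicate_index": spots["replicate_index"].to_numpy(),
                "intensity": values,
            }
        ).pivot(index="substrate_id", columns="replicate_index", values="intensity")
        return wide.reindex(layout.substrate_ids)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"spot_id": self.intensities.index, "intensity": self.intensities.to_numpy()}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chip_id: str | None = None) -> "IntensitySet":
        df = pd.read_csv(path, sep="\t")
        name = chip_id if chip_id is not None else str(path)
        return cls(name, pd.Series(df["intensity"].to_numpy(), index=df["spot_id"]))


def pooled_replicates(
    layout: ChipLayout, chips: Sequence[IntensitySet]
) -> pd.DataFrame:
    """Concatenate replicate values per substrate across chips (columns renamed
    chip_id:replicate)."""
    parts = []
    for chip in chips:
        mat = chip.replicate_matrix(layout)
        mat.columns = [f"{chip.chip_id}:{c}" for c in mat.columns]
        parts.append(mat)
    return pd.concat(parts, axis=1)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth behind a synthetic experiment.

    substrate_effects maps substrate_id -> true fold change
    (experimental/control, dimensionless, > 0); substrates absent from the map
    are null (FC 1). unreliable_substrates are planted to fail the triplicate
    reliability filter. noise_cv is the coefficient of variation of the
    multiplicative log-normal spot noise.
    """

    substrate_effects: Mapping[str, float]
    unreliable_substrates: frozenset[str] = field(default_factory=frozenset)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.substrate_effects.values()):
            raise InvalidParameterError("true fold changes must be strictly positive")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        object.__setattr__(
            self, "unreliable_substrates", frozenset(self.unreliable_substrates)
        )

    def validate_against(self, layout: ChipLayout) -> None:
        known = set(layout.substrate_ids)
        unknown = (set(self.substrate_effects) | set(self.unreliable_substrates)) - known
        if unknown:
            raise ConsistencyError(f"truth references unknown substrates: {sorted(unknown)[:5]}")

    def to_yaml(self, path) -> None:
        doc = {
            "substrate_effects": {k: float(v) for k, v in self.substrate_effects.items()},
            "unreliable_substrates": sorted(self.unreliable_substrates),
            "noise_cv": float(self.noise_cv),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            substrate_effects=doc.get("substrate_effects", {}),
            unreliable_substrates=frozenset(doc.get("unreliable_substrates", [])),
            noise_cv=doc.get("noise_cv", 0.0),
            seed=doc.get("seed", 0),
        )
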
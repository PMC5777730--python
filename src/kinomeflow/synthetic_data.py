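"""Synthetic inputs with known ground truth.

Emulates every input the pipeline consumes: a PepChip-style layout of up to
1,024 substrates in triplicate, per-spot densities for two conditions
(chemosensitive vs chemoresistant lysates) under multiplicative log-normal
noise, rendered phospho-imager-style array images, MTT dose-response tables,
and annexin-V/7-AAD flow-cytometry event tables.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ChipLayout,
    GroundTruth,
    IntensitySet,
    ConsistencyError,
    GeometryError,
    InvalidParameterError,
)
from .spot_quant import GridGeometry

# Common human kinase gene names used for putative-kinase annotations.
KINASE_POOL = (
    "PRKCA", "PRKCB", "PRKCD", "PRKCE", "PRKCZ", "PRKD1",
    "JAK1", "JAK2", "JAK3", "TYK2", "SRC", "LCK", "LYN", "FYN",
    "ABL1", "AKT1", "AKT2", "GSK3B", "CDK1", "CDK2", "CDK5",
    "MAPK1", "MAPK3", "MAPK8", "MAPK14", "MAPKAPK2",
    "CSNK1A1", "CSNK2A1", "CAMK2A", "PRKACA", "PLK1", "AURKA", "AURKB",
    "CHEK1", "CHEK2", "EGFR", "ERBB2", "INSR", "IGF1R", "PDGFRB",
    "FGFR1", "MET", "RET", "KIT", "FLT3", "BTK", "SYK", "ZAP70",
    "ROCK1", "PAK1", "RPS6KA1", "RPS6KB1", "MTOR", "PIM1",
    "DYRK1A", "NEK2", "TTK", "WEE1",
)

#: Default gate thresholds (annexin-V, 7-AAD) used by the flow simulator.
DEFAULT_FLOW_GATES = (1.0, 1.0)

# Cluster centers sit well inside their quadrant relative to the default
# gates; spread 0.1 keeps classification unambiguous (7 sigma to the gate).
_NEG_CENTER, _POS_CENTER, _CLUSTER_SD = 0.3, 3.0, 0.1
QUADRANTS = ("live", "early_apoptosis", "late_apoptosis", "non_apoptotic_death")


def make_layout(
    n_substrates: int,
    n_replicates: int,
    kinase_annotation_density: float,
    seed: int = 0,
) -> ChipLayout:
    """Build a rectangular chip layout.

    Each of ``n_substrates`` substrates gets ``n_replicates`` spots at
    consecutive grid positions; approximately ``kinase_annotation_density`` of
    substrates carry a putative-kinase gene name drawn from a fixed pool.
    """
    if n_substrates < 1 or n_replicates < 2:
        raise InvalidParameterError(
            "need n_substrates >= 1 and n_replicates >= 2"
        )
    if not 0.0 <= kinase_annotation_density <= 1.0:
        raise InvalidParameterError("kinase_annotation_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    total = n_substrates * n_replicates
    n_cols = math.ceil(math.sqrt(total))

    annotated = rng.random(n_substrates) < kinase_annotation_density
    kinases = rng.choice(KINASE_POOL, size=n_substrates)

    rows = []
    idx = 0
    for s in range(n_substrates):
        sid = f"pep{s:04d}"
        kin = str(kinases[s]) if annotated[s] else ""
        for r in range(n_replicates):
            rows.append((f"spot{idx:05d}", idx // n_cols, idx % n_cols, sid, r, kin))
            idx += 1
    df = pd.DataFrame(rows, columns=["spot_id", "row", "col", "substrate_id",
                                     "replicate_index", "kinase"])
    return ChipLayout(df)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    # Multiplicative noise with mean exactly 1 and coefficient of variation cv.
    sigma2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))


def simulate_intensities(
    layout: ChipLayout,
    truth: GroundTruth,
    baseline: float = 1000.0,
    n_chips_per_condition: int = 1,
) -> tuple[list[IntensitySet], list[IntensitySet]]:
    """Simulate per-spot densities for control and experimental chips.

    Control spots are ``baseline`` times log-normal noise with CV
    ``truth.noise_cv``; experimental spots are additionally scaled by the
    substrate's true fold change. Each substrate in
    ``truth.unreliable_substrates`` has its first replicate replaced by a 5x
    outlier on the first chip of each condition, which deterministically
    fails the triplicate reliability filter (SD/A ~ 0.99, A/M ~ 2.33).
    """
    if baseline <= 0:
        raise InvalidParameterError("baseline must be positive")
    if n_chips_per_condition < 1:
        raise InvalidParameterError("need at least one chip per condition")
    truth.validate_against(layout)

    rng = np.random.default_rng(truth.seed)
    spots = layout.spots
    effects = spots["substrate_id"].map(
        lambda s: truth.substrate_effects.get(s, 1.0)
    ).to_numpy(dtype=float)
    outlier_mask = (
        spots["substrate_id"].isin(truth.unreliable_substrates)
        & (spots["replicate_index"] == 0)
    ).to_numpy()

    def one_chip(chip_id: str, scale: np.ndarray, plant: bool) -> IntensitySet:
        values = baseline * scale * _lognormal_factors(rng, truth.noise_cv, len(spots))
        if plant:
            values = np.where(outlier_mask, 5.0 * values, values)
        return IntensitySet(chip_id, pd.Series(values, index=spots["spot_id"].to_numpy()))

    ones = np.ones(len(spots))
    controls = [
        one_chip(f"control_{i + 1}", ones, plant=(i == 0))
        for i in range(n_chips_per_condition)
    ]
    experimentals = [
        one_chip(f"experimental_{i + 1}", effects, plant=(i == 0))
        for i in range(n_chips_per_condition)
    ]
    return controls, experimentals


def render_array_image(
    layout: ChipLayout,
    intensities: IntensitySet,
    spot_radius_px: int = 4,
    background_level: float = 100.0,
    pitch_px: int = 16,
    margin_px: int | None = None,
) -> tuple[np.ndarray, GridGeometry]:
    """Render spots as uniform discs on a flat background.

    Each spot's integrated excess density above background equals its
    intensity value exactly (per-pixel excess = intensity / disc pixel
    count), so grid quantification can be validated as a round trip.
    Returns the float64 image and the matching grid geometry.
    """
    if spot_radius_px < 1:
        raise InvalidParameterError("spot_radius_px must be >= 1")
    if pitch_px <= 2 * spot_radius_px:
        raise GeometryError(
            f"pitch {pitch_px}px overlaps discs of radius {spot_radius_px}px"
        )
    if margin_px is None:
        margin_px = spot_radius_px + 8  # room for the background annulus
    spots = layout.spots
    missing = set(spots["spot_id"]) - set(intensities.intensities.index)
    if missing:
        raise ConsistencyError(f"intensities missing for {len(missing)} spots")

    n_rows = int(spots["row"].max()) + 1
    n_cols = int(spots["col"].max()) + 1
    height = 2 * margin_px + (n_rows - 1) * pitch_px + 1
    width = 2 * margin_px + (n_cols - 1) * pitch_px + 1
    image = np.full((height, width), float(background_level))

    # Disc stamp shared by all spots (pixel center within radius of spot center).
    r = spot_radius_px
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (yy * yy + xx * xx) <= r * r
    disc_area = int(disc.sum())

    values = intensities.intensities.reindex(spots["spot_id"]).to_numpy()
    for (row, col), val in zip(zip(spots["row"], spots["col"]), values):
        cy = margin_px + int(row) * pitch_px
        cx = margin_px + int(col) * pitch_px
        image[cy - r:cy + r + 1, cx - r:cx + r + 1][disc] += val / disc_area

    geometry = GridGeometry(
        origin=(float(margin_px), float(margin_px)),
        pitch=(float(pitch_px), float(pitch_px)),
        spot_radius=float(spot_radius_px),
    )
    return image, geometry


def simulate_dose_response(
    ic50: float,
    hill: float,
    concentrations: Sequence[float],
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate an MTT viability table from a logistic dose-response model.

    Mean viability (% of drug-free control) follows
    ``100 / (1 + (c / ic50) ** hill)``, i.e. a logistic in log-concentration
    with midpoint ``ic50``; replicate noise is additive Gaussian with sd
    ``noise_sd`` (fraction of full scale, so 0.05 = 5 percentage points),
    truncated at zero.
    """
    from .pharm import DoseResponseCurve

    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise InvalidParameterError("need at least 2 distinct concentrations")
    if np.any(conc <= 0):
        raise InvalidParameterError("concentrations must be strictly positive")
    if ic50 <= 0:
        raise InvalidParameterError("ic50 must be positive")
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    mean = 100.0 / (1.0 + (conc / ic50) ** hill)
    viab = mean[:, None] + rng.normal(0.0, noise_sd * 100.0, (conc.size, n_reps))
    viab = np.clip(viab, 0.0, None)
    return DoseResponseCurve(concentrations=conc, viabilities=viab)


def simulate_flow_events(
    n_events: int,
    fractions: Sequence[float],
    seed: int = 0,
    gates: tuple[float, float] = DEFAULT_FLOW_GATES,
    exact_counts: bool = False,
) -> pd.DataFrame:
    """Simulate a two-channel flow-cytometry event table.

    ``fractions`` gives the (live, early_apoptosis, late_apoptosis,
    non_apoptotic_death) proportions; events are drawn from four Gaussian
    clusters placed unambiguously within the quadrants defined by ``gates``
    (annexin threshold, 7-AAD threshold). Per-cluster counts are multinomial,
    or exact (largest-remainder rounding) when ``exact_counts`` is set.

    Returns a DataFrame with columns ``annexin``, ``aad7``, ``true_quadrant``.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.size != 4 or np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            "fractions must be four non-negative values summing to 1"
        )
    if n_events < 0:
        raise InvalidParameterError("n_events must be non-negative")
    rng = np.random.default_rng(seed)
    if n_events == 0:
        return pd.DataFrame(columns=["annexin", "aad7", "true_quadrant"])

    if exact_counts:
        raw = frac * n_events
        counts = np.floor(raw).astype(int)
        rem = n_events - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    else:
        counts = rng.multinomial(n_events, frac)

    # Quadrant -> (annexin positive?, 7-AAD positive?)
    signs = {"live": (0, 0), "early_apoptosis": (1, 0),
             "late_apoptosis": (1, 1), "non_apoptotic_death": (0, 1)}
    gx, gy = gates
    ann, aad, label = [], [], []
    for quad, n in zip(QUADRANTS, counts):
        ax, ay = signs[quad]
        cx = gx - 1.0 + (_POS_CENTER if ax else _NEG_CENTER)
        cy = gy - 1.0 + (_POS_CENTER if ay else _NEG_CENTER)
        ann.append(rng.normal(cx, _CLUSTER_SD, n))
        aad.append(rng.normal(cy, _CLUSTER_SD, n))
        label.extend([quad] * int(n))
    events = pd.DataFrame(
        {"annexin": np.concatenate(ann), "aad7": np.concatenate(aad),
         "true_quadrant": label}
    )
    # Shuffle so event order carries no cluster information.
    perm = rng.permutation(len(events))
    return events.iloc[perm].reset_index(drop=True)
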
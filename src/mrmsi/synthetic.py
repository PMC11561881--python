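"""Seeded synthetic fixtures with ground truth.

Generates the three kinds of inputs the pipeline consumes — tissue images
with region-structured lipid fields (an airway annulus inside parenchyma,
emulating the lumen/airway/parenchyma contrast of lung sections),
calibration slides with variable-footprint spots at known pg amounts, and
LC-MS/MS feature tables with planted fold changes — all as pure functions of
their parameters and a seed.

Noise model: MS responses are heteroscedastic, so signal is multiplied by a
mean-corrected log-normal factor (``sigma² = ln(1 + CV²)``, ``mu = −sigma²/2``,
giving an expectation of exactly 1) and an additive half-normal background
term ``background_level·|N(0,1)|`` is added everywhere. The generators are
not physical DESI simulations: they reproduce the statistical structure the
processing steps rely on (region contrast, footprint-dependent pg/pixel,
blank/QC levels), nothing about desorption or ion suppression.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import BACKGROUND_LABEL, MRMImage, MRMTransition, PixelGrid
from .preprocess import ROISpec

__all__ = [
    "Disk",
    "Annulus",
    "Rectangle",
    "Complement",
    "TissueScene",
    "GroundTruth",
    "simulate_tissue_image",
    "simulate_calibration_slide",
    "simulate_lcms_table",
    "default_airway_scene",
    "CALIBRATION_AMOUNTS_PG",
    "DIHOME_TRANSITION",
]

#: Printed calibration ladder: pg deposited per spot (1 μL of 0–400 ng/mL).
CALIBRATION_AMOUNTS_PG = (0.0, 0.5, 1.0, 5.0, 10.0, 25.0, 150.0, 400.0)

#: The 12,13-DiHOME quantifier channel used on the calibration slides.
DIHOME_TRANSITION = MRMTransition(
    label="12,13-DiHOME",
    precursor_mz=313.2,
    product_mz=183.1,
    collision_energy=20.0,
    cone_voltage=30.0,
)


# ---------------------------------------------------------------------------
# Region geometries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]
    radius: float

    def contains(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        dr = r - self.center[0]
        dc = c - self.center[1]
        return dr**2 + dc**2 <= self.radius**2


@dataclass(frozen=True)
class Annulus:
    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def contains(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        d2 = (r - self.center[0]) ** 2 + (c - self.center[1]) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)


@dataclass(frozen=True)
class Rectangle:
    r0: int
    c0: int
    r1: int
    c1: int

    def contains(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        return (r >= self.r0) & (r < self.r1) & (c >= self.c0) & (c < self.c1)


@dataclass(frozen=True)
class Complement:
    """All grid pixels not claimed by any earlier region."""

    def contains(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        return np.ones_like(r, dtype=bool)


@dataclass
class TissueScene:
    """Parameters of a synthetic tissue acquisition.

    ``regions`` are applied in order, first-come-wins; uncovered pixels are
    background. ``lipid_fields`` maps region label → {transition label →
    mean response}; a region missing a transition has mean 0 there.
    ``noise_cv`` is the multiplicative coefficient of variation (scalar or
    per-transition mapping).
    """

    grid: PixelGrid
    transitions: list[MRMTransition]
    regions: list[tuple[str, object]]
    lipid_fields: Mapping[str, Mapping[str, float]]
    noise_cv: float | Mapping[str, float] = 0.2
    background_level: float = 1.0
    seed: int = 0
    sample_id: str = "synthetic"

    def cv_for(self, label: str) -> float:
        if isinstance(self.noise_cv, Mapping):
            return float(self.noise_cv[label])
        return float(self.noise_cv)


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated object."""

    region: np.ndarray | None = None
    expected_response: np.ndarray | None = None
    region_means: dict = field(default_factory=dict)
    amount_per_pixel: np.ndarray | None = None
    fc: pd.Series | None = None
    group_means: pd.DataFrame | None = None


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit expectation and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Tissue images
# ---------------------------------------------------------------------------


def simulate_tissue_image(scene: TissueScene) -> tuple[MRMImage, GroundTruth]:
    """Generate a labeled tissue image from a scene description.

    Response of a pixel in region R for transition t is
    ``mean(R, t) · L + background_level·|N(0, 1)|`` with L the mean-corrected
    log-normal factor at the scene CV; uncovered (background) pixels carry
    only the additive term and are labeled ``"background"``. Deterministic
    under the scene seed.
    """
    grid = scene.grid
    rng = np.random.default_rng(scene.seed)
    coords = grid.row_major_coords()
    rr = coords[:, 0].astype(float)
    cc = coords[:, 1].astype(float)
    region = np.full(grid.n_pixels, BACKGROUND_LABEL, dtype=object)
    unclaimed = np.ones(grid.n_pixels, dtype=bool)
    for label, geom in scene.regions:
        inside = geom.contains(rr, cc) & unclaimed
        region[inside] = label
        unclaimed &= ~inside

    t_labels = [t.label for t in scene.transitions]
    n_t = len(t_labels)
    means = np.zeros((grid.n_pixels, n_t))
    for label, _ in scene.regions:
        fields = scene.lipid_fields.get(label, {})
        mask = region == label
        for j, tl in enumerate(t_labels):
            means[mask, j] = float(fields.get(tl, 0.0))

    responses = np.empty_like(means)
    for j, tl in enumerate(t_labels):
        cv = scene.cv_for(tl)
        factor = _lognormal_factor(rng, cv, grid.n_pixels)
        bg = scene.background_level * np.abs(rng.standard_normal(grid.n_pixels))
        responses[:, j] = means[:, j] * factor + bg

    expected = means + scene.background_level * math.sqrt(2.0 / math.pi)
    image = MRMImage(
        grid=grid,
        transitions=list(scene.transitions),
        responses=responses,
        sample_id=scene.sample_id,
        pixel_labels=region.copy(),
    )
    truth = GroundTruth(
        region=region,
        expected_response=expected,
        region_means={
            lbl: dict(scene.lipid_fields.get(lbl, {}))
            for lbl, _ in scene.regions
        },
    )
    return image, truth


def default_airway_scene(
    airway_mean: float = 100.0,
    parenchyma_mean: float = 50.0,
    noise_cv: float = 0.2,
    background_level: float = 1.0,
    seed: int = 0,
    grid: PixelGrid | None = None,
    transitions: Sequence[MRMTransition] | None = None,
) -> TissueScene:
    """Airway-annulus-in-parenchyma scene mirroring a lung section.

    A 40×40 raster holds a circular tissue section (radius 14 px): an airway
    wall annulus (radii 5–8) around an empty lumen, parenchyma elsewhere in
    the section, embedding medium (background) outside. The lumen (inner
    disk) is part of no lipid field — the "absence of tissue" that makes
    solvent-standard normalization produce artifacts there.
    """
    grid = grid or PixelGrid(40, 40)
    transitions = list(transitions or [DIHOME_TRANSITION])
    center = ((grid.n_rows - 1) / 2.0, (grid.n_cols - 1) / 2.0)
    regions = [
        ("lumen", Disk(center, 5.0 - 1e-9)),
        ("airways", Annulus(center, 5.0, 8.0)),
        ("parenchyma", Disk(center, 14.0)),
    ]
    fields = {
        "lumen": {t.label: 0.0 for t in transitions},
        "airways": {t.label: airway_mean for t in transitions},
        "parenchyma": {t.label: parenchyma_mean for t in transitions},
    }
    return TissueScene(
        grid=grid,
        transitions=transitions,
        regions=regions,
        lipid_fields=fields,
        noise_cv=noise_cv,
        background_level=background_level,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Calibration slides
# ---------------------------------------------------------------------------


def simulate_calibration_slide(
    amounts: Sequence[float] = CALIBRATION_AMOUNTS_PG,
    spot_radius_px: int = 4,
    replicates: int = 3,
    response_per_pg_pixel: float = 100.0,
    cv: float = 0.08,
    seed: int = 0,
    background_level: float = 0.2,
    radius_jitter: int = 1,
    transition: MRMTransition = DIHOME_TRANSITION,
) -> tuple[MRMImage, list[tuple[str, float, ROISpec]]]:
    """Generate a calibration slide of spotted standards with known amounts.

    Each replicate row carries one disk-shaped spot per amount; spot radii
    are jittered by up to ``radius_jitter`` pixels so footprints (and hence
    pg/pixel) vary between replicates, as hand-spotted standards do. The
    expected response of a spot pixel is
    ``response_per_pg_pixel × amount / n_pixels`` under multiplicative noise
    at ``cv``, on top of the additive background. Returns the image and the
    spot metadata ``(label, deposited pg, ROISpec)`` ready for
    :func:`mrmsi.quantify.summarize_calibration`.
    """
    if spot_radius_px < 1:
        raise ValueError("spot radius must be at least 1 pixel")
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be non-negative")
    rng = np.random.default_rng(seed)
    r_max = spot_radius_px + radius_jitter
    pitch = 2 * r_max + 3
    n_rows = replicates * pitch + 2
    n_cols = len(amounts) * pitch + 2
    grid = PixelGrid(n_rows, n_cols)
    coords = grid.row_major_coords()
    rr = coords[:, 0].astype(float)
    cc = coords[:, 1].astype(float)

    labels = np.full(grid.n_pixels, BACKGROUND_LABEL, dtype=object)
    signal = np.zeros(grid.n_pixels)
    spots: list[tuple[str, float, ROISpec]] = []
    for rep in range(replicates):
        for k, amount in enumerate(amounts):
            center = (1 + rep * pitch + r_max, 1 + k * pitch + r_max)
            radius = spot_radius_px + int(
                rng.integers(-radius_jitter, radius_jitter + 1)
            )
            radius = max(radius, 1)
            inside = Disk(center, radius).contains(rr, cc)
            n_px = int(inside.sum())
            label = f"rep{rep + 1}_spot{k + 1}"
            labels[inside] = label
            if n_px:
                signal[inside] = response_per_pg_pixel * amount / n_px
            pix = [tuple(map(int, rc)) for rc in coords[inside]]
            spots.append(
                (label, float(amount), ROISpec.from_pixels(label, pix))
            )

    factor = _lognormal_factor(rng, cv, grid.n_pixels)
    bg = background_level * np.abs(rng.standard_normal(grid.n_pixels))
    responses = (signal * factor + bg)[:, None]
    image = MRMImage(
        grid=grid,
        transitions=[transition],
        responses=responses,
        sample_id=f"calibration_seed{seed}",
        pixel_labels=labels,
    )
    return image, spots


# ---------------------------------------------------------------------------
# LC-MS/MS feature tables
# ---------------------------------------------------------------------------


def simulate_lcms_table(
    n_compounds: int = 20,
    n_per_group: int = 12,
    planted_fc: Mapping[str, float] | float = 1.0,
    cv: float = 0.15,
    blank_level: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
    cv_qc: float = 0.05,
    n_blanks: int = 3,
    n_qc: int = 4,
    panel: str = "octadecanoid",
    base_range: tuple[float, float] = (20.0, 150.0),
    snr_value: float = 100.0,
) -> tuple["FeatureTable", GroundTruth]:
    """Generate an LC-MS/MS feature table with planted fold changes.

    Per compound, a base concentration (pg/mg) is drawn log-uniformly from
    ``base_range`` for parenchyma; the airway mean is that times the planted
    airways:parenchyma FC (scalar or per-compound map). Study values are
    mean-corrected log-normal at ``cv`` (matching the default 3 biological ×
    4 technical replicates per tissue, n = 12); blanks sit at ``blank_level``
    × the overall sample mean; QCs at the pooled mean with CV ``cv_qc``.
    Missing values are injected into study cells at ``missing_rate``. A
    constant S/N matrix at ``snr_value`` is attached.
    """
    from .lcms_screen import FeatureTable  # local import to avoid a cycle

    for name, rate in (("blank_level", blank_level), ("missing_rate", missing_rate)):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    compounds = [f"{panel[:3]}_cpd{i + 1:02d}" for i in range(n_compounds)]
    if isinstance(planted_fc, Mapping):
        fcs = np.array([float(planted_fc.get(c, 1.0)) for c in compounds])
    else:
        fcs = np.full(n_compounds, float(planted_fc))
    lo, hi = base_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_compounds))
    mean_par = base
    mean_air = base * fcs

    air_ids = [f"airways_{i + 1}" for i in range(n_per_group)]
    par_ids = [f"parenchyma_{i + 1}" for i in range(n_per_group)]
    blank_ids = [f"blank_{i + 1}" for i in range(n_blanks)]
    qc_ids = [f"QC_{i + 1}" for i in range(n_qc)]

    def draw(means: np.ndarray, n: int, c: float) -> np.ndarray:
        f = _lognormal_factor(rng, c, (n_compounds, n))
        return means[:, None] * f

    air = draw(mean_air, n_per_group, cv)
    par = draw(mean_par, n_per_group, cv)
    overall = (mean_air + mean_par) / 2.0
    blanks = draw(blank_level * overall, n_blanks, cv)
    qcs = draw(overall, n_qc, cv_qc)

    conc = pd.DataFrame(
        np.hstack([air, par, blanks, qcs]),
        index=compounds,
        columns=air_ids + par_ids + blank_ids + qc_ids,
    )
    if missing_rate > 0:
        study_cols = air_ids + par_ids
        mask = rng.random((n_compounds, len(study_cols))) < missing_rate
        block = conc[study_cols].to_numpy()
        block[mask] = np.nan
        conc[study_cols] = block

    sample_meta = pd.DataFrame(
        {
            "class": ["sample"] * (2 * n_per_group)
            + ["blank"] * n_blanks
            + ["QC"] * n_qc,
            "tissue": ["airways"] * n_per_group
            + ["parenchyma"] * n_per_group
            + [np.nan] * (n_blanks + n_qc),
        },
        index=conc.columns,
    )
    compound_meta = pd.DataFrame(
        {"panel": panel, "pathway": "synthetic"}, index=compounds
    )
    snr = pd.DataFrame(
        snr_value, index=conc.index, columns=conc.columns, dtype=float
    )
    table = FeatureTable(
        concentrations=conc,
        sample_meta=sample_meta,
        compound_meta=compound_meta,
        snr=snr,
    )
    truth = GroundTruth(
        fc=pd.Series(fcs, index=compounds),
        group_means=pd.DataFrame(
            {"airways": mean_air, "parenchyma": mean_par}, index=compounds
        ),
    )
    return table, truth
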
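"""Calibration-based pg/pixel quantification.

Calibration standards are spotted at known amounts (pg) onto a pseudo-
biological matrix section and imaged alongside the samples. Because spot
footprints vary, the working concentration of a spot is its deposited amount
divided by the number of pixels it covers (pg/pixel). An ordinary
least-squares line of mean spot response versus pg/pixel, pooled over
replicate curves, converts the response of each tissue pixel that passes the
quantification gate (S/N > 5) into an estimated pg/pixel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import MRMImage, StateError
from .preprocess import ROISpec, SNRResult, gate

__all__ = [
    "CalibrationSpot",
    "CalibrationModel",
    "ConcentrationResult",
    "spot_amount",
    "summarize_calibration",
    "fit_calibration",
    "estimate_concentration",
    "concentration_summary",
    "compute_dwell",
]


def spot_amount(volume_ul: float, concentration_ng_ml: float) -> float:
    """Amount of analyte (pg) deposited by spotting a solution.

    1 ng/mL equals 1 pg/μL, so ``volume_ul × concentration_ng_ml`` is the
    deposited amount in pg (e.g. 1 μL of a 400 ng/mL solution → 400 pg).
    """
    if volume_ul < 0 or concentration_ng_ml < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_ul * concentration_ng_ml


@dataclass
class CalibrationSpot:
    """Summary of one calibration spot ROI.

    ``amount_per_pixel = deposited_amount / n_pixels`` (pg/pixel): replicate
    spots of the same deposited amount land at different working
    concentrations because their pixel footprints differ.
    """

    label: str
    deposited_amount: float
    roi: ROISpec | None
    n_pixels: int
    mean_response: float
    amount_per_pixel: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("spot must cover at least one pixel")
        if self.deposited_amount < 0:
            raise ValueError("deposited amount must be non-negative")
        self.amount_per_pixel = self.deposited_amount / self.n_pixels


@dataclass
class CalibrationModel:
    """OLS line of mean spot response on pg/pixel.

    ``r_squared`` is the coefficient of determination on the pooled fitted
    points; when replicate curves were supplied, ``replicate_r_squared``
    holds the per-replicate values and ``mean_replicate_r_squared`` their
    mean (the "average linear response").
    """

    slope: float
    intercept: float
    r_squared: float
    spots: list[CalibrationSpot]
    replicate_count: int = 1
    replicate_r_squared: list[float] = field(default_factory=list)
    mean_replicate_r_squared: float | None = None

    def predict(self, amount_per_pixel) -> np.ndarray:
        """Forward map: expected response at a given pg/pixel."""
        return self.slope * np.asarray(amount_per_pixel, float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "replicate_count": self.replicate_count,
            "replicate_r_squared": self.replicate_r_squared,
            "mean_replicate_r_squared": self.mean_replicate_r_squared,
            "spots": [
                {
                    "label": s.label,
                    "deposited_amount_pg": s.deposited_amount,
                    "n_pixels": s.n_pixels,
                    "mean_response": s.mean_response,
                    "amount_per_pixel": s.amount_per_pixel,
                }
                for s in self.spots
            ],
        }


def summarize_calibration(
    image: MRMImage,
    spots,
    transition: str,
) -> list[CalibrationSpot]:
    """Summarize calibration spot ROIs: pixel count and mean response.

    ``spots`` is a sequence of ``(label, deposited_amount_pg, ROISpec)``.
    Spot ROIs must be disjoint. Calibration pixels are deliberately not S/N
    gated — the spot ROI defines membership, and gating would bias low-level
    means upward.
    """
    j = image.transition_index(transition)
    index = {
        (int(r), int(c)): k for k, (r, c) in enumerate(image.pixel_coords)
    }
    resolved = []
    for label, amount, roi in spots:
        pix = roi.resolve(image.grid)
        resolved.append((label, amount, roi, pix))
    for i in range(len(resolved)):
        for k in range(i + 1, len(resolved)):
            if resolved[i][3] & resolved[k][3]:
                raise ValueError(
                    f"calibration ROIs {resolved[i][0]!r} and "
                    f"{resolved[k][0]!r} overlap"
                )
    out = []
    for label, amount, roi, pix in resolved:
        rows = [index[rc] for rc in sorted(pix)]
        vals = image.responses[rows, j]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"calibration ROI {label!r} has no responses")
        out.append(
            CalibrationSpot(
                label=label,
                deposited_amount=float(amount),
                roi=roi,
                n_pixels=len(pix),
                mean_response=float(vals.mean()),
            )
        )
    return out


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def fit_calibration(
    spots=None,
    replicates=None,
) -> CalibrationModel:
    """Fit the calibration line by unweighted OLS.

    Pass either ``spots`` (one pooled list of :class:`CalibrationSpot`) or
    ``replicates`` (a list of per-replicate spot lists). The working model is
    fitted on all spots pooled; with replicates the per-replicate r² values
    are reported as well. At least 3 distinct pg/pixel levels are required.
    """
    if replicates is not None:
        groups = [list(g) for g in replicates]
        pooled = [s for g in groups for s in g]
    elif spots is not None:
        groups = [list(spots)]
        pooled = list(spots)
    else:
        raise ValueError("pass spots or replicates")
    x = np.array([s.amount_per_pixel for s in pooled], float)
    y = np.array([s.mean_response for s in pooled], float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            "calibration requires >= 3 distinct pg/pixel levels"
        )
    if np.ptp(x) == 0:
        raise ValueError("zero variance in calibration amounts")
    res = stats.linregress(x, y)
    rep_r2 = []
    if replicates is not None:
        for g in groups:
            gx = np.array([s.amount_per_pixel for s in g], float)
            gy = np.array([s.mean_response for s in g], float)
            rep_r2.append(_r_squared(gx, gy))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        spots=pooled,
        replicate_count=len(groups),
        replicate_r_squared=rep_r2,
        mean_replicate_r_squared=float(np.mean(rep_r2)) if rep_r2 else None,
    )


@dataclass
class ConcentrationResult:
    """Per-pixel estimated concentration (pg/pixel).

    ``values`` is NaN at pixels that did not pass the quantification gate
    ("not quantified"); ``floored`` flags pixels whose back-calculated
    estimate was negative and was clamped to 0.
    """

    transition: str
    values: np.ndarray
    quantified: np.ndarray
    floored: np.ndarray

    @property
    def quantified_values(self) -> np.ndarray:
        return self.values[self.quantified]


def estimate_concentration(
    image: MRMImage,
    model: CalibrationModel,
    snr: SNRResult,
    transition: str,
) -> ConcentrationResult:
    """Back-calculate pg/pixel for pixels passing the quantification gate.

    ``concentration = (response − intercept) / slope`` for pixels with
    S/N > 5 on the target channel; others are "not quantified" (NaN).
    Negative estimates are floored at 0 and flagged. A non-positive slope is
    a non-identifiable calibration and raises.
    """
    if model.slope <= 0:
        raise ValueError("non-identifiable calibration: slope must be > 0")
    j = image.transition_index(transition)
    mask = gate(snr, "quantification")[:, j]
    resp = image.responses[:, j]
    conc = np.full(image.n_pixels, np.nan)
    raw = (resp[mask] - model.intercept) / model.slope
    floored_local = raw < 0
    conc[mask] = np.where(floored_local, 0.0, raw)
    floored = np.zeros(image.n_pixels, dtype=bool)
    floored[np.flatnonzero(mask)[floored_local]] = True
    return ConcentrationResult(
        transition=transition, values=conc, quantified=mask, floored=floored
    )


def concentration_summary(
    result: ConcentrationResult | np.ndarray,
    bins: int = 20,
    calibration_levels=None,
) -> dict:
    """Histogram of quantified pixel concentrations plus the maximum.

    Returns bin edges/counts over the quantified pixels, the maximum pixel
    value, and the calibration pg/pixel levels supplied for overlay. With no
    quantified pixels an empty summary is returned with a warning.
    """
    if isinstance(result, ConcentrationResult):
        vals = result.quantified_values
    else:
        vals = np.asarray(result, float)
        vals = vals[np.isfinite(vals)]
    levels = (
        sorted(float(v) for v in calibration_levels)
        if calibration_levels is not None
        else []
    )
    if vals.size == 0:
        warnings.warn("no quantified pixels; empty concentration summary")
        return {
            "counts": np.array([], dtype=int),
            "bin_edges": np.array([]),
            "max": None,
            "n_quantified": 0,
            "calibration_levels": levels,
        }
    counts, edges = np.histogram(vals, bins=bins)
    return {
        "counts": counts,
        "bin_edges": edges,
        "max": float(vals.max()),
        "n_quantified": int(vals.size),
        "calibration_levels": levels,
    }


def compute_dwell(
    scan_rate: float, n_transitions: int, interscan_delay_ms: float = 3.0
) -> float:
    """Per-transition dwell time (ms) within one pixel's duty cycle.

    The pixel period ``1000/scan_rate`` ms is shared equally among the
    monitored transitions after subtracting the interscan delay, and the
    instrument reports whole milliseconds: ``floor(1000/rate/n − delay)``,
    clipped at 0. At 4 Hz with 6 transitions and a 3 ms delay this gives
    38 ms/pixel per transition.
    """
    if scan_rate <= 0:
        raise ValueError("scan_rate must be positive")
    if n_transitions < 1:
        raise ValueError("need at least one transition")
    if interscan_delay_ms < 0:
        raise ValueError("interscan delay must be non-negative")
    dwell = math.floor(1000.0 / scan_rate / n_transitions - interscan_delay_ms)
    return float(max(dwell, 0))
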
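"""ROI labeling, background-referenced S/N, gating and normalization.

Noise for a channel is the mean response of the off-tissue ("background")
pixels of the same acquisition; the S/N of a pixel is its response divided by
that noise. Pixels pass detection at S/N > 3 and quantification at S/N > 5
(strict inequalities). Channels detected in fewer than a small fraction of
tissue pixels are treated as blank and removed. An optional per-pixel
normalization to a solvent-spiked technical standard (e.g. CUDA) is provided
but is off by default: dividing analyte responses by the standard corrects
global trends but creates artifacts over tissue voids such as airway lumens,
so the flagged-pixel record it returns should be inspected before use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .core_io import BACKGROUND_LABEL, MRMImage, PixelGrid, StateError

__all__ = [
    "DETECTION_SNR",
    "QUANTIFICATION_SNR",
    "ROISpec",
    "SNRResult",
    "label_rois",
    "compute_snr",
    "gate",
    "remove_blank_channels",
    "normalize_to_solvent_standard",
    "rois_to_json",
    "rois_from_json",
]

#: Default S/N threshold for detection (strict >).
DETECTION_SNR = 3.0
#: Default S/N threshold for quantification (strict >).
QUANTIFICATION_SNR = 5.0


# ---------------------------------------------------------------------------
# ROI specification
# ---------------------------------------------------------------------------


@dataclass
class ROISpec:
    """A labeled pixel region: rectangle, polygon or explicit pixel list.

    Exactly one of ``rectangle``, ``polygon`` or ``pixels`` is set.

    * ``rectangle = (r0, c0, r1, c1)`` — half-open: rows ``r0 ≤ r < r1``,
      columns ``c0 ≤ c < c1``.
    * ``polygon`` — vertex list in pixel units, ``(row, col)``; a pixel
      belongs to the ROI when its center ``(r + 0.5, c + 0.5)`` lies inside.
    * ``pixels`` — explicit list of ``(row, col)`` pairs.

    The label ``"background"`` is reserved for off-tissue pixels.
    """

    label: str
    rectangle: tuple | None = None
    polygon: list | None = None
    pixels: list | None = None

    def __post_init__(self) -> None:
        n_set = sum(
            x is not None for x in (self.rectangle, self.polygon, self.pixels)
        )
        if n_set != 1:
            raise ValueError(
                "exactly one of rectangle, polygon or pixels must be given"
            )

    @classmethod
    def rect(cls, label: str, r0: int, c0: int, r1: int, c1: int) -> "ROISpec":
        return cls(label=label, rectangle=(r0, c0, r1, c1))

    @classmethod
    def poly(cls, label: str, vertices: Iterable) -> "ROISpec":
        return cls(label=label, polygon=[tuple(v) for v in vertices])

    @classmethod
    def from_pixels(cls, label: str, pixels: Iterable) -> "ROISpec":
        return cls(label=label, pixels=[tuple(p) for p in pixels])

    def resolve(self, grid: PixelGrid) -> set[tuple[int, int]]:
        """Resolve to the set of (row, col) pixels; must be non-empty and
        inside the grid."""
        if self.rectangle is not None:
            r0, c0, r1, c1 = self.rectangle
            out = {
                (r, c)
                for r in range(max(r0, 0), min(r1, grid.n_rows))
                for c in range(max(c0, 0), min(c1, grid.n_cols))
            }
            if r0 < 0 or c0 < 0 or r1 > grid.n_rows or c1 > grid.n_cols:
                raise ValueError(
                    f"ROI {self.label!r}: rectangle extends outside the grid"
                )
        elif self.polygon is not None:
            path = MplPath([(c, r) for r, c in self.polygon])
            coords = grid.row_major_coords()
            centers = np.column_stack(
                [coords[:, 1] + 0.5, coords[:, 0] + 0.5]
            )
            inside = path.contains_points(centers)
            out = {tuple(map(int, rc)) for rc in coords[inside]}
        else:
            out = set()
            for r, c in self.pixels:
                if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                    raise ValueError(
                        f"ROI {self.label!r}: pixel ({r}, {c}) outside the grid"
                    )
                out.add((int(r), int(c)))
        if not out:
            raise ValueError(f"ROI {self.label!r} resolves to no pixels")
        return out

    def to_dict(self) -> dict:
        d = {"label": self.label}
        if self.rectangle is not None:
            d["shape"] = "rectangle"
            d["bounds"] = list(self.rectangle)
        elif self.polygon is not None:
            d["shape"] = "polygon"
            d["vertices"] = [list(v) for v in self.polygon]
        else:
            d["shape"] = "pixels"
            d["pixels"] = [list(p) for p in self.pixels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        shape = d["shape"]
        if shape == "rectangle":
            return cls(label=d["label"], rectangle=tuple(d["bounds"]))
        if shape == "polygon":
            return cls(
                label=d["label"], polygon=[tuple(v) for v in d["vertices"]]
            )
        if shape == "pixels":
            return cls(
                label=d["label"], pixels=[tuple(p) for p in d["pixels"]]
            )
        raise ValueError(f"unknown ROI shape {shape!r}")


def rois_to_json(specs: Sequence[ROISpec], path=None) -> str:
    """Serialize ROI specs to JSON (returned; also written when ``path``)."""
    text = json.dumps([s.to_dict() for s in specs], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def rois_from_json(source) -> list[ROISpec]:
    """Load ROI specs from a JSON string or file path."""
    try:
        data = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            data = json.load(fh)
    return [ROISpec.from_dict(d) for d in data]


def label_rois(image: MRMImage, specs: Sequence[ROISpec]) -> MRMImage:
    """Apply ROI labels to an acquisition's pixels.

    Specs must resolve to disjoint pixel sets; overlap raises an error naming
    the offending labels. Returns a relabeled copy; existing labels on pixels
    not covered by any spec are kept.
    """
    if image.is_combined:
        raise ValueError("label ROIs per acquisition, before combining")
    resolved: dict[str, set] = {}
    for spec in specs:
        resolved[spec.label] = spec.resolve(image.grid)
    keys = list(resolved)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if resolved[a] & resolved[b]:
                raise ValueError(f"ROIs {a!r} and {b!r} overlap")
    out = image.copy()
    index = {
        (int(r), int(c)): k for k, (r, c) in enumerate(image.pixel_coords)
    }
    for label, pixset in resolved.items():
        for rc in pixset:
            out.pixel_labels[index[rc]] = label
    return out


# ---------------------------------------------------------------------------
# Signal-to-noise
# ---------------------------------------------------------------------------


@dataclass
class SNRResult:
    """Per-pixel S/N against per-acquisition background noise.

    ``noise`` is a DataFrame (acquisition sample_id × transition label) of
    mean background responses; ``snr`` the (pixel, transition) matrix.
    Channels whose background is all zero in an acquisition fall back to the
    smallest positive background response; if none exists the channel is
    recorded in ``no_noise_estimate`` and its S/N set to +inf where the
    response is positive, 0 elsewhere.
    """

    noise: pd.DataFrame
    snr: np.ndarray
    detection_threshold: float = DETECTION_SNR
    quantification_threshold: float = QUANTIFICATION_SNR
    no_noise_estimate: list = field(default_factory=list)


def compute_snr(
    image: MRMImage,
    detection_threshold: float = DETECTION_SNR,
    quantification_threshold: float = QUANTIFICATION_SNR,
) -> SNRResult:
    """Compute per-pixel S/N with noise = mean background response.

    Noise is estimated per acquisition (background pixels come from the same
    DESI run); not-acquired sentinels are excluded. Raises
    :class:`~mrmsi.core_io.StateError` when an acquisition has no background
    pixels.
    """
    samples = pd.unique(image.pixel_samples)
    t_labels = image.transition_labels
    noise = pd.DataFrame(
        np.nan, index=list(samples), columns=t_labels, dtype=float
    )
    snr = np.full_like(image.responses, np.nan)
    no_noise: list[tuple[str, str]] = []
    for s in samples:
        in_sample = image.pixel_samples == s
        bg = in_sample & (image.pixel_labels == BACKGROUND_LABEL)
        if not bg.any():
            raise StateError(
                f"acquisition {s!r} has no pixels labeled "
                f"{BACKGROUND_LABEL!r}; cannot estimate noise"
            )
        bg_resp = image.responses[bg]
        for j, lbl in enumerate(t_labels):
            col = bg_resp[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                # channel not acquired in this run
                no_noise.append((s, lbl))
                continue
            nz = float(col.mean())
            if nz == 0.0:
                pos = col[col > 0]
                if pos.size:
                    nz = float(pos.min())
                else:
                    no_noise.append((s, lbl))
                    resp = image.responses[in_sample, j]
                    out = np.where(resp > 0, np.inf, 0.0)
                    out[~np.isfinite(resp)] = np.nan
                    snr[in_sample, j] = out
                    continue
            noise.loc[s, lbl] = nz
            snr[in_sample, j] = image.responses[in_sample, j] / nz
    return SNRResult(
        noise=noise,
        snr=snr,
        detection_threshold=detection_threshold,
        quantification_threshold=quantification_threshold,
        no_noise_estimate=no_noise,
    )


def gate(snr_result: SNRResult, purpose: str = "detection") -> np.ndarray:
    """Boolean (pixel, transition) mask of pixels passing the S/N gate.

    ``purpose`` is ``"detection"`` (S/N > 3) or ``"quantification"``
    (S/N > 5); the inequality is strict, and NaN S/N never passes.
    """
    if purpose == "detection":
        thr = snr_result.detection_threshold
    elif purpose == "quantification":
        thr = snr_result.quantification_threshold
    else:
        raise ValueError(f"unknown gating purpose {purpose!r}")
    with np.errstate(invalid="ignore"):
        return snr_result.snr > thr


def remove_blank_channels(
    image: MRMImage,
    snr_result: SNRResult,
    min_frac: float = 0.01,
) -> tuple[MRMImage, pd.DataFrame]:
    """Drop MRM channels that are blank on tissue.

    A channel is blank when fewer than ``min_frac`` of the non-background
    pixels pass the detection gate (a channel at exactly ``min_frac`` is
    retained). Returns the filtered image and a removal log with the
    detected-pixel counts per channel. Removing every channel is allowed
    (empty image) and noted in the log.
    """
    tissue = image.pixel_labels != BACKGROUND_LABEL
    n_tissue = int(tissue.sum())
    detected = gate(snr_result, "detection")
    keep, records = [], []
    for j, lbl in enumerate(image.transition_labels):
        n_det = int(detected[tissue, j].sum())
        retained = n_det >= min_frac * n_tissue
        keep.append(retained)
        records.append(
            {
                "transition": lbl,
                "n_detected": n_det,
                "n_tissue": n_tissue,
                "removed": not retained,
            }
        )
    log = pd.DataFrame.from_records(records).set_index("transition")
    out = image.copy()
    out.transitions = [t for t, k in zip(image.transitions, keep) if k]
    out.responses = image.responses[:, np.asarray(keep, dtype=bool)]
    return out, log


def normalize_to_solvent_standard(
    image: MRMImage,
    standard_channel: str,
    epsilon: float = 1.0,
) -> tuple[MRMImage, np.ndarray]:
    """Divide every response by the solvent-standard response, pixelwise.

    The divisor is ``max(standard, epsilon)`` so tissue voids (standard ≈ 0)
    do not explode; pixels where the standard fell below ``epsilon`` are
    returned as a flag mask because ratios there are artifacts. This step is
    deliberately not part of the default pipeline.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    j = image.transition_index(standard_channel)
    std = image.responses[:, j]
    divisor = np.maximum(std, epsilon)
    flagged = ~(std > epsilon)
    out = image.copy()
    out.responses = image.responses / divisor[:, None]
    return out, flagged
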
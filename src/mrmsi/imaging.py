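"""Ion-image rendering with quantile suppression and thresholding.

Each MRM transition is rendered as a 2-D raster where the pixel's response,
S/N, or estimated concentration maps to a scaled color. Two quantile
operations make low-abundance pixels visible: *suppression* clips values
above an upper quantile (so a few hot pixels do not dominate the color
scale) and *thresholding* zeroes values below a lower quantile (removing
residual background). Quantiles are pinned to the lower order statistic
(``numpy.quantile(..., method="lower")``) — under that definition
suppression is exactly idempotent, which interpolated definitions break —
and are computed over tissue (non-background) pixels by default;
null pixels (not acquired / not quantified) are excluded from the quantile
computation and rendered in a distinct null color.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .core_io import BACKGROUND_LABEL, MRMImage, StateError
from .preprocess import SNRResult

__all__ = [
    "RenderSpec",
    "RenderResult",
    "suppress_quantile",
    "threshold_quantile",
    "render_ion_image",
    "save_png",
]

#: RGBA used for null (not acquired / not quantified) pixels.
NULL_COLOR = (0.35, 0.35, 0.35, 1.0)


@dataclass
class RenderSpec:
    """Rendering options for one ion image."""

    value_layer: str = "response"
    suppress_quantile: float = 0.99
    threshold_quantile: float = 0.0
    colormap: str = "viridis"
    quantiles_over: str = "tissue"  # or "all"

    def __post_init__(self) -> None:
        if not (0 < self.suppress_quantile <= 1):
            raise ValueError("suppress_quantile must be in (0, 1]")
        if not (0 <= self.threshold_quantile < 1):
            raise ValueError("threshold_quantile must be in [0, 1)")
        if self.threshold_quantile >= self.suppress_quantile:
            raise ValueError(
                "threshold_quantile must be below suppress_quantile"
            )
        if self.value_layer not in ("response", "snr", "concentration"):
            raise ValueError(f"unknown value layer {self.value_layer!r}")
        if self.quantiles_over not in ("tissue", "all"):
            raise ValueError("quantiles_over must be 'tissue' or 'all'")


def _quantile(values: np.ndarray, q: float, reference=None) -> float:
    ref = values if reference is None else reference
    ref = np.asarray(ref, float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("no finite values to compute a quantile over")
    return float(np.quantile(ref, q, method="lower"))


def suppress_quantile(values, q: float, reference=None) -> np.ndarray:
    """Clip values above the q-quantile down to that quantile.

    The quantile is computed over the finite entries of ``reference``
    (default: the values themselves). ``q = 1`` is the identity; the
    operation is idempotent and never increases a value.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty input")
    cap = _quantile(values, q, reference)
    out = values.copy()
    finite = np.isfinite(out)
    out[finite] = np.minimum(out[finite], cap)
    return out


def threshold_quantile(values, q: float, reference=None) -> np.ndarray:
    """Zero values strictly below the q-quantile; others unchanged.

    ``q = 0`` is the identity. With all-equal values any q leaves the input
    unchanged, because the quantile equals the common value and the
    comparison is strict.
    """
    if not (0 <= q < 1):
        raise ValueError("q must be in [0, 1)")
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty input")
    floor = _quantile(values, q, reference)
    out = values.copy()
    finite = np.isfinite(out)
    out[finite & (values < floor)] = 0.0
    return out


@dataclass
class RenderResult:
    """A rendered ion image.

    ``rgba`` is the (n_rows, n_cols, 4) color raster; ``scaled`` the
    pre-colormap scalar field in [0, 1] (NaN at null pixels); ``legend``
    records the layer, quantiles and the pre-scaling min/max so the color
    scale can be reconstructed.
    """

    rgba: np.ndarray
    scaled: np.ndarray
    legend: dict


def render_ion_image(
    image: MRMImage,
    transition: str,
    spec: RenderSpec | None = None,
    snr: SNRResult | None = None,
    concentrations: np.ndarray | None = None,
) -> RenderResult:
    """Render one transition of a single acquisition as a colored raster.

    Pipeline: threshold → suppress → min-max scale to [0, 1] → colormap.
    The pipeline is deterministic — re-rendering with an identical spec is
    bit-identical — and monotone in the pixel values.
    """
    spec = spec or RenderSpec()
    if image.is_combined:
        raise ValueError("render one acquisition at a time")
    j = image.transition_index(transition)
    if spec.value_layer == "response":
        vals = image.responses[:, j].astype(float)
    elif spec.value_layer == "snr":
        if snr is None:
            raise StateError("snr layer requested but no SNRResult supplied")
        vals = snr.snr[:, j].astype(float)
    else:
        if concentrations is None:
            raise StateError(
                "concentration layer requested but none supplied"
            )
        vals = np.asarray(concentrations, float)
        if vals.shape != (image.n_pixels,):
            raise ValueError("concentrations must be one value per pixel")

    if spec.quantiles_over == "tissue":
        ref_mask = image.pixel_labels != BACKGROUND_LABEL
    else:
        ref_mask = np.ones(image.n_pixels, dtype=bool)
    reference = vals[ref_mask & np.isfinite(vals)]
    if reference.size == 0:
        reference = vals[np.isfinite(vals)]

    lo_q = _quantile(vals, spec.threshold_quantile, reference)
    hi_q = _quantile(vals, spec.suppress_quantile, reference)
    piped = threshold_quantile(vals, spec.threshold_quantile, reference)
    piped = suppress_quantile(piped, spec.suppress_quantile, reference)

    finite = np.isfinite(piped)
    vmin = float(piped[finite].min())
    vmax = float(piped[finite].max())
    scaled = np.full(image.n_pixels, np.nan)
    if vmax > vmin:
        scaled[finite] = (piped[finite] - vmin) / (vmax - vmin)
    else:
        scaled[finite] = 0.0

    cmap = colormaps[spec.colormap]
    rgba_flat = np.empty((image.n_pixels, 4))
    rgba_flat[finite] = cmap(scaled[finite])
    rgba_flat[~finite] = NULL_COLOR

    grid = image.grid
    raster = np.full((grid.n_rows, grid.n_cols, 4), NULL_COLOR)
    scaled_raster = np.full((grid.n_rows, grid.n_cols), np.nan)
    rows = image.pixel_coords[:, 0]
    cols = image.pixel_coords[:, 1]
    raster[rows, cols] = rgba_flat
    scaled_raster[rows, cols] = scaled

    legend = {
        "transition": transition,
        "layer": spec.value_layer,
        "colormap": spec.colormap,
        "threshold_quantile": spec.threshold_quantile,
        "suppress_quantile": spec.suppress_quantile,
        "threshold_value": lo_q,
        "suppress_value": hi_q,
        "min": vmin,
        "max": vmax,
        "n_null_pixels": int((~finite).sum()),
    }
    return RenderResult(rgba=raster, scaled=scaled_raster, legend=legend)


def save_png(result: RenderResult, path, legend_path=None) -> str:
    """Write the raster as PNG (and the legend as sidecar JSON)."""
    import json

    from PIL import Image

    arr = (np.clip(result.rgba, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGBA").save(path)
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            json.dump(result.legend, fh, indent=1)
    return str(path)
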
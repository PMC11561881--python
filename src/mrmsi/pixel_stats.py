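"""Pixel-level nonparametric statistics for ROI contrasts.

For tissue-type comparisons (e.g. airways vs parenchyma), a fixed number of
pixels (default 50) is sampled uniformly without replacement from each ROI
and each retained transition is tested with a two-sided
Mann–Whitney–Wilcoxon test; p-values are corrected across transitions with
the Benjamini–Hochberg step-up FDR procedure.

The Mann–Whitney implementation uses midranks for ties, an exact null
distribution (computed by the standard count recurrence) when the combined
sample size is at most 16 and there are no ties, and otherwise the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MRMImage
from .preprocess import SNRResult

__all__ = [
    "PixelSample",
    "MannWhitneyResult",
    "sample_roi_pixels",
    "mann_whitney_u",
    "bh_fdr",
    "compare_rois",
    "boxplot_summary",
]

#: Combined sample size at or below which the exact null is used (no ties).
EXACT_N_MAX = 16


@dataclass
class PixelSample:
    """A seeded random sample of pixels from one ROI.

    ``values`` is the (pixel, transition) matrix of the sampled pixels;
    sampling is uniform without replacement and reproducible under ``seed``.
    """

    roi_label: str
    pixel_ids: np.ndarray
    values: np.ndarray
    n_requested: int
    seed: int


def sample_roi_pixels(
    image: MRMImage,
    roi_label: str,
    n: int = 50,
    seed: int = 0,
    layer: np.ndarray | None = None,
) -> PixelSample:
    """Sample ``n`` pixels uniformly without replacement from an ROI.

    If the ROI holds fewer than ``n`` pixels, all of them are returned with a
    warning. ``layer`` optionally substitutes a (pixel, transition) value
    matrix (e.g. S/N) for the raw responses.
    """
    idx = np.flatnonzero(image.pixel_labels == roi_label)
    if idx.size == 0:
        raise KeyError(f"no pixels labeled {roi_label!r}")
    values = image.responses if layer is None else np.asarray(layer, float)
    if idx.size <= n:
        if idx.size < n:
            warnings.warn(
                f"ROI {roi_label!r} has only {idx.size} pixels "
                f"(requested {n}); returning all"
            )
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(idx, size=n, replace=False))
    return PixelSample(
        roi_label=roi_label,
        pixel_ids=chosen,
        values=values[chosen],
        n_requested=n,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


class MannWhitneyResult(NamedTuple):
    u: float
    p: float
    method: str
    degenerate: bool


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Null distribution of U as arrangement counts, by the recurrence
    N(u; n1, n2) = N(u − n2; n1 − 1, n2) + N(u; n1, n2 − 1)."""
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, cnt in enumerate(a):
        out[u + n2] += cnt
    for u, cnt in enumerate(b):
        out[u] += cnt
    return tuple(out)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney–Wilcoxon test.

    Returns the U statistic of group ``a`` (computed from rank sums with
    midranks for ties) and the two-sided p-value. ``method`` is ``"auto"``
    (exact when the combined n ≤ 16 and there are no ties), ``"exact"``, or
    ``"asymptotic"`` (normal approximation with tie and continuity
    corrections). When every pooled value is identical the test is
    degenerate and p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    nn = n1 + n2
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    uniq, counts = np.unique(pooled, return_counts=True)
    has_ties = uniq.size < nn
    if uniq.size == 1:
        return MannWhitneyResult(u=u1, p=1.0, method="degenerate", degenerate=True)

    if method == "auto":
        method = "exact" if (nn <= EXACT_N_MAX and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        dist = np.array(_u_counts(n1, n2), dtype=float)
        total = dist.sum()
        k = int(round(u1))
        cdf = dist[: k + 1].sum() / total
        sf = dist[k:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return MannWhitneyResult(u=u1, p=p, method="exact", degenerate=False)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    mu = n1 * n2 / 2.0
    tie_term = float(((counts**3 - counts).sum()) / (nn * (nn - 1)))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u=u1, p=1.0, method="degenerate", degenerate=True)
    # continuity correction toward the mean
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return MannWhitneyResult(u=u1, p=p, method="asymptotic", degenerate=False)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    ``q_i = min_{j ≥ rank(i)} p_(j) · m / j``, capped at 1, returned in the
    original order. Inputs outside [0, 1] raise.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def boxplot_summary(values: Sequence[float]) -> dict:
    """Median, quartiles and Tukey 1.5·IQR whiskers for boxplot output."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {k: np.nan for k in ("median", "q1", "q3", "lo", "hi", "n")}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "lo": float(in_lo.min()),
        "hi": float(in_hi.max()),
        "n": int(v.size),
    }


def compare_rois(
    image: MRMImage,
    roi_a: str,
    roi_b: str,
    n: int = 50,
    seed: int = 0,
    layer: str = "response",
    snr: SNRResult | None = None,
) -> pd.DataFrame:
    """Per-transition Mann–Whitney contrast between two ROIs.

    Samples ``n`` pixels per ROI (same seed for both, so identical ROIs
    yield identical samples), tests each transition two-sided, corrects
    across transitions with BH-FDR, and returns boxplot-ready summaries.
    ``layer`` is ``"response"`` (default) or ``"snr"``.
    """
    if layer == "snr":
        if snr is None:
            raise ValueError("layer='snr' requires an SNRResult")
        values = snr.snr
    elif layer == "response":
        values = None
    else:
        raise ValueError(f"unknown value layer {layer!r}")
    sa = sample_roi_pixels(image, roi_a, n=n, seed=seed, layer=values)
    sb = sample_roi_pixels(image, roi_b, n=n, seed=seed, layer=values)
    rows = []
    for j, lbl in enumerate(image.transition_labels):
        va = sa.values[:, j]
        vb = sb.values[:, j]
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        res = mann_whitney_u(va, vb)
        row = {"transition": lbl, "U": res.u, "p": res.p}
        for suffix, summ in (("a", boxplot_summary(va)), ("b", boxplot_summary(vb))):
            for k, v in summ.items():
                row[f"{k}_{suffix}"] = v
        rows.append(row)
    out = pd.DataFrame.from_records(rows).set_index("transition")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
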
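"""Core data model and I/O for MRM-based mass spectrometry imaging.

A targeted (multiple-reaction-monitoring) imaging acquisition measures, at
every raster position ("pixel") of the sample stage, one response per MRM
channel — a fixed precursor→product ion transition on a triple-quadrupole
instrument. This module defines the in-memory containers (transition, pixel
grid, image cube), a documented tab-separated text dialect for interchange,
harmonization of transitions across acquisitions onto a common axis, the
combination of acquisitions into one study-level experiment, and export to
conventional omics matrices (lipids in rows).

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``, row-major, origin at the
  top-left of the raster; in the text dialect ``x`` is the column index and
  ``y`` the row index.
* A response is a non-negative, finite MS count. The value ``NaN`` is the
  "not acquired" sentinel (a channel absent from one member of a combined
  study) and is distinct from a measured zero.
* The reserved ROI label ``"background"`` marks off-tissue pixels used for
  noise estimation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAX_TRANSITIONS",
    "BACKGROUND_LABEL",
    "FormatError",
    "StateError",
    "MRMTransition",
    "PixelGrid",
    "MRMImage",
    "TransitionAxis",
    "MatrixExport",
    "read_mrm_txt",
    "write_mrm_txt",
    "build_common_axis",
    "combine_experiments",
    "export_matrix",
    "write_matrix_csv",
    "read_matrix_csv",
]

#: Instrument limit on simultaneously monitored transitions per acquisition.
MAX_TRANSITIONS = 32

#: Reserved ROI label for off-tissue pixels.
BACKGROUND_LABEL = "background"

#: Default Q1/Q3 matching window (Th) for unit-resolution quadrupoles.
DEFAULT_MZ_TOLERANCE = 0.1


class FormatError(ValueError):
    """Raised when a file does not conform to the MRM-MSI text dialect."""


class StateError(RuntimeError):
    """Raised when an operation is requested before its inputs exist."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRMTransition:
    """One MRM channel: precursor m/z → product m/z at a collision energy.

    Parameters
    ----------
    label
        Free-text analyte name, unique within a transition axis.
    precursor_mz, product_mz
        Q1 and Q3 m/z in thomson. The product may exceed the precursor by at
        most 1.0 Th (isotope/adduct slack).
    collision_energy
        Collision energy in eV.
    cone_voltage
        Cone voltage in V.
    polarity
        Ionization polarity, ``"negative"`` or ``"positive"``.
    """

    label: str
    precursor_mz: float
    product_mz: float
    collision_energy: float = 0.0
    cone_voltage: float = 0.0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("precursor_mz and product_mz must be positive")
        if self.product_mz > self.precursor_mz + 1.0:
            raise ValueError(
                f"product m/z {self.product_mz} exceeds precursor "
                f"{self.precursor_mz} by more than 1.0 Th"
            )
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def channel_id(self) -> str:
        """Column identifier in the text dialect: ``Q1>Q3@CE``."""
        return (
            f"{self.precursor_mz:g}>{self.product_mz:g}@{self.collision_energy:g}"
        )

    def matches(self, other: "MRMTransition", mz_tolerance: float) -> bool:
        """True when both Q1 and Q3 agree within ``mz_tolerance`` Th."""
        return (
            abs(self.precursor_mz - other.precursor_mz) <= mz_tolerance
            and abs(self.product_mz - other.product_mz) <= mz_tolerance
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MRMTransition":
        return cls(**d)


@dataclass(frozen=True)
class PixelGrid:
    """Raster geometry of a DESI acquisition.

    ``pixel_size`` is the square pixel edge in μm; ``scan_rate`` the stage
    scan rate in Hz.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 50.0
    scan_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def row_major_coords(self) -> np.ndarray:
        """(n_pixels, 2) array of (row, col), row-major order."""
        rr, cc = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return np.column_stack([rr.ravel(), cc.ravel()])


@dataclass
class MRMImage:
    """Per-pixel MRM response cube with pixel, transition and sample metadata.

    ``responses`` is ``(n_pixels, n_transitions)``; measured values are finite
    and non-negative, NaN marks "not acquired". ``pixel_labels`` holds one ROI
    label per pixel (empty string = unlabeled; ``"background"`` reserved).
    ``pixel_samples`` carries the originating acquisition per pixel and allows
    a combined study to retain per-acquisition provenance.
    """

    grid: PixelGrid
    transitions: list[MRMTransition]
    responses: np.ndarray
    sample_id: str = "sample"
    acquisition_date: datetime.date = datetime.date(2024, 1, 1)
    pixel_labels: np.ndarray | None = None
    pixel_coords: np.ndarray | None = None
    pixel_samples: np.ndarray | None = None
    read_log: list = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        n = self.responses.shape[0]
        if self.responses.ndim != 2 or self.responses.shape[1] != len(
            self.transitions
        ):
            raise ValueError("responses must be (n_pixels, n_transitions)")
        if len(self.transitions) > MAX_TRANSITIONS:
            raise ValueError(
                f"at most {MAX_TRANSITIONS} MRM transitions per acquisition"
            )
        labels = [t.label for t in self.transitions]
        if len(set(labels)) != len(labels):
            raise ValueError("transition labels must be unique")
        finite = self.responses[np.isfinite(self.responses)]
        if np.isinf(self.responses).any():
            raise ValueError("responses must be finite or NaN (not acquired)")
        if (finite < 0).any():
            raise ValueError("responses must be non-negative")
        if self.pixel_coords is None:
            if n != self.grid.n_pixels:
                raise ValueError(
                    "pixel count does not match grid; pass pixel_coords "
                    "explicitly for partial/combined images"
                )
            self.pixel_coords = self.grid.row_major_coords()
        else:
            self.pixel_coords = np.asarray(self.pixel_coords, dtype=int)
            if self.pixel_coords.shape != (n, 2):
                raise ValueError("pixel_coords must be (n_pixels, 2)")
        if self.pixel_labels is None:
            self.pixel_labels = np.full(n, "", dtype=object)
        else:
            self.pixel_labels = np.asarray(self.pixel_labels, dtype=object)
            if self.pixel_labels.shape != (n,):
                raise ValueError("pixel_labels must have one entry per pixel")
        if self.pixel_samples is None:
            self.pixel_samples = np.full(n, self.sample_id, dtype=object)
        else:
            self.pixel_samples = np.asarray(self.pixel_samples, dtype=object)
            if self.pixel_samples.shape != (n,):
                raise ValueError("pixel_samples must have one entry per pixel")
        oob = (
            (self.pixel_coords[:, 0] < 0)
            | (self.pixel_coords[:, 0] >= self.grid.n_rows)
            | (self.pixel_coords[:, 1] < 0)
            | (self.pixel_coords[:, 1] >= self.grid.n_cols)
        )
        # Combined multi-acquisition images may exceed the nominal grid of
        # their first member; only enforce bounds for single acquisitions.
        if not self.is_combined and oob.any():
            raise ValueError("pixel coordinates outside the grid")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.responses.shape[0]

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    @property
    def transition_labels(self) -> list[str]:
        return [t.label for t in self.transitions]

    @property
    def is_combined(self) -> bool:
        return len(set(self.pixel_samples.tolist())) > 1

    def transition_index(self, label: str) -> int:
        for i, t in enumerate(self.transitions):
            if t.label == label:
                return i
        raise KeyError(f"unknown transition {label!r}")

    def pixel_ids(self) -> list[str]:
        """Per-pixel identifiers ``sample:row:col``."""
        return [
            f"{s}:{r}:{c}"
            for s, (r, c) in zip(self.pixel_samples, self.pixel_coords)
        ]

    def pixel_index(self) -> dict[tuple, int]:
        """Map (sample, row, col) → flat pixel index."""
        return {
            (s, int(r), int(c)): i
            for i, (s, (r, c)) in enumerate(
                zip(self.pixel_samples, self.pixel_coords)
            )
        }

    def copy(self) -> "MRMImage":
        return MRMImage(
            grid=self.grid,
            transitions=list(self.transitions),
            responses=self.responses.copy(),
            sample_id=self.sample_id,
            acquisition_date=self.acquisition_date,
            pixel_labels=self.pixel_labels.copy(),
            pixel_coords=self.pixel_coords.copy(),
            pixel_samples=self.pixel_samples.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MRMImage):
            return NotImplemented
        return (
            self.grid == other.grid
            and self.transitions == other.transitions
            and self.sample_id == other.sample_id
            and self.acquisition_date == other.acquisition_date
            and np.array_equal(self.responses, other.responses, equal_nan=True)
            and np.array_equal(self.pixel_labels, other.pixel_labels)
            and np.array_equal(self.pixel_coords, other.pixel_coords)
            and np.array_equal(self.pixel_samples, other.pixel_samples)
        )


@dataclass
class TransitionAxis:
    """Harmonized list of MRM channels shared across acquisitions.

    No two axis entries may match each other within ``mz_tolerance`` on both
    Q1 and Q3; every member image's channels map to exactly one entry or none.
    """

    transitions: list[MRMTransition]
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE

    def __post_init__(self) -> None:
        for i, a in enumerate(self.transitions):
            for b in self.transitions[i + 1 :]:
                if a.matches(b, self.mz_tolerance):
                    raise ValueError(
                        f"axis entries {a.label!r} and {b.label!r} match "
                        f"within {self.mz_tolerance} Th"
                    )

    def __len__(self) -> int:
        return len(self.transitions)

    def match(self, channel: MRMTransition) -> int | None:
        """Index of the unique axis entry matching ``channel``, or None."""
        hits = [
            i
            for i, t in enumerate(self.transitions)
            if t.matches(channel, self.mz_tolerance)
        ]
        if len(hits) > 1:
            raise ValueError(
                f"channel {channel.label!r} matches {len(hits)} axis entries"
            )
        return hits[0] if hits else None


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

_DIALECT_MAGIC = "MRMSI"
_DIALECT_VERSION = "1"
_MISSING_TOKEN = "NA"


def _fmt(x: float) -> str:
    """Shortest decimal representation that round-trips the float."""
    if math.isnan(x):
        return _MISSING_TOKEN
    return repr(float(x))


def write_mrm_txt(image: MRMImage, path) -> str:
    """Write ``image`` in the MRM-MSI tab-separated dialect.

    The file has a ``#``-prefixed header block (grid dimensions, pixel size,
    scan rate, sample id, acquisition date, transition metadata as JSON)
    followed by one data row per pixel with columns ``x`` (column index),
    ``y`` (row index), one response column per transition named ``Q1>Q3@CE``,
    and a trailing ``roi_label`` column. Reading the file back reproduces the
    image bit-exactly.
    """
    if image.is_combined:
        raise ValueError("combined studies cannot be written as one acquisition")
    lines = [
        f"# {_DIALECT_MAGIC}\t{_DIALECT_VERSION}",
        f"# sample_id\t{image.sample_id}",
        f"# acquisition_date\t{image.acquisition_date.isoformat()}",
        f"# n_rows\t{image.grid.n_rows}",
        f"# n_cols\t{image.grid.n_cols}",
        f"# pixel_size_um\t{_fmt(image.grid.pixel_size)}",
        f"# scan_rate_hz\t{_fmt(image.grid.scan_rate)}",
        "# transition_meta\t"
        + json.dumps([t.to_dict() for t in image.transitions]),
    ]
    header = ["x", "y"] + [t.channel_id for t in image.transitions] + ["roi_label"]
    lines.append("\t".join(header))
    for i in range(image.n_pixels):
        r, c = image.pixel_coords[i]
        row = [str(int(c)), str(int(r))]
        row += [_fmt(v) for v in image.responses[i]]
        row.append(str(image.pixel_labels[i]))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def _parse_header(lines: list[str]) -> dict:
    meta: dict = {}
    for ln in lines:
        body = ln[1:].strip()
        if "\t" not in body:
            if body in (_DIALECT_MAGIC, f"{_DIALECT_MAGIC} {_DIALECT_VERSION}"):
                continue
            raise FormatError(f"malformed header line: {ln!r}")
        key, _, value = body.partition("\t")
        meta[key] = value
    return meta


def read_mrm_txt(path, dialect: dict | None = None) -> MRMImage:
    """Read an acquisition from the MRM-MSI text dialect.

    Pixels absent from the file are filled with 0 responses and listed in the
    returned image's ``read_log``. Duplicate pixel coordinates, malformed
    headers and negative responses raise :class:`FormatError`.

    The ``dialect`` mapping may override ``delimiter`` (default tab) and
    ``missing`` (default ``"NA"``, read as the not-acquired sentinel).
    """
    dialect = dialect or {}
    sep = dialect.get("delimiter", "\t")
    missing = dialect.get("missing", _MISSING_TOKEN)

    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header_lines = [ln for ln in raw if ln.startswith("#")]
    data_lines = [ln for ln in raw if not ln.startswith("#")]
    if not header_lines or not data_lines:
        raise FormatError("file lacks a header block or data rows")
    meta = _parse_header(header_lines)
    try:
        n_rows = int(meta["n_rows"])
        n_cols = int(meta["n_cols"])
        grid = PixelGrid(
            n_rows=n_rows,
            n_cols=n_cols,
            pixel_size=float(meta.get("pixel_size_um", 50.0)),
            scan_rate=float(meta.get("scan_rate_hz", 4.0)),
        )
        sample_id = meta["sample_id"]
        date = datetime.date.fromisoformat(
            meta.get("acquisition_date", "2024-01-01")
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed header: {exc}") from exc

    columns = data_lines[0].split(sep)
    if columns[:2] != ["x", "y"]:
        raise FormatError("first two data columns must be 'x' and 'y'")
    has_labels = columns[-1] == "roi_label"
    channel_cols = columns[2 : -1 if has_labels else len(columns)]

    if "transition_meta" in meta:
        transitions = [
            MRMTransition.from_dict(d) for d in json.loads(meta["transition_meta"])
        ]
        if len(transitions) != len(channel_cols):
            raise FormatError("transition_meta does not match data columns")
    else:
        transitions = []
        for col in channel_cols:
            try:
                q1q3, _, ce = col.partition("@")
                q1, _, q3 = q1q3.partition(">")
                transitions.append(
                    MRMTransition(
                        label=col,
                        precursor_mz=float(q1),
                        product_mz=float(q3),
                        collision_energy=float(ce or 0.0),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"cannot parse channel column {col!r}") from exc

    responses = np.zeros((grid.n_pixels, len(transitions)))
    labels = np.full(grid.n_pixels, "", dtype=object)
    seen = np.zeros(grid.n_pixels, dtype=bool)
    for ln in data_lines[1:]:
        parts = ln.split(sep)
        if len(parts) != len(columns):
            raise FormatError(f"row has {len(parts)} fields, expected {len(columns)}")
        c, r = int(parts[0]), int(parts[1])
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise FormatError(f"pixel ({r}, {c}) outside {n_rows}x{n_cols} grid")
        idx = r * n_cols + c
        if seen[idx]:
            raise FormatError(f"duplicate pixel coordinate ({r}, {c})")
        seen[idx] = True
        vals = parts[2 : 2 + len(transitions)]
        for j, v in enumerate(vals):
            if v == missing:
                responses[idx, j] = np.nan
            else:
                x = float(v)
                if x < 0:
                    raise FormatError(f"negative response at pixel ({r}, {c})")
                responses[idx, j] = x
        if has_labels:
            labels[idx] = parts[-1]

    log: list[str] = []
    n_missing = int((~seen).sum())
    if n_missing:
        log.append(f"{n_missing} missing pixel(s) filled with 0")
    img = MRMImage(
        grid=grid,
        transitions=transitions,
        responses=responses,
        sample_id=sample_id,
        acquisition_date=date,
        pixel_labels=labels,
    )
    img.read_log = log
    return img


# ---------------------------------------------------------------------------
# Common axis & combination
# ---------------------------------------------------------------------------


def build_common_axis(
    images: Sequence[MRMImage],
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
) -> tuple[TransitionAxis, dict]:
    """Set a common MRM axis across acquisitions so they can be merged.

    Channels are grouped into equivalence classes whose Q1 and Q3 both agree
    within ``mz_tolerance``; the class representative is the channel from the
    earliest-acquired image. Returns the axis together with a mapping
    ``(sample_id, channel label) → axis index``.

    Raises
    ------
    ValueError
        If two channels within one image match each other, or a channel
        matches two axis entries (ambiguity).
    """
    if not images:
        raise ValueError("at least one image is required")
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be positive")

    for img in images:
        for i, a in enumerate(img.transitions):
            for b in img.transitions[i + 1 :]:
                if a.matches(b, mz_tolerance):
                    raise ValueError(
                        f"channels {a.label!r} and {b.label!r} within image "
                        f"{img.sample_id!r} match each other"
                    )

    order = sorted(range(len(images)), key=lambda i: images[i].acquisition_date)
    axis_entries: list[MRMTransition] = []
    mapping: dict = {}
    for i in order:
        img = images[i]
        for ch in img.transitions:
            hits = [
                k for k, t in enumerate(axis_entries) if t.matches(ch, mz_tolerance)
            ]
            if len(hits) > 1:
                raise ValueError(
                    f"channel {ch.label!r} of {img.sample_id!r} matches "
                    f"{len(hits)} axis entries"
                )
            if hits:
                mapping[(img.sample_id, ch.label)] = hits[0]
            else:
                axis_entries.append(ch)
                mapping[(img.sample_id, ch.label)] = len(axis_entries) - 1
    return TransitionAxis(axis_entries, mz_tolerance), mapping


def combine_experiments(
    images: Sequence[MRMImage], axis: TransitionAxis
) -> MRMImage:
    """Combine acquisitions of one study onto a shared transition axis.

    The pixel table of the result is the concatenation of the member pixel
    tables; each pixel retains its originating ``sample_id``. Channels a
    member did not acquire are filled with the not-acquired sentinel (NaN),
    which downstream noise estimation excludes.
    """
    ids = [img.sample_id for img in images]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be distinct")
    blocks, coords, labels, samples = [], [], [], []
    for img in images:
        block = np.full((img.n_pixels, len(axis)), np.nan)
        for j, ch in enumerate(img.transitions):
            k = axis.match(ch)
            if k is None:
                raise ValueError(
                    f"channel {ch.label!r} of {img.sample_id!r} is not mapped "
                    "onto the common axis"
                )
            block[:, k] = img.responses[:, j]
        blocks.append(block)
        coords.append(img.pixel_coords)
        labels.append(img.pixel_labels)
        samples.append(img.pixel_samples)
    combined = MRMImage(
        grid=images[0].grid,
        transitions=list(axis.transitions),
        responses=np.vstack(blocks),
        sample_id="+".join(ids),
        acquisition_date=min(img.acquisition_date for img in images),
        pixel_coords=np.vstack(coords),
        pixel_labels=np.concatenate(labels),
        pixel_samples=np.concatenate(samples),
    )
    return combined


# ---------------------------------------------------------------------------
# Matrix export
# ---------------------------------------------------------------------------


@dataclass
class MatrixExport:
    """Omics-style matrix with transitions (lipids) in rows.

    ``matrix`` columns are pixels (``sample:row:col``) or ROI aggregates;
    ``row_meta`` and ``col_meta`` are the companion metadata tables.
    """

    matrix: pd.DataFrame
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame


def export_matrix(
    image: MRMImage,
    level: str = "pixel",
    value: str = "response",
    snr: np.ndarray | None = None,
    concentrations: np.ndarray | None = None,
) -> MatrixExport:
    """Export an analysis matrix with lipids in rows.

    ``level`` is ``"pixel"`` (one column per pixel) or ``"roi"`` (one column
    per ROI label, the mean over that ROI's pixels, not-acquired excluded).
    ``value`` selects the layer: ``"response"``, ``"snr"`` (pass the S/N
    matrix) or ``"concentration"`` (pass the per-pixel concentration vector
    or matrix).
    """
    if value == "response":
        data = image.responses
    elif value == "snr":
        if snr is None:
            raise StateError("S/N layer requested but no S/N result supplied")
        data = np.asarray(snr, dtype=float)
    elif value == "concentration":
        if concentrations is None:
            raise StateError(
                "concentration layer requested before quantification"
            )
        data = np.asarray(concentrations, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
    else:
        raise ValueError(f"unknown value layer {value!r}")
    if data.shape[0] != image.n_pixels:
        raise ValueError("layer shape does not match pixel count")
    n_t = data.shape[1]
    t_labels = image.transition_labels[:n_t]

    row_meta = pd.DataFrame(
        [t.to_dict() for t in image.transitions[:n_t]]
    ).set_index("label")

    if level == "pixel":
        cols = image.pixel_ids()
        matrix = pd.DataFrame(data.T, index=t_labels, columns=cols)
        col_meta = pd.DataFrame(
            {
                "sample_id": image.pixel_samples,
                "row": image.pixel_coords[:, 0],
                "col": image.pixel_coords[:, 1],
                "roi_label": image.pixel_labels,
            },
            index=cols,
        )
    elif level == "roi":
        roi_labels = sorted({l for l in image.pixel_labels.tolist() if l})
        if not roi_labels:
            raise StateError("no labeled ROIs to aggregate")
        cols = {}
        counts = {}
        for lbl in roi_labels:
            mask = image.pixel_labels == lbl
            with np.errstate(invalid="ignore"):
                cols[lbl] = np.nanmean(data[mask], axis=0)
            counts[lbl] = int(mask.sum())
        matrix = pd.DataFrame(cols, index=t_labels)
        col_meta = pd.DataFrame(
            {"n_pixels": pd.Series(counts)}, index=list(matrix.columns)
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    matrix.index.name = "lipid"
    return MatrixExport(matrix=matrix, row_meta=row_meta, col_meta=col_meta)


def write_matrix_csv(export: MatrixExport, path) -> str:
    export.matrix.to_csv(path)
    return str(path)


def read_matrix_csv(path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be off by an ulp
    return pd.read_csv(path, index_col=0, float_precision="round_trip")
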
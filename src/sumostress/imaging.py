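"""Fluorescence inclusion quantification and colocalization.

Fixed-cell fluorescence fields (GFP-tagged Cyc8/Tup1, optionally an
mCherry-tagged marker in a second channel) are scored for bright puncta
("inclusions") within labeled cell masks:

* per cell, a multiscale Laplacian-of-Gaussian detector finds candidate
  spots; a spot counts only if its peak rises ``min_prominence`` robust
  scale units (MAD-based) above the cell's local background, making the
  call invariant to detector gain,
* a field's readout is the fraction of cells with >=1 inclusion; a
  condition is summarized as mean +/- SD of that fraction across fields
  (six fields of >=40 cells each in the reference protocol),
* conditions are compared with a two-tailed heteroscedastic (Welch)
  t-test on the per-field fractions,
* nuclear/cytoplasmic partitioning is the ratio of mean intensities over
  the nuclear mask and the cell-minus-nucleus pixels,
* two-channel colocalization uses the Manders overlap coefficient
  r = Sum(R*G) / sqrt(Sum(R^2) * Sum(G^2)) over masked pixels, and line
  profiles sample intensities along a segment by bilinear interpolation.

Pixel convention: (row, col), 0-based, origin top-left; masks are integer
label images with 0 = background, and nuclear labels match cell labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
import tifffile
from skimage.feature import blob_log, peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

DEFAULT_MIN_PROMINENCE = 5.0
DEFAULT_MIN_SIGMA = 1.0
DEFAULT_MAX_SIGMA = 4.0
DEFAULT_MIN_FIELDS = 6
DEFAULT_MIN_CELLS_PER_FIELD = 40

#: 1.4826 * MAD estimates the standard deviation of Gaussian noise.
_MAD_TO_SD = 1.4826


@dataclass
class ImageField:
    """One or two registered channels plus labeled cell/nuclear masks."""

    channels: list[np.ndarray]
    cell_mask: np.ndarray
    nuclear_mask: np.ndarray
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 2:
            raise ValueError("an ImageField carries 1 or 2 channels")
        shape = self.channels[0].shape
        for ch in self.channels:
            if ch.shape != shape or (np.asarray(ch) < 0).any():
                raise ValueError("channels must share shape and be non-negative")
        if self.cell_mask.shape != shape or self.nuclear_mask.shape != shape:
            raise ValueError("masks must share the channel shape")
        cell_labels = set(np.unique(self.cell_mask)) - {0}
        nuc_labels = set(np.unique(self.nuclear_mask)) - {0}
        if not nuc_labels <= cell_labels:
            raise ValueError("nuclear labels must match cell labels")
        inside = self.nuclear_mask > 0
        if inside.any() and not np.array_equal(
            self.nuclear_mask[inside], self.cell_mask[inside]
        ):
            raise ValueError("nuclear pixels must lie inside their own cell")

    @property
    def cell_labels(self) -> np.ndarray:
        labels = np.unique(self.cell_mask)
        return labels[labels > 0]


# ---------------------------------------------------------------------------
# segmentation


def segment_cells(
    image: np.ndarray, expected_cell_area_range: tuple[float, float]
) -> np.ndarray:
    """Label cells in a single-channel image.

    Otsu threshold, hole filling and a distance-transform watershed split
    touching cells; objects outside the expected area range are
    discarded.  Labels are assigned deterministically in raster order of
    the object centroids.  A blank image yields an empty (all-zero) mask
    with a warning rather than an exception.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_cells expects a single-channel 2-D image")
    area_min, area_max = expected_cell_area_range
    if image.max() == image.min():
        warnings.warn("segment_cells: blank image, no objects found")
        return np.zeros(image.shape, dtype=np.int32)

    fg = image > threshold_otsu(image)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        warnings.warn("segment_cells: nothing above threshold")
        return np.zeros(image.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(fg)
    min_dist = max(3, int(round(np.sqrt(area_min / np.pi))))
    coords = peak_local_max(distance, min_distance=min_dist, labels=fg)
    markers = np.zeros(image.shape, dtype=np.int32)
    for k, (r, c) in enumerate(coords, start=1):
        markers[r, c] = k
    labels = watershed(-distance, markers, mask=fg)

    # filter by area, then relabel by centroid raster order
    out = np.zeros(image.shape, dtype=np.int32)
    objects = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        if not area_min <= area <= area_max:
            continue
        cy, cx = ndi.center_of_mass(mask)
        objects.append((round(cy), round(cx), mask))
    if not objects:
        warnings.warn("segment_cells: no objects within the area range")
        return out
    for new_lab, (_, _, mask) in enumerate(sorted(objects, key=lambda o: (o[0], o[1])), start=1):
        out[mask] = new_lab
    return out


# ---------------------------------------------------------------------------
# inclusion detection


def _cell_background(crop, cellmask, nucmask):
    """Per-compartment median background within one cell.

    Nuclei carry a higher baseline than the cytoplasm (nuclear
    enrichment), so flattening against a single median would let every
    nucleus masquerade as one giant spot; each compartment is flattened
    against its own median instead.
    """
    bg = np.zeros_like(crop)
    cyto = cellmask & ~nucmask
    if cyto.any():
        bg[cyto] = np.median(crop[cyto])
    if nucmask.any():
        bg[nucmask] = np.median(crop[nucmask])
    return bg


def detect_inclusions(
    field: ImageField,
    channel: int = 0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    max_sigma: float = DEFAULT_MAX_SIGMA,
) -> dict[int, list[tuple[float, float, float, float]]]:
    """Per-cell multiscale LoG spot detection with a robust prominence gate.

    For each cell the image is flattened against the per-compartment
    median background and divided by the cell's robust intensity scale
    (1.4826 x MAD of the residual, falling back to the SD when the MAD is
    zero).  LoG blobs on that normalized crop whose peak value is
    >= ``min_prominence`` are kept.  Both steps are invariant to a global
    gain change.  Returns label -> list of (row, col, sigma, peak).
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be positive")
    img = np.asarray(field.channels[channel], dtype=float)
    out: dict[int, list[tuple[float, float, float, float]]] = {}
    pad = int(np.ceil(3 * max_sigma))
    slices = ndi.find_objects(field.cell_mask)
    for lab in field.cell_labels:
        sl = slices[lab - 1]
        rows = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, img.shape[0]))
        cols = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, img.shape[1]))
        crop = img[rows, cols]
        cellmask = field.cell_mask[rows, cols] == lab
        nucmask = field.nuclear_mask[rows, cols] == lab

        residual = crop - _cell_background(crop, cellmask, nucmask)
        vals = residual[cellmask]
        mad = np.median(np.abs(vals - np.median(vals)))
        scale = _MAD_TO_SD * mad
        if scale == 0:
            scale = vals.std()
        out[int(lab)] = []
        if scale == 0:  # perfectly flat cell: nothing to detect
            continue
        z = np.where(cellmask, residual / scale, 0.0)
        blobs = blob_log(
            np.clip(z, 0, None),
            min_sigma=min_sigma,
            max_sigma=max_sigma,
            num_sigma=4,
            threshold=0.2,
        )
        for r, c, sigma in blobs:
            ri, ci = int(round(r)), int(round(c))
            if not cellmask[ri, ci]:
                continue
            peak = z[ri, ci]
            if peak >= min_prominence:
                out[int(lab)].append(
                    (float(r + rows.start), float(c + cols.start), float(sigma), float(peak))
                )
    return out


@dataclass(frozen=True)
class InclusionSummary:
    """Per-field inclusion fractions and their across-field mean +/- SD.

    The mean and SD are computed across fields (the field is the
    statistical unit), never over pooled cells.
    """

    per_field: pd.DataFrame
    mean_fraction: float
    sd_fraction: float
    n_fields: int
    total_cells: int
    underpowered: bool
    condition: str | None = None
    timepoint: float | None = None


def summarize_inclusion_fractions(
    fields: list[ImageField],
    min_fields: int = DEFAULT_MIN_FIELDS,
    min_cells_per_field: int = DEFAULT_MIN_CELLS_PER_FIELD,
    channel: int = 0,
    detections: list[dict] | None = None,
    **detector_kwargs,
) -> InclusionSummary:
    """Fraction of cells with >=1 inclusion, averaged across fields.

    ``detections`` may carry precomputed per-cell spot lists (one dict per
    field); otherwise :func:`detect_inclusions` runs with
    ``detector_kwargs``.  Fields with zero cells are excluded with a
    warning.  Inputs below ``min_fields`` fields or with any field below
    ``min_cells_per_field`` cells are still summarized but flagged
    ``underpowered``.
    """
    if not fields:
        raise ValueError("no fields given")
    rows = []
    for k, f in enumerate(fields):
        labels = f.cell_labels
        if labels.size == 0:
            logger.warning("field %d has zero cells; excluded", k)
            continue
        spots = (
            detections[k]
            if detections is not None
            else detect_inclusions(f, channel=channel, **detector_kwargs)
        )
        n_pos = sum(1 for lab in labels if spots.get(int(lab)))
        rows.append(
            {
                "field_id": f.metadata.get("field_id", k),
                "n_cells": int(labels.size),
                "n_cells_with_inclusion": int(n_pos),
                "fraction": n_pos / labels.size,
            }
        )
    if not rows:
        raise ValueError("all fields had zero cells")
    per_field = pd.DataFrame(rows)
    fractions = per_field["fraction"].to_numpy()
    underpowered = len(per_field) < min_fields or bool(
        (per_field["n_cells"] < min_cells_per_field).any()
    )
    first_meta = fields[0].metadata
    return InclusionSummary(
        per_field=per_field,
        mean_fraction=float(fractions.mean()),
        sd_fraction=float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0,
        n_fields=len(per_field),
        total_cells=int(per_field["n_cells"].sum()),
        underpowered=underpowered,
        condition=first_meta.get("condition"),
        timepoint=first_meta.get("timepoint"),
    )


def compare_conditions(fractions_a, fractions_b) -> float:
    """Two-tailed Welch (heteroscedastic) t-test on per-field fractions."""
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 fields per condition")
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both groups constant
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# intensity readouts


def nc_ratio(field: ImageField, channel: int = 0) -> pd.DataFrame:
    """Per-cell nuclear and cytoplasmic mean intensities and their ratio.

    The cytoplasm is the cell mask minus the nuclear mask.  A zero
    cytoplasmic mean (or a cell without cytoplasmic/nuclear pixels)
    leaves the ratio NaN, flagged in the ``defined`` column.
    """
    img = np.asarray(field.channels[channel], dtype=float)
    labels = field.cell_labels
    cyto_mask = np.where(field.nuclear_mask > 0, 0, field.cell_mask)
    rows = []
    for lab in labels:
        nuc = img[field.nuclear_mask == lab]
        cyt = img[cyto_mask == lab]
        nuc_mean = float(nuc.mean()) if nuc.size else np.nan
        cyt_mean = float(cyt.mean()) if cyt.size else np.nan
        if cyt.size and cyt_mean > 0 and nuc.size:
            ratio = nuc_mean / cyt_mean
        else:
            ratio = np.nan
        rows.append(
            {
                "label": int(lab),
                "nuclear_mean": nuc_mean,
                "cytoplasmic_mean": cyt_mean,
                "ratio": ratio,
                "defined": np.isfinite(ratio),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def manders_overlap(ch1, ch2, mask) -> tuple[float, int]:
    """Manders overlap coefficient over masked pixels.

    r = Sum(R*G) / sqrt(Sum(R^2) * Sum(G^2)), in [0, 1] for non-negative
    channels; invariant to scaling either channel by a positive constant.
    Returns (r, number of masked pixels).
    """
    r = np.asarray(ch1, dtype=float)
    g = np.asarray(ch2, dtype=float)
    m = np.asarray(mask).astype(bool)
    if r.shape != g.shape or r.shape != m.shape:
        raise ValueError("channels and mask must share a shape")
    if not m.any():
        raise ValueError("mask is empty")
    rv, gv = r[m], g[m]
    if (rv < 0).any() or (gv < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = np.sqrt((rv * rv).sum() * (gv * gv).sum())
    if denom == 0:
        raise ValueError("overlap undefined: a channel is all-zero within the mask")
    return float((rv * gv).sum() / denom), int(m.sum())


def line_profile(image, p0, p1, n_samples: int) -> np.ndarray:
    """Bilinear intensity profile along the segment p0 -> p1 (inclusive).

    Endpoints are (row, col) and must lie inside the image; ``n_samples``
    evenly spaced points are sampled.
    """
    img = np.asarray(image, dtype=float)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    for p in (p0, p1):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {p} outside the image")
    rows = np.linspace(p0[0], p1[0], n_samples)
    cols = np.linspace(p0[1], p1[1], n_samples)
    return ndi.map_coordinates(img, [rows, cols], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# field I/O (TIFF images, 16-bit label masks, JSON sidecar)


def write_field(field_obj: ImageField, directory, name: str) -> None:
    """Write channels, masks and metadata sidecar for one field."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stack = np.stack(field_obj.channels).astype(np.float32)
    tifffile.imwrite(d / f"{name}.tif", stack)
    tifffile.imwrite(d / f"{name}_cellmask.tif", field_obj.cell_mask.astype(np.uint16))
    tifffile.imwrite(d / f"{name}_nucmask.tif", field_obj.nuclear_mask.astype(np.uint16))
    with open(d / f"{name}_meta.json", "w") as fh:
        json.dump(field_obj.metadata, fh, indent=2, sort_keys=True)


def read_field(directory, name: str) -> ImageField:
    """Inverse of :func:`write_field` (ground truth is not round-tripped)."""
    from pathlib import Path

    d = Path(directory)
    stack = tifffile.imread(d / f"{name}.tif")
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    meta_path = d / f"{name}_meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return ImageField(
        channels=[np.asarray(c, dtype=float) for c in stack],
        cell_mask=tifffile.imread(d / f"{name}_cellmask.tif").astype(np.int32),
        nuclear_mask=tifffile.imread(d / f"{name}_nucmask.tif").astype(np.int32),
        metadata=meta,
    )
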
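"""Fixed-threshold segmentation and overlap quantification for
multi-channel fluorescence fields.

The pipeline mirrors a batch immunocytochemistry workflow: every channel
of a field is resized (optional), min–max normalized, contrast-adjusted by
gamma correction (default γ = 0.8) and clipped to 8-bit; a binary mask is
then cut at a fixed global per-channel threshold ("suprathreshold" =
strictly greater than, configurable). From the masks the pipeline reports

* percent area positive per channel (fraction of field pixels, ×100);
* the "merged" denominator mask — a provided composite mask, or the
  pixelwise union (bitwise OR) of all channel masks when absent;
* pairwise overlap (bitwise AND) percentages, relative to the merged area
  and relative to the target mask's own area;
* a membership heatmap counting per-pixel channel co-occurrence;
* live/dead ratios from green/red channel percent areas;
* technical-replicate (field-level) aggregation to well means ± SD.

Segmentation parameters are deliberately immutable per batch: thresholds
are required configuration with no default, because they are the free
parameter that decides every downstream number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from skimage.transform import rescale

__all__ = [
    "SegmentationParams",
    "MultiChannelField",
    "BinaryMask",
    "AreaReport",
    "MembershipMap",
    "LiveDeadResult",
    "WellSummary",
    "preprocess",
    "segment",
    "percent_area",
    "merged_area",
    "overlap_metrics",
    "membership_map",
    "membership_to_rgb",
    "quantify_field",
    "live_dead_ratio",
    "aggregate",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Batch-constant preprocessing and segmentation parameters.

    ``thresholds`` maps channel label → 8-bit intensity cut applied after
    preprocessing. There is no default threshold: per-channel cuts must be
    stated explicitly and are held constant across all fields of a batch.
    ``strict`` selects strictly-greater-than thresholding (the default);
    set False for >=.
    """

    thresholds: dict
    resize_factor: float = 1.0
    gamma: float = 0.8
    strict: bool = True

    def __post_init__(self) -> None:
        if self.resize_factor <= 0:
            raise ValueError("resize_factor must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for label, thr in self.thresholds.items():
            if not 0 <= thr <= 255:
                raise ValueError(f"threshold for {label!r} outside [0, 255]")


@dataclass
class MultiChannelField:
    """Co-registered single-channel rasters for one microscope field."""

    channels: dict
    merged_mask: np.ndarray | None = None
    field_id: str = ""
    well_id: str = ""
    dose_mM: float = 0.0
    status: str = ""

    def __post_init__(self) -> None:
        shapes = {np.asarray(r).shape for r in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel rasters disagree in shape: {shapes}")
        if self.merged_mask is not None and \
                np.asarray(self.merged_mask).shape not in shapes:
            raise ValueError("merged mask shape does not match channels")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


@dataclass
class BinaryMask:
    pixels: np.ndarray
    source_channel: str = ""
    threshold_used: float = np.nan

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class MembershipMap:
    """Per-pixel count of channel memberships with a display legend."""

    counts: np.ndarray
    legend: dict


@dataclass
class LiveDeadResult:
    green_pct: float
    red_pct: float
    ratio: float          # NaN when the red (dead) area is zero
    defined: bool


def preprocess(raster: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Resize, min–max normalize, gamma-correct and clip to 8-bit.

    The mapping is monotone in the input intensities; a constant image
    (including all-zero) maps to all zeros rather than dividing by a zero
    range. Resize (bilinear) happens before normalization so the intensity
    statistics reflect the working resolution.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.size == 0:
        raise ValueError("empty raster")
    if params.resize_factor != 1.0:
        arr = rescale(arr, params.resize_factor, order=1,
                      preserve_range=True, anti_aliasing=False)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    norm = (arr - lo) / (hi - lo)
    out = 255.0 * np.power(norm, params.gamma)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def segment(raster8: np.ndarray, threshold: float, *, strict: bool = True,
            label: str = "") -> BinaryMask:
    """Cut a binary mask at a fixed global threshold.

    A pixel is positive iff its intensity is strictly above the threshold
    (``strict=False`` switches to >=). Re-segmenting a mask rendered as
    {0, 255} at any threshold in [0, 254] reproduces the mask.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold outside [0, 255]")
    arr = np.asarray(raster8)
    pixels = arr > threshold if strict else arr >= threshold
    return BinaryMask(pixels, label, threshold)


def percent_area(mask: BinaryMask) -> float:
    """Percent of field pixels that are positive in the mask."""
    px = mask.pixels
    if px.size == 0:
        raise ValueError("empty mask raster")
    return 100.0 * float(px.sum()) / px.size


def merged_area(masks: list, provided: BinaryMask | None = None) -> BinaryMask:
    """Denominator mask: the provided composite, else the pixelwise union."""
    if provided is not None:
        return provided
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.pixels.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes disagree: {shapes}")
    union = np.zeros(masks[0].pixels.shape, bool)
    for m in masks:
        union |= m.pixels
    return BinaryMask(union, "merged")


def overlap_metrics(target: BinaryMask, other: BinaryMask,
                    merged: BinaryMask) -> dict:
    """Overlap (AND) percentages against the merged and the target area.

    Returns ``{"overlap_pct_merged": ..., "overlap_pct_target": ...,
    "and_area_px": ...}``; a zero denominator makes the corresponding
    percentage NaN (undefined), never 0.
    """
    for m in (other, merged):
        if m.pixels.shape != target.pixels.shape:
            raise ValueError("mask shapes disagree")
    and_px = int((target.pixels & other.pixels).sum())
    merged_px = merged.area_px
    target_px = target.area_px
    return {
        "overlap_pct_merged": 100.0 * and_px / merged_px if merged_px else np.nan,
        "overlap_pct_target": 100.0 * and_px / target_px if target_px else np.nan,
        "and_area_px": and_px,
    }


_MEMBERSHIP_COLORS = {2: (255, 255, 0), 3: (255, 128, 0), 4: (255, 0, 0)}


def membership_map(masks: list) -> MembershipMap:
    """Sum per-pixel mask memberships for 2–4 channels.

    The legend color-codes pixels belonging to exactly two, three or four
    channels; the scheme does not extend past four.
    """
    if not 2 <= len(masks) <= 4:
        raise ValueError("membership map defined for 2 to 4 masks")
    shapes = {m.pixels.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes disagree: {shapes}")
    counts = np.zeros(masks[0].pixels.shape, np.uint8)
    for m in masks:
        counts += m.pixels.astype(np.uint8)
    legend = {k: _MEMBERSHIP_COLORS[k]
              for k in (2, 3, 4) if k <= len(masks)}
    return MembershipMap(counts, legend)


def membership_to_rgb(mm: MembershipMap) -> np.ndarray:
    """Render a membership map to an RGB uint8 image using its legend."""
    rgb = np.zeros(mm.counts.shape + (3,), np.uint8)
    for count, color in mm.legend.items():
        rgb[mm.counts == count] = color
    return rgb


@dataclass
class AreaReport:
    """Percent-area and overlap statistics for one field.

    Per-channel totals are reported against the whole field and against
    the merged denominator; ordered channel pairs carry the two overlap
    percentages. Undefined metrics (zero denominators) are NaN.
    """

    field_id: str
    well_id: str
    merged_area_px: int
    total_area_pct_field: dict
    total_area_pct_merged: dict
    overlap_pct_merged: dict
    overlap_pct_target: dict

    def metrics(self) -> dict:
        """Flatten to metric-name → value (keys stable across fields)."""
        out = {"merged_area_px": float(self.merged_area_px)}
        for ch, v in self.total_area_pct_field.items():
            out[f"area_pct_field/{ch}"] = v
        for ch, v in self.total_area_pct_merged.items():
            out[f"area_pct_merged/{ch}"] = v
        for (t, o), v in self.overlap_pct_merged.items():
            out[f"overlap_pct_merged/{t}&{o}"] = v
        for (t, o), v in self.overlap_pct_target.items():
            out[f"overlap_pct_target/{t}&{o}"] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-metric frame (the CSV export shape)."""
        rows = [{"field_id": self.field_id, "well_id": self.well_id,
                 "metric": k, "value": v} for k, v in self.metrics().items()]
        return pd.DataFrame(rows)


def quantify_field(fld: MultiChannelField,
                   params: SegmentationParams) -> AreaReport:
    """Run the full per-field pipeline: preprocess, segment, measure.

    Every channel present in the field must have a threshold in
    ``params.thresholds``. The merged denominator is the field's provided
    merged mask when present (resized nearest-neighbor if needed),
    otherwise the union of the channel masks. Overlap metrics are emitted
    for every ordered channel pair.
    """
    missing = [c for c in fld.channels if c not in params.thresholds]
    if missing:
        raise ValueError(f"no threshold configured for channel(s): {missing}")
    masks = {}
    for label, raster in fld.channels.items():
        proc = preprocess(raster, params)
        masks[label] = segment(proc, params.thresholds[label],
                               strict=params.strict, label=label)
    provided = None
    if fld.merged_mask is not None:
        mm = np.asarray(fld.merged_mask, bool)
        target_shape = next(iter(masks.values())).pixels.shape
        if mm.shape != target_shape:
            mm = rescale(mm.astype(float), params.resize_factor, order=0,
                         preserve_range=True).astype(bool)
        provided = BinaryMask(mm, "merged(provided)")
    merged = merged_area(list(masks.values()), provided)
    merged_px = merged.area_px

    area_field = {c: percent_area(m) for c, m in masks.items()}
    area_merged = {
        c: (100.0 * m.area_px / merged_px if merged_px else np.nan)
        for c, m in masks.items()}
    ov_merged, ov_target = {}, {}
    for t, o in permutations(masks, 2):
        res = overlap_metrics(masks[t], masks[o], merged)
        ov_merged[(t, o)] = res["overlap_pct_merged"]
        ov_target[(t, o)] = res["overlap_pct_target"]
    return AreaReport(fld.field_id, fld.well_id, merged_px,
                      area_field, area_merged, ov_merged, ov_target)


def live_dead_ratio(green: np.ndarray, red: np.ndarray,
                    params: SegmentationParams) -> LiveDeadResult:
    """Ratio of live (green) to dead (red) percent areas.

    Thresholds are looked up under the ``"green"`` and ``"red"`` labels.
    A zero dead area flags the ratio undefined (NaN) rather than raising.
    """
    if np.asarray(green).shape != np.asarray(red).shape:
        raise ValueError("green and red rasters disagree in shape")
    g_mask = segment(preprocess(green, params), params.thresholds["green"],
                     strict=params.strict, label="green")
    r_mask = segment(preprocess(red, params), params.thresholds["red"],
                     strict=params.strict, label="red")
    g_pct, r_pct = percent_area(g_mask), percent_area(r_mask)
    if r_pct == 0.0:
        return LiveDeadResult(g_pct, r_pct, np.nan, False)
    return LiveDeadResult(g_pct, r_pct, g_pct / r_pct, True)


@dataclass
class WellSummary:
    """Mean ± SD of each metric over a well's technical-replicate fields."""

    well_id: str
    n_fields: int
    table: pd.DataFrame    # columns: metric, mean, sd, n


def aggregate(field_reports: list) -> WellSummary:
    """Average technical replicates (fields) into one well summary.

    Means and sample standard deviations are computed per metric;
    undefined (NaN) metrics are excluded pairwise, with the effective n
    recorded per metric. SD is NaN when fewer than two defined values
    remain.
    """
    if not field_reports:
        raise ValueError("need at least one field report")
    wells = {r.well_id for r in field_reports}
    if len(wells) > 1:
        raise ValueError(f"reports span multiple wells: {wells}")
    frame = pd.DataFrame([r.metrics() for r in field_reports])
    rows = []
    for metric in frame.columns:
        vals = frame[metric].dropna()
        n = len(vals)
        rows.append({
            "metric": metric,
            "mean": float(vals.mean()) if n else np.nan,
            "sd": float(vals.std(ddof=1)) if n >= 2 else np.nan,
            "n": n,
        })
    return WellSummary(wells.pop(), len(field_reports), pd.DataFrame(rows))
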
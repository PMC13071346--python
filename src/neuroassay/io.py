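"""Reading and writing the pipeline's on-disk formats.

Fields travel as one single-channel 8/16-bit grayscale PNG/TIFF per
channel (never implicitly decomposed RGB composites) plus an optional
JSON sidecar carrying the generator's ground truth; Ct tables and reports
are tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .imaging import AreaReport, MembershipMap, MultiChannelField, \
    WellSummary, membership_to_rgb
from .qpcr import CT_COLUMNS
from .synthetic import FieldGroundTruth

__all__ = [
    "write_field", "read_field", "write_ground_truth", "read_ground_truth",
    "write_ct_table", "read_ct_table", "write_reports", "write_well_summary",
    "write_membership_png",
]


def write_field(fld: MultiChannelField, directory, prefix: str = "field") -> dict:
    """Write one grayscale PNG per channel; returns label → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, raster in fld.channels.items():
        path = directory / f"{prefix}_{label}.png"
        iio.imwrite(path, np.asarray(raster, np.uint8))
        paths[label] = path
    if fld.merged_mask is not None:
        path = directory / f"{prefix}_merged.png"
        iio.imwrite(path, (np.asarray(fld.merged_mask, bool) * 255).astype(np.uint8))
        paths["__merged__"] = path
    return paths


def read_field(paths: dict, **meta) -> MultiChannelField:
    """Assemble a field from label → single-channel image path."""
    channels, merged = {}, None
    for label, path in paths.items():
        img = np.asarray(iio.imread(path))
        if img.ndim != 2:
            raise ValueError(
                f"{path}: expected a single-channel image, got shape {img.shape}; "
                "RGB composites are not decomposed implicitly")
        if label == "__merged__":
            merged = img > 0
        else:
            channels[label] = img
    return MultiChannelField(channels, merged_mask=merged, **meta)


def write_ground_truth(truth: FieldGroundTruth, path) -> None:
    """JSON sidecar with the generator's true fractions (masks omitted)."""
    payload = {
        "seed": truth.seed,
        "true_area_fraction": dict(truth.true_area_fraction),
        "true_overlap_fraction": {f"{a}&{b}": v for (a, b), v
                                  in truth.true_overlap_fraction.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["true_overlap_fraction"] = {
        tuple(k.split("&")): v
        for k, v in payload["true_overlap_fraction"].items()}
    return payload


def write_ct_table(table: pd.DataFrame, path) -> None:
    table[list(CT_COLUMNS)].to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct CSV lacks columns: {missing}")
    return table


def write_reports(reports: list, path) -> None:
    """Tidy CSV of AreaReports: one row per field × metric."""
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        path, index=False)


def write_well_summary(summary: WellSummary, path) -> None:
    out = summary.table.assign(well_id=summary.well_id,
                               n_fields=summary.n_fields)
    out.to_csv(path, index=False)


def write_membership_png(mm: MembershipMap, path, legend_path=None) -> None:
    """Membership heatmap as RGB PNG plus an optional CSV legend."""
    iio.imwrite(path, membership_to_rgb(mm))
    if legend_path is not None:
        pd.DataFrame(
            [{"n_channels": k, "r": r, "g": g, "b": b}
             for k, (r, g, b) in mm.legend.items()]
        ).to_csv(legend_path, index=False)
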
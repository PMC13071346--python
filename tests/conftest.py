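import numpy as np
import pytest

from neuroassay import ChannelSpec, SegmentationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_specs():
    return (ChannelSpec("a"), ChannelSpec("b"))


@pytest.fixture
def zero_threshold_params():
    """Thresholds just above background: exact mask recovery on clean fields."""
    return SegmentationParams(thresholds={"a": 0, "b": 0})


def naive_mask_metrics(masks: dict, merged: np.ndarray) -> dict:
    """Pure-Python pixel-loop oracle for every mask statistic the imaging
    pipeline reports. Deliberately written as explicit double loops over
    pixels, independent of any vectorized code path."""
    h = len(merged)
    w = len(merged[0])
    total = h * w
    merged_count = 0
    for i in range(h):
        for j in range(w):
            if merged[i][j]:
                merged_count += 1
    out = {"merged_area_px": merged_count}
    counts = {}
    for label, m in masks.items():
        c = 0
        for i in range(h):
            for j in range(w):
                if m[i][j]:
                    c += 1
        counts[label] = c
        out[f"area_pct_field/{label}"] = 100.0 * float(c) / total
        out[f"area_pct_merged/{label}"] = (
            100.0 * c / merged_count if merged_count else None)
    labels = list(masks)
    for t in labels:
        for o in labels:
            if t == o:
                continue
            a = 0
            for i in range(h):
                for j in range(w):
                    if masks[t][i][j] and masks[o][i][j]:
                        a += 1
            out[f"and_px/{t}&{o}"] = a
            out[f"overlap_pct_merged/{t}&{o}"] = (
                100.0 * a / merged_count if merged_count else None)
            out[f"overlap_pct_target/{t}&{o}"] = (
                100.0 * a / counts[t] if counts[t] else None)
    return out
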
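"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the data structures the quantification stages
consume, with known truth attached so recovery is testable end to end:

* :func:`generate_field` — a multi-channel fluorescence field of
  blob-like cells with configurable per-channel intensity, blur and noise
  and controlled pairwise colocalization. Cells are Gaussian-profile
  discs placed on a jittered grid so that discs never overlap within a
  channel; colocalization is produced by co-placing a controlled subset
  of blob centers across channels, which makes the true overlap fraction
  a simple count ratio.
* :func:`generate_live_dead` — a green/red (live/dead) image pair whose
  channel masks are disjoint and whose cell-count split follows the
  requested live fraction.
* :func:`generate_ct_table` — a qPCR Ct table with specified true fold
  changes, i.i.d. replicate noise, and housekeeping candidates of
  configurable group-wise stability.

All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence` substreams (one per channel / gene),
so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import MultiChannelField

__all__ = [
    "ChannelSpec",
    "FieldGroundTruth",
    "CtGroundTruth",
    "InfeasibleColocalizationError",
    "generate_field",
    "generate_live_dead",
    "generate_ct_table",
    "STUDY_GROUPS",
]

#: The factorial design the study-mimicking fixtures follow:
#: differentiation status x ethanol dose (mM).
STUDY_GROUPS = (
    ("UnDiff", 0.0), ("UnDiff", 7.0), ("UnDiff", 35.0),
    ("Diff", 0.0), ("Diff", 7.0), ("Diff", 35.0),
)


class InfeasibleColocalizationError(ValueError):
    """Requested pairwise overlap fractions cannot be realized."""


@dataclass(frozen=True)
class ChannelSpec:
    """Rendering recipe for one fluorescence channel.

    ``intensity`` is the blob peak on the 8-bit scale; ``radius`` the disc
    radius in pixels; ``blur_sigma`` an optional Gaussian smoothing of the
    rendered image; ``noise_sd`` additive Gaussian read noise. The radial
    intensity profile is Gaussian with scale ``profile_sigma`` (default
    2×radius, leaving ~88% of peak at the disc edge), cut hard at the mask
    boundary — like a well-stained soma, the object interior stays far
    above background so thresholds between the two levels recover the
    mask: exactly at zero blur/noise, and robustly under moderate noise.
    """

    label: str
    intensity: float = 200.0
    radius: float = 6.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    profile_sigma: float | None = None


@dataclass
class FieldGroundTruth:
    """True masks and fractions behind one generated field.

    ``true_overlap_fraction`` is keyed by ordered channel pair (a, b) and
    holds |A∩B| / |A| — the fraction of the first channel's area shared
    with the second (the target-referenced overlap the pipeline reports).
    Absolute AND areas never exceed either channel's own area.
    """

    true_masks: dict
    true_area_fraction: dict
    true_overlap_fraction: dict
    seed: int


@dataclass
class CtGroundTruth:
    """True expression structure behind a generated Ct table.

    ``true_fold_change`` maps (gene, (status, dose)) → the fold change the
    ΔΔCt pipeline should recover under the within-status convention;
    calibrator groups (dose 0) are fixed at 1 and missing entries default
    to 1. ``housekeeping_bias`` maps (hk_gene, (status, dose)) → a Ct
    shift modelling group-wise reference-gene instability. ``gene_sd``
    overrides ``replicate_sd`` per gene.
    """

    true_fold_change: dict
    replicate_sd: float = 0.2
    housekeeping_bias: dict = field(default_factory=dict)
    housekeeping_genes: tuple = ("B-ACTIN", "PGK1", "GAPDH")
    gene_sd: dict = field(default_factory=dict)
    groups: tuple = STUDY_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")
        for (gene, group), fc in self.true_fold_change.items():
            if fc <= 0:
                raise ValueError(f"fold change for {(gene, group)} must be positive")
            if group[1] == 0 and fc != 1:
                raise ValueError(
                    f"calibrator (dose 0) fold change for {gene!r} must be 1")

    def fold_change(self, gene: str, group: tuple) -> float:
        return self.true_fold_change.get((gene, group), 1.0)

    @property
    def target_genes(self) -> tuple:
        return tuple(sorted({g for g, _ in self.true_fold_change}))


def _grid_centers(shape: tuple, radius: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Jittered-grid centers guaranteeing discs never touch or leave the
    frame, in a deterministic shuffled order."""
    r = math.ceil(radius)
    pitch = 2 * r + 3
    jitter = 1.0                       # pitch - 2*jitter >= 2r + 1
    ys = np.arange(r + 2, shape[0] - r - 1, pitch)
    xs = np.arange(r + 2, shape[1] - r - 1, pitch)
    grid = np.array([(y, x) for y in ys for x in xs], float)
    if len(grid):
        grid += rng.uniform(-jitter, jitter, grid.shape)
        grid = grid[rng.permutation(len(grid))]
    return grid


def _render_channel(shape: tuple, centers: np.ndarray, spec: ChannelSpec,
                    rng: np.random.Generator) -> tuple:
    """Rasterize Gaussian-profile discs; return (uint8 image, bool mask)."""
    img = np.zeros(shape, float)
    mask = np.zeros(shape, bool)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    sigma_p = spec.profile_sigma or 2.0 * spec.radius
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= spec.radius ** 2
        mask |= inside
        profile = spec.intensity * np.exp(-d2 / (2.0 * sigma_p ** 2))
        img = np.where(inside, np.maximum(img, profile), img)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def generate_field(n_cells: int, shape: tuple = (256, 256),
                   channels: tuple = (ChannelSpec("a"), ChannelSpec("b")),
                   coloc: dict | None = None, seed: int = 0,
                   ) -> tuple:
    """Generate one multi-channel field with known masks and overlaps.

    Every channel receives ``n_cells`` discs. For each ordered pair
    (a, b) in ``coloc`` with requested fraction f, round(f * n_cells)
    centers are shared between the two channels; remaining cells get
    exclusive, non-overlapping positions. The realized overlap fraction
    |A∩B|/|A| therefore equals the requested one up to center rounding
    and rasterization.

    Returns ``(MultiChannelField, FieldGroundTruth)``. Raises
    :class:`InfeasibleColocalizationError` when a pair fraction is
    outside [0, 1] or a channel's shared allocations exceed its cells,
    and ``ValueError`` when the frame cannot hold the required number of
    non-overlapping cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError("field shape must be at least 64x64")
    labels = [c.label for c in channels]
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    coloc = dict(coloc or {})
    for pair, f in coloc.items():
        if pair[0] not in labels or pair[1] not in labels:
            raise ValueError(f"coloc pair {pair} names unknown channel")
        if not 0.0 <= f <= 1.0:
            raise InfeasibleColocalizationError(
                f"overlap fraction {f} for pair {pair} outside [0, 1]")

    # Allocate shared center slots per requested pair, then exclusive ones.
    shared_counts = {pair: round(f * n_cells) for pair, f in coloc.items()}
    used = {lab: 0 for lab in labels}
    for (a, b), s in shared_counts.items():
        used[a] += s
        used[b] += s
    for lab, u in used.items():
        if u > n_cells:
            raise InfeasibleColocalizationError(
                f"channel {lab!r} needs {u} shared cells but has only "
                f"{n_cells}; requested overlaps exceed its achievable area")

    n_slots = sum(shared_counts.values()) + sum(n_cells - u for u in used.values())
    ss = np.random.SeedSequence(seed)
    place_ss, *chan_ss = ss.spawn(1 + len(channels))
    place_rng = np.random.default_rng(place_ss)
    grid = _grid_centers(shape, max(c.radius for c in channels), place_rng)
    if n_slots > len(grid):
        raise ValueError(
            f"cannot place {n_slots} non-overlapping cells of this radius "
            f"in a {shape} field; enlarge the field or shrink the cells")

    cursor = 0
    centers = {lab: [] for lab in labels}
    for (a, b), s in shared_counts.items():
        block = grid[cursor:cursor + s]
        cursor += s
        centers[a].extend(block)
        centers[b].extend(block)
    for lab in labels:
        extra = n_cells - used[lab]
        centers[lab].extend(grid[cursor:cursor + extra])
        cursor += extra

    rasters, masks = {}, {}
    for spec, sub in zip(channels, chan_ss):
        rng = np.random.default_rng(sub)
        rasters[spec.label], masks[spec.label] = _render_channel(
            shape, np.asarray(centers[spec.label]), spec, rng)

    npix = shape[0] * shape[1]
    area = {lab: masks[lab].sum() / npix for lab in labels}
    overlap = {}
    for (a, b) in coloc:
        a_px = masks[a].sum()
        overlap[(a, b)] = float((masks[a] & masks[b]).sum() / a_px) if a_px else 0.0
    truth = FieldGroundTruth(masks, area, overlap, seed)
    fld = MultiChannelField(rasters, field_id=f"synthetic-{seed}")
    return fld, truth


def generate_live_dead(live_fraction: float, n_cells: int,
                       shape: tuple = (256, 256), seed: int = 0,
                       live_spec: ChannelSpec | None = None,
                       dead_spec: ChannelSpec | None = None) -> tuple:
    """Generate a green (live) / red (dead) image pair with disjoint masks.

    ``round(live_fraction * n_cells)`` cells are rendered green and the
    remainder red, at non-overlapping positions, so connected-component
    counts recover the allocation exactly.
    """
    if not 0.0 <= live_fraction <= 1.0:
        raise ValueError("live_fraction must be in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    live_spec = live_spec or ChannelSpec("green")
    dead_spec = dead_spec or ChannelSpec("red")
    n_live = round(live_fraction * n_cells)
    n_dead = n_cells - n_live

    ss = np.random.SeedSequence(seed)
    place_ss, g_ss, r_ss = ss.spawn(3)
    place_rng = np.random.default_rng(place_ss)
    grid = _grid_centers(shape, max(live_spec.radius, dead_spec.radius),
                         place_rng)
    if n_cells > len(grid):
        raise ValueError(f"cannot place {n_cells} non-overlapping cells "
                         f"in a {shape} field")
    g_img, g_mask = _render_channel(shape, grid[:n_live], live_spec,
                                    np.random.default_rng(g_ss))
    r_img, r_mask = _render_channel(shape, grid[n_live:n_cells], dead_spec,
                                    np.random.default_rng(r_ss))
    npix = shape[0] * shape[1]
    truth = FieldGroundTruth(
        {"green": g_mask, "red": r_mask},
        {"green": g_mask.sum() / npix, "red": r_mask.sum() / npix},
        {("green", "red"): 0.0}, seed)
    fld = MultiChannelField({"green": g_img, "red": r_img},
                            field_id=f"livedead-{seed}")
    return fld, truth


def generate_ct_table(truth: CtGroundTruth, n_reps: int = 3,
                      base_ct: float = 20.0) -> pd.DataFrame:
    """Generate a replicate-level Ct table realizing a CtGroundTruth.

    Target-gene Ct values are ``base_ct + gene offset − log2(FC) + noise``
    and housekeeping Ct values ``base_ct + gene offset + bias + noise``,
    so the expected ΔCt of a (gene, group) against an unbiased reference
    is the calibrator's mean ΔCt minus log2 of the true fold change, and
    the ΔΔCt pipeline recovers the specified fold changes exactly at zero
    noise. Gene offsets are drawn once per table (uniform, 0–6 cycles) to
    spread genes over a realistic Ct range.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    genes = truth.target_genes + tuple(truth.housekeeping_genes)
    ss = np.random.SeedSequence(truth.seed)
    offset_ss, *gene_ss = ss.spawn(1 + len(genes))
    offsets = dict(zip(genes, np.random.default_rng(offset_ss)
                       .uniform(0.0, 6.0, len(genes))))
    rows = []
    for gene, sub in zip(genes, gene_ss):
        rng = np.random.default_rng(sub)
        sd = truth.gene_sd.get(gene, truth.replicate_sd)
        is_hk = gene in truth.housekeeping_genes
        for group in truth.groups:
            status, dose = group
            if is_hk:
                level = offsets[gene] + truth.housekeeping_bias.get(
                    (gene, group), 0.0)
            else:
                level = offsets[gene] - math.log2(truth.fold_change(gene, group))
            noise = rng.normal(0.0, sd, n_reps) if sd > 0 else np.zeros(n_reps)
            for rep in range(1, n_reps + 1):
                rows.append({"gene": gene, "group": status, "dose_mM": dose,
                             "replicate": rep,
                             "ct": base_ct + level + noise[rep - 1]})
    return pd.DataFrame(rows)
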
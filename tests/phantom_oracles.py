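"""Shared helpers for oracle-based tests.

Provides noise-free phantom designs with well-separated nuclei (centre
spacing larger than twice the maximal nuclear axis), a matched exact
analysis protocol (fixed threshold, no smoothing, no size gates), and the
brute-force 26-connected 3D component-labelling oracle the nearest-
neighbour linker is compared against.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from nucleovol import (
    FociParams,
    LinkParams,
    NoiseModel,
    PhantomDesign,
    SegmentationParams,
    link_slices,
    nuclei_label_stack,
    segment_nuclei_slice,
)
from nucleovol.config import PipelineConfig


def clean_design(seed: int, cells: int = 5, foci=(1, 4), conditions=("EV",), **kw) -> PhantomDesign:
    """Zero-noise, zero-PSF design with nuclei spaced > 2x max axis."""
    base = dict(
        conditions=list(conditions),
        wells_per_condition=1,
        fields_per_well=1,
        cells_per_field=cells,
        image_shape=(12, 160, 160),
        nuclear_radius_um=(3.0, 0.25),
        min_center_spacing_um=11.0,
        foci_per_nucleus=foci,
        noise=NoiseModel(read_sd=0.0, shot=False),
        psf_sigma_um=0.0,
        seed=seed,
    )
    base.update(kw)
    return PhantomDesign(**base)


def dapi_threshold(design: PhantomDesign) -> float:
    spec = design.channel_baselines[design.dapi_channel]
    return spec.background + 0.5 * spec.nuclear_amplitude


def exact_config(design: PhantomDesign, max_z_gap: int = 0) -> PipelineConfig:
    """Protocol under which the per-slice masks equal the thresholded stack
    exactly (no smoothing, no gates), for oracle comparisons."""
    spec = design.channel_baselines[design.dapi_channel]
    foci = None
    if design.foci_channels:
        ch = design.foci_channels[0]
        foci = FociParams(
            channel=ch,
            min_area_px2=1.0,
            max_area_px2=1e4,
            brightness_factor=2.0,
            scale_px=round(2.2 * design.focus_radius_um[0] / design.pixel_size_xy) + 1,
            smooth_sigma_px=0.0,
            min_prominence=0.25 * design.channel_baselines[ch].focus_amplitude,
        )
    return PipelineConfig(
        dapi_channel=design.dapi_channel,
        segmentation=SegmentationParams(
            smooth_sigma_px=0.0,
            threshold=f"fixed:{dapi_threshold(design)}",
            min_area_px2=1.0,
            max_area_px2=1e9,
            fill_holes=False,
        ),
        foci=foci,
        link_nuclei=LinkParams(
            max_link_dist_um=2.0, max_z_gap=max_z_gap, min_slices=1, border_policy="keep"
        ),
        link_foci=LinkParams(max_link_dist_um=1.0, max_z_gap=0, min_slices=1),
        cyto=None,
    )


def segment_stack(grid, config):
    dapi = grid.channel(config.dapi_channel)
    return [
        segment_nuclei_slice(dapi[z], config.segmentation, z=z)
        for z in range(grid.n_z)
    ]


def linked_label_stack(grid, config):
    slices = segment_stack(grid, config)
    nuclei = link_slices(slices, grid.calibration, config.link_nuclei)
    return nuclei_label_stack(nuclei, slices), nuclei, slices


def oracle_label_stack(grid, threshold: float) -> np.ndarray:
    """Brute-force 26-connected 3D component labelling of the thresholded
    DAPI stack — the independent oracle for the z-linker."""
    mask = grid.channel("DAPI") > threshold
    labels, _ = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label images partition the same foreground into the
    same voxel sets (label values themselves may differ)."""
    fa, fb = a > 0, b > 0
    if not np.array_equal(fa, fb):
        return False
    if not fa.any():
        return True
    pairs = np.unique(np.stack([a[fa], b[fa]]), axis=1)
    n = pairs.shape[1]
    return len(np.unique(pairs[0])) == n and len(np.unique(pairs[1])) == n


def ratio_and_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """mean(y)/mean(x) with its delta-method Monte-Carlo standard error."""
    mx, my = x.mean(), y.mean()
    r = my / mx
    se = r * np.sqrt(x.var(ddof=1) / (x.size * mx**2) + y.var(ddof=1) / (y.size * my**2))
    return float(r), float(se)


def match_to_truth(records_frame, truth_cells, calib=None):
    """Match measured cells to ground-truth cells of the same well/field by
    nearest centroid (um); returns the merged frame."""
    import pandas as pd

    rows = []
    for (well, field), sub in records_frame.groupby(["well", "field"]):
        t = truth_cells[(truth_cells.well == well) & (truth_cells.field == field)]
        tpos = t[["cz_um", "cy_um", "cx_um"]].to_numpy()
        for _, r in sub.iterrows():
            cz, cy, cx = r["centroid_z"], r["centroid_y"], r["centroid_x"]
            d = np.linalg.norm(tpos - np.array([cz, cy, cx]), axis=1)
            i = int(np.argmin(d))
            row = dict(r)
            row.update(
                true_volume_um3=float(t.iloc[i].volume_um3),
                true_n_foci=int(t.iloc[i].n_foci),
                match_dist_um=float(d[i]),
            )
            rows.append(row)
    return pd.DataFrame(rows)


def make_grid(design: PhantomDesign):
    """Single-field convenience: returns (grid, truth)."""
    from nucleovol import make_plate_phantom

    stacks, truth = make_plate_phantom(design)
    assert len(stacks) == len(design.conditions) * design.wells_per_condition * design.fields_per_well
    return stacks, truth


def clean_suite(n_phantoms: int, cells: int = 5, foci=(1, 4), seed0: int = 100):
    """Yield (design, grid, truth) for a suite of independent clean phantoms."""
    for i in range(n_phantoms):
        design = clean_design(seed=seed0 + i, cells=cells, foci=foci)
        stacks, truth = make_grid(design)
        (_, grid), = stacks.items()
        yield design, grid, truth
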
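"""Pipeline configuration: dataclass blocks plus YAML round-trip.

A pipeline config bundles the segmentation, foci, linking, cytoplasm and
aggregation parameter blocks consumed by :mod:`nucleovol.quantify`.  The
YAML layout mirrors the dataclass fields verbatim, e.g.::

    dapi_channel: DAPI
    segmentation: {threshold: "fixed:60", min_area_px2: 25, ...}
    foci: {channel: nP-Tau, detector: tophat, ...}
    link_nuclei: {max_link_dist_um: 2.0, max_z_gap: 1, min_slices: 2}
    link_foci: {max_link_dist_um: 1.0, max_z_gap: 0, min_slices: 1}
    cyto: {shell_width_um: 1.5, exclude_other_nuclei: true}

:func:`default_pipeline_config` derives a config matched to a phantom
design (threshold halfway between background and the in-nucleus DAPI
amplitude, gates scaled from the designed radii), which is the protocol
used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .link3d import CytoParams, LinkParams
from .phantom import PhantomDesign
from .segment2d import FociParams, SegmentationParams

__all__ = [
    "PipelineConfig",
    "default_pipeline_config",
    "load_pipeline_config",
    "save_pipeline_config",
]


@dataclass
class PipelineConfig:
    dapi_channel: str = "DAPI"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    foci: FociParams | None = field(default_factory=FociParams)
    link_nuclei: LinkParams = field(default_factory=LinkParams)
    link_foci: LinkParams = field(
        default_factory=lambda: LinkParams(max_link_dist_um=1.0, max_z_gap=0, min_slices=1)
    )
    cyto: CytoParams | None = field(default_factory=CytoParams)
    min_cells_per_well: int = 50


def default_pipeline_config(design: PhantomDesign) -> PipelineConfig:
    """Analysis protocol matched to a phantom design.

    Uses a fixed DAPI threshold halfway up the in-nucleus amplitude, area
    gates bracketing the designed nuclear cross-sections, and a focus
    prominence floor at a quarter of the designed focus amplitude.
    """
    dapi = design.channel_baselines[design.dapi_channel]
    px = design.pixel_size_xy
    r_px = design.nuclear_radius_um[0] / px
    seg = SegmentationParams(
        smooth_sigma_px=1.0,
        threshold=f"fixed:{dapi.background + 0.5 * dapi.nuclear_amplitude}",
        min_area_px2=max(4.0, 0.05 * math.pi * r_px**2),
        max_area_px2=16.0 * math.pi * r_px**2,
        min_mean_intensity=dapi.background + 0.25 * dapi.nuclear_amplitude,
    )
    foci = None
    foci_channels = design.foci_channels
    if foci_channels:
        ch = foci_channels[0]
        spec = design.channel_baselines[ch]
        fr_px = design.focus_radius_um[0] / px
        foci = FociParams(
            channel=ch,
            min_area_px2=2.0,
            max_area_px2=25.0 * math.pi * fr_px**2,
            brightness_factor=2.0,
            detector="tophat",
            scale_px=max(3.0, round(2.2 * fr_px)),
            min_prominence=0.25 * spec.focus_amplitude,
        )
    return PipelineConfig(
        dapi_channel=design.dapi_channel,
        segmentation=seg,
        foci=foci,
        cyto=CytoParams(shell_width_um=design.cyto_shell_um)
        if any(s.cyto_amplitude > 0 for s in design.channel_baselines.values())
        else None,
    )


# ----------------------------------------------------------------------
# YAML round-trip
# ----------------------------------------------------------------------

_BLOCKS = {
    "segmentation": SegmentationParams,
    "foci": FociParams,
    "link_nuclei": LinkParams,
    "link_foci": LinkParams,
    "cyto": CytoParams,
}


def save_pipeline_config(config: PipelineConfig, path: str | Path) -> Path:
    out: dict = {
        "dapi_channel": config.dapi_channel,
        "min_cells_per_well": config.min_cells_per_well,
    }
    for name in _BLOCKS:
        block = getattr(config, name)
        out[name] = dataclasses.asdict(block) if block is not None else None
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=False))
    return path


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    kwargs: dict = {}
    for key in ("dapi_channel", "min_cells_per_well"):
        if key in raw:
            kwargs[key] = raw[key]
    for name, cls in _BLOCKS.items():
        if name in raw:
            block = raw[name]
            if block is None:
                kwargs[name] = None
            else:
                kwargs[name] = cls(**{k: _coerce(v) for k, v in block.items()})
    return PipelineConfig(**kwargs)


def _coerce(v):
    if isinstance(v, list):
        return tuple(v)
    return v


# ----------------------------------------------------------------------
# phantom design YAML (the `nucleovol simulate --design` file)
# ----------------------------------------------------------------------

def save_design(design: PhantomDesign, path: str | Path) -> Path:
    from .phantom import ChannelSpec, NoiseModel  # noqa: F401  (doc reference)

    d = dataclasses.asdict(design)
    d["image_shape"] = list(design.image_shape)
    d["channel_baselines"] = {
        ch: dataclasses.asdict(spec) for ch, spec in design.channel_baselines.items()
    }
    # YAML-friendly nested mapping: condition -> quantity -> factor
    eff: dict = {}
    for (cond, quantity), f in design.effect_table.items():
        eff.setdefault(cond, {})[quantity] = f
    d["effect_table"] = eff
    path = Path(path)
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_design(path: str | Path) -> PhantomDesign:
    from .phantom import ChannelSpec, NoiseModel

    raw = yaml.safe_load(Path(path).read_text())
    raw["image_shape"] = tuple(raw["image_shape"])
    for key in ("nuclear_radius_um", "foci_per_nucleus", "focus_radius_um",
                "axis_ratio_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    raw["channel_baselines"] = {
        ch: ChannelSpec(**spec) for ch, spec in raw.get("channel_baselines", {}).items()
    }
    if "noise" in raw and isinstance(raw["noise"], dict):
        raw["noise"] = NoiseModel(**raw["noise"])
    eff = raw.get("effect_table", {}) or {}
    raw["effect_table"] = {
        (cond, quantity): float(f)
        for cond, qf in eff.items()
        for quantity, f in qf.items()
    }
    design = PhantomDesign(**raw)
    design.validate()
    return design
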
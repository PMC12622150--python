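"""Synthetic fluorescence phantoms and qPCR Ct tables with known ground truth.

The study design this package targets compares a control condition (empty
vector or a donor/isogenic control line) against MAPT-mutant conditions and
reads out small multiplicative effects on nuclear volume, nucleolar focus
size, and marker intensities from hundreds to thousands of cells per
condition.  Because the raw stacks of such experiments are rarely deposited,
this module generates plates of multi-channel z-stacks whose statistical
structure mirrors that design while every planted quantity is known exactly:

* nuclei are filled ellipsoids with mild, volume-preserving random
  anisotropy, placed by rejection sampling with a minimum in-plane spacing;
* each nucleus carries 1..4 bright spherical nucleolar foci in a designated
  marker channel;
* per-condition effects are purely multiplicative (a volume factor ``f``
  scales every radius by ``f**(1/3)``, an area factor by ``f**(1/2)``);
* the optical train is an isotropic Gaussian blur followed by Poisson shot
  noise and additive Gaussian read noise, each independently switchable off
  so that exact, noise-free oracles remain available.

Ground truth (cell centres, radii, true volumes, planted foci and the
injected factors) is recorded *before* blur and noise are applied.

The companion qPCR generator plants condition-dependent abundance ratios as
Ct shifts of ``-log2(ratio)`` around per-gene baselines, with drift-free
reference genes, so the delta-delta-Ct layer can be validated in closed
form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid

__all__ = [
    "ChannelSpec",
    "NoiseModel",
    "PhantomDesign",
    "GroundTruth",
    "QpcrDesign",
    "PhantomGenerationError",
    "make_plate_phantom",
    "iter_fields",
    "plate_truth",
    "study_presets",
    "qpcr_study_preset",
    "make_ct_table",
    "EFFECT_QUANTITIES",
]

EFFECT_QUANTITIES = (
    "nuclear_volume",
    "focus_area",
    "focus_amplitude",
    "nuclear_marker_amplitude",
    "cyto_marker_amplitude",
)


class PhantomGenerationError(RuntimeError):
    """Raised when cell placement cannot satisfy the spacing constraint."""


@dataclass(frozen=True)
class ChannelSpec:
    """Photometric description of one channel.

    ``background`` is the flat offset everywhere; the three amplitudes are
    *added* inside the corresponding compartment (nucleus, nucleolar focus,
    cytoplasmic shell).  A channel may light up several compartments; an
    amplitude of zero switches that compartment off for the channel.
    """

    background: float = 0.0
    nuclear_amplitude: float = 0.0
    focus_amplitude: float = 0.0
    cyto_amplitude: float = 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian imaging noise: shot noise on the blurred signal
    (interpreted as expected photon counts) plus additive read noise."""

    read_sd: float = 0.0
    shot: bool = False


@dataclass
class PhantomDesign:
    """Full description of a synthetic plate.

    The first entry of ``conditions`` is the control; the effect table must
    leave every control factor at 1.  ``effect_table`` maps
    ``(condition, quantity)`` to a multiplicative factor, with quantities
    drawn from :data:`EFFECT_QUANTITIES`; missing entries default to 1.
    """

    conditions: list[str] = field(default_factory=lambda: ["EV", "P301S"])
    wells_per_condition: int = 6
    fields_per_well: int = 4
    cells_per_field: int = 100
    image_shape: tuple[int, int, int] = (16, 512, 512)
    pixel_size_xy: float = 0.3
    z_step: float = 1.0
    nuclear_radius_um: tuple[float, float] = (3.5, 0.25)
    foci_per_nucleus: tuple[int, int] = (1, 4)
    focus_radius_um: tuple[float, float] = (0.8, 0.1)
    channel_baselines: dict[str, ChannelSpec] = field(
        default_factory=lambda: {
            "DAPI": ChannelSpec(background=10.0, nuclear_amplitude=100.0),
            "nP-Tau": ChannelSpec(background=0.0, focus_amplitude=150.0),
        }
    )
    effect_table: dict[tuple[str, str], float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(read_sd=2.0, shot=True))
    psf_sigma_um: float = 0.2
    min_center_spacing_um: float = 8.0
    cyto_shell_um: float = 1.5
    axis_ratio_range: tuple[float, float] = (0.8, 1.2)
    dapi_channel: str = "DAPI"
    seed: int = 0
    max_place_attempts: int = 10_000

    # ------------------------------------------------------------------
    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def foci_channels(self) -> list[str]:
        return [c for c, s in self.channel_baselines.items() if s.focus_amplitude > 0]

    def factor(self, condition: str, quantity: str) -> float:
        if quantity not in EFFECT_QUANTITIES:
            raise KeyError(f"unknown effect quantity {quantity!r}")
        return float(self.effect_table.get((condition, quantity), 1.0))

    def wells(self) -> list[tuple[str, str]]:
        """Deterministic well roster as ``(well_id, condition)`` pairs,
        condition-major, wells named ``W001``.."""
        out = []
        k = 1
        for cond in self.conditions:
            for _ in range(self.wells_per_condition):
                out.append((f"W{k:03d}", cond))
                k += 1
        return out

    def layout(self) -> pd.DataFrame:
        return pd.DataFrame(self.wells(), columns=["well", "condition"])

    def validate(self) -> None:
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition names")
        for name, n in [
            ("wells_per_condition", self.wells_per_condition),
            ("fields_per_well", self.fields_per_well),
            ("cells_per_field", self.cells_per_field),
        ]:
            if n < 1:
                raise ValueError(f"{name} must be >= 1, got {n}")
        if min(self.image_shape) < 1:
            raise ValueError("image_shape entries must be >= 1")
        for name, (m, s) in [
            ("nuclear_radius_um", self.nuclear_radius_um),
            ("focus_radius_um", self.focus_radius_um),
        ]:
            if m <= 0 or s <= 0:
                raise ValueError(f"{name} mean and sd must be > 0")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel calibration must be > 0")
        if self.min_center_spacing_um <= 0:
            raise ValueError("min_center_spacing_um must be > 0")
        lo, hi = self.foci_per_nucleus
        if not (0 <= lo <= hi):
            raise ValueError("foci_per_nucleus must satisfy 0 <= min <= max")
        if self.dapi_channel not in self.channel_baselines:
            raise ValueError(f"dapi_channel {self.dapi_channel!r} not in channel_baselines")
        for (cond, quantity), f in self.effect_table.items():
            if cond not in self.conditions:
                raise ValueError(f"effect for unknown condition {cond!r}")
            if quantity not in EFFECT_QUANTITIES:
                raise ValueError(f"effect for unknown quantity {quantity!r}")
            if f <= 0:
                raise ValueError(f"effect factor must be > 0, got {f} for {(cond, quantity)}")
            if cond == self.control and f != 1.0:
                raise ValueError(
                    f"control condition {cond!r} must have all effect factors = 1"
                )
        # quick feasibility screen: packing density of exclusion discs must
        # leave room; the hard guarantee is the bounded rejection sampler
        nz, ny, nx = self.image_shape
        area = ny * nx * self.pixel_size_xy**2
        disc = math.pi * (self.min_center_spacing_um / 2) ** 2
        if self.cells_per_field * disc > 0.9 * area:
            raise ValueError(
                "image too small for the requested number of non-overlapping "
                f"placements ({self.cells_per_field} cells, spacing "
                f"{self.min_center_spacing_um} um in {ny}x{nx} px)"
            )


@dataclass
class GroundTruth:
    """Planted truth for a phantom plate, recorded before blur/noise.

    ``cells`` columns: well, field, condition, cell_id, cz_um..cx_um,
    r_um (volume-equivalent radius), rz_um..rx_um (semi-axes),
    volume_um3, n_foci.  ``foci`` columns: well, field, cell_id, focus_id,
    cz_um..cx_um, radius_um, amplitude_factor.
    """

    cells: pd.DataFrame
    foci: pd.DataFrame
    effects: dict[tuple[str, str], float]
    layout: pd.DataFrame

    def condition_mean(self, column: str) -> pd.Series:
        return self.cells.groupby("condition")[column].mean()


# ----------------------------------------------------------------------
# sampling helpers
# ----------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to mean +/- 2.5 sd (and > 0) by resampling."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 2.5 * sd and x > 0:
            return float(x)
    return mean  # pragma: no cover - sd pathologically large


def _field_rngs(design: PhantomDesign, well_idx: int, field_idx: int):
    base = [int(design.seed) & 0x7FFFFFFF, well_idx, field_idx]
    truth = np.random.default_rng(np.random.SeedSequence(base + [0]))
    noise = np.random.default_rng(np.random.SeedSequence(base + [1]))
    return truth, noise


def _sample_field_truth(
    design: PhantomDesign, condition: str, well: str, field_idx: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    nz, ny, nx = design.image_shape
    ext = (nz * design.z_step, ny * design.pixel_size_xy, nx * design.pixel_size_xy)
    f_vol = design.factor(condition, "nuclear_volume")
    f_area = design.factor(condition, "focus_area")
    f_amp = design.factor(condition, "focus_amplitude")
    r_mean, r_sd = design.nuclear_radius_um
    fr_mean, fr_sd = design.focus_radius_um
    lo, hi = design.axis_ratio_range
    pad = 0.3  # um kept clear of the stack faces

    cells: list[dict] = []
    centers_xy: list[tuple[float, float]] = []
    attempts = 0
    for cid in range(1, design.cells_per_field + 1):
        placed = False
        while attempts < design.max_place_attempts:
            attempts += 1
            r = _trunc_normal(rng, r_mean, r_sd) * f_vol ** (1 / 3)
            u = rng.uniform(lo, hi, size=3)
            u /= u.prod() ** (1 / 3)  # volume-preserving shape anisotropy
            axes = r * u  # (rz, ry, rx)
            if any(2 * (a + pad) >= e for a, e in zip(axes, ext)):
                continue
            center = tuple(
                rng.uniform(a + pad, e - a - pad) for a, e in zip(axes, ext)
            )
            ok = all(
                math.hypot(center[1] - y, center[2] - x)
                >= design.min_center_spacing_um
                for (y, x) in centers_xy
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PhantomGenerationError(
                f"could not place cell {cid} in well {well} field {field_idx} "
                f"after {design.max_place_attempts} attempts"
            )
        centers_xy.append((center[1], center[2]))
        cells.append(
            dict(
                well=well,
                field=field_idx,
                condition=condition,
                cell_id=cid,
                cz_um=center[0],
                cy_um=center[1],
                cx_um=center[2],
                r_um=float(np.prod(axes) ** (1 / 3)),
                rz_um=axes[0],
                ry_um=axes[1],
                rx_um=axes[2],
                volume_um3=4 / 3 * math.pi * float(np.prod(axes)),
                n_foci=0,
            )
        )

    foci: list[dict] = []
    f_lo, f_hi = design.foci_per_nucleus
    for cell in cells:
        n_foci = int(rng.integers(f_lo, f_hi + 1)) if f_hi > 0 else 0
        axes = np.array([cell["rz_um"], cell["ry_um"], cell["rx_um"]])
        center = np.array([cell["cz_um"], cell["cy_um"], cell["cx_um"]])
        placed_foci: list[tuple[np.ndarray, float]] = []
        for fid in range(1, n_foci + 1):
            fr = _trunc_normal(rng, fr_mean, fr_sd) * f_area**0.5
            ok_pos = None
            for _ in range(200):
                # uniform in the unit ball, then scaled so the focus sphere
                # stays strictly inside the nuclear ellipsoid
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                v *= rng.uniform() ** (1 / 3)
                scale = np.maximum(0.05, 1.0 - (fr + 0.15) / axes)
                pos = center + v * axes * scale
                # keep foci laterally separated so they never merge in 2D
                if all(
                    math.hypot(pos[1] - q[1], pos[2] - q[2]) >= fr + qr + 0.6
                    for q, qr in placed_foci
                ):
                    ok_pos = pos
                    break
            if ok_pos is None:
                break  # nucleus too crowded; plant fewer foci
            placed_foci.append((ok_pos, fr))
            foci.append(
                dict(
                    well=cell["well"],
                    field=cell["field"],
                    condition=condition,
                    cell_id=cell["cell_id"],
                    focus_id=fid,
                    cz_um=ok_pos[0],
                    cy_um=ok_pos[1],
                    cx_um=ok_pos[2],
                    radius_um=fr,
                    amplitude_factor=f_amp,
                )
            )
        cell["n_foci"] = len(placed_foci)

    cells_df = pd.DataFrame(cells)
    foci_cols = [
        "well", "field", "condition", "cell_id", "focus_id",
        "cz_um", "cy_um", "cx_um", "radius_um", "amplitude_factor",
    ]
    foci_df = pd.DataFrame(foci, columns=foci_cols)
    return cells_df, foci_df


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _ellipsoid_bbox(shape, spacing, center, axes):
    """Bounding-box slices and boolean mask of an axis-aligned ellipsoid.

    ``spacing``/``center``/``axes`` are (z, y, x) in micrometres; voxel i
    sits at (i + 0.5) * spacing.
    """
    los, his, grids = [], [], []
    for dim, (s, c, a) in enumerate(zip(spacing, center, axes)):
        lo = max(0, int(math.floor((c - a) / s - 0.5)))
        hi = min(shape[dim], int(math.ceil((c + a) / s - 0.5)) + 1)
        los.append(lo)
        his.append(hi)
        coords = (np.arange(lo, hi) + 0.5) * s
        grids.append((coords - c) / a)
    gz, gy, gx = np.ix_(grids[0], grids[1], grids[2])
    mask = gz**2 + gy**2 + gx**2 <= 1.0
    return tuple(slice(lo, hi) for lo, hi in zip(los, his)), mask


def render_field(
    design: PhantomDesign,
    condition: str,
    cells: pd.DataFrame,
    foci: pd.DataFrame,
    rng_noise: np.random.Generator,
) -> VoxelGrid:
    """Rasterize one field from its truth records and apply blur + noise."""
    shape = design.image_shape
    spacing = (design.z_step, design.pixel_size_xy, design.pixel_size_xy)
    f_nuc = design.factor(condition, "nuclear_marker_amplitude")
    f_cyto = design.factor(condition, "cyto_marker_amplitude")

    imgs = {
        ch: np.full(shape, spec.background, dtype=np.float64)
        for ch, spec in design.channel_baselines.items()
    }
    occupancy = np.zeros(shape, dtype=bool)

    cell_geom = [
        (
            np.array([c.cz_um, c.cy_um, c.cx_um]),
            np.array([c.rz_um, c.ry_um, c.rx_um]),
        )
        for c in cells.itertuples()
    ]
    for center, axes in cell_geom:
        sl, mask = _ellipsoid_bbox(shape, spacing, center, axes)
        occupancy[sl] |= mask
        for ch, spec in design.channel_baselines.items():
            if spec.nuclear_amplitude > 0:
                amp = spec.nuclear_amplitude * (1.0 if ch == design.dapi_channel else f_nuc)
                imgs[ch][sl][mask] += amp

    if any(s.cyto_amplitude > 0 for s in design.channel_baselines.values()):
        for center, axes in cell_geom:
            sl, shell = _ellipsoid_bbox(shape, spacing, center, axes + design.cyto_shell_um)
            shell = shell & ~occupancy[sl]
            for ch, spec in design.channel_baselines.items():
                if spec.cyto_amplitude > 0:
                    imgs[ch][sl][shell] += spec.cyto_amplitude * f_cyto

    for f in foci.itertuples():
        center = np.array([f.cz_um, f.cy_um, f.cx_um])
        sl, mask = _ellipsoid_bbox(shape, spacing, center, np.full(3, f.radius_um))
        for ch, spec in design.channel_baselines.items():
            if spec.focus_amplitude > 0:
                imgs[ch][sl][mask] += spec.focus_amplitude * f.amplitude_factor

    if design.psf_sigma_um > 0:
        sig = (
            design.psf_sigma_um / design.z_step,
            design.psf_sigma_um / design.pixel_size_xy,
            design.psf_sigma_um / design.pixel_size_xy,
        )
        for ch in imgs:
            imgs[ch] = gaussian_filter(imgs[ch], sigma=sig)

    for ch in imgs:
        img = imgs[ch]
        if design.noise.shot:
            img = rng_noise.poisson(np.clip(img, 0, None)).astype(np.float64)
        if design.noise.read_sd > 0:
            img = img + rng_noise.normal(0.0, design.noise.read_sd, size=shape)
        imgs[ch] = np.clip(img, 0, None).astype(np.float32)

    return VoxelGrid(
        {ch: imgs[ch] for ch in design.channel_baselines},
        design.pixel_size_xy,
        design.z_step,
        meta={"condition": condition},
    )


# ----------------------------------------------------------------------
# plate-level API
# ----------------------------------------------------------------------

def plate_truth(design: PhantomDesign) -> GroundTruth:
    """Sample the full plate's ground truth (no rendering).

    Deterministic for a fixed design and seed; per-field sub-streams are
    derived from the design seed so the truth is independent of the order
    in which fields are later rendered.
    """
    design.validate()
    all_cells, all_foci = [], []
    for wi, (well, cond) in enumerate(design.wells()):
        for fi in range(design.fields_per_well):
            rng_truth, _ = _field_rngs(design, wi, fi)
            cells, foci = _sample_field_truth(design, cond, well, fi, rng_truth)
            all_cells.append(cells)
            all_foci.append(foci)
    return GroundTruth(
        cells=pd.concat(all_cells, ignore_index=True),
        foci=pd.concat(all_foci, ignore_index=True),
        effects=dict(design.effect_table),
        layout=design.layout(),
    )


def iter_fields(design: PhantomDesign) -> Iterator[tuple[str, int, str, VoxelGrid]]:
    """Yield ``(well, field, condition, stack)`` one field at a time.

    Rendering is streamed so plates far larger than memory can be produced;
    the truth for any field matches :func:`plate_truth` exactly.
    """
    design.validate()
    for wi, (well, cond) in enumerate(design.wells()):
        for fi in range(design.fields_per_well):
            rng_truth, rng_noise = _field_rngs(design, wi, fi)
            cells, foci = _sample_field_truth(design, cond, well, fi, rng_truth)
            yield well, fi, cond, render_field(design, cond, cells, foci, rng_noise)


def make_plate_phantom(
    design: PhantomDesign,
) -> tuple[dict[tuple[str, int], VoxelGrid], GroundTruth]:
    """Generate the whole plate in memory.

    Returns a dict keyed by ``(well, field)`` plus the :class:`GroundTruth`.
    For large designs prefer :func:`iter_fields`, which streams stacks.
    """
    truth = plate_truth(design)
    stacks = {(well, fi): grid for well, fi, _cond, grid in iter_fields(design)}
    return stacks, truth


# ----------------------------------------------------------------------
# presets encoding the reported per-condition effect magnitudes
# ----------------------------------------------------------------------

# (model, mutation) -> control name, {quantity: factor}
_IMAGING_PRESETS: dict[tuple[str, str], tuple[str, dict[str, float]]] = {
    # Differentiated SH-SY5Y, 1 h induction: ~2.5 % / ~2.7 % nuclear-volume
    # increase, ~10 % / ~6 % nucleolar-size increase, ~100 % / ~140 %
    # nucleolar nP-Tau intensity increase (P301S / S305N).
    ("SH-SY5Y-1h", "P301S"): (
        "EV",
        {"nuclear_volume": 1.025, "focus_area": 1.10, "focus_amplitude": 2.0},
    ),
    ("SH-SY5Y-1h", "S305N"): (
        "EV",
        {"nuclear_volume": 1.027, "focus_area": 1.06, "focus_amplitude": 2.4},
    ),
    # 48 h sustained induction: ~15 % / ~13 % nuclear volume, ~12 % / ~16 %
    # nucleolar size.  The 48 h nucleolar tau intensity increase was reported
    # as similar to 1 h, so the 1 h amplitude factors are carried over.
    ("SH-SY5Y-48h", "P301S"): (
        "EV",
        {"nuclear_volume": 1.15, "focus_area": 1.12, "focus_amplitude": 2.0},
    ),
    ("SH-SY5Y-48h", "S305N"): (
        "EV",
        {"nuclear_volume": 1.13, "focus_area": 1.16, "focus_amplitude": 2.4},
    ),
    # iPSC-derived neurons: ~52 % / ~45 % nuclear volume, ~26 % / ~35 %
    # nucleolar size (mean 2D focus area), ~1.5 % / ~4 % nucleolar nP-Tau.
    ("iPSC", "P301S"): (
        "Iso-Ctrl",
        {"nuclear_volume": 1.52, "focus_area": 1.26, "focus_amplitude": 1.015},
    ),
    ("iPSC", "IVS10+16"): (
        "Don-Ctrl",
        {"nuclear_volume": 1.45, "focus_area": 1.35, "focus_amplitude": 1.04},
    ),
}


def study_presets(model: str, mutation: str) -> PhantomDesign:
    """Phantom design whose effect table encodes the reported effect sizes
    for one cell model and MAPT mutation.

    ``model`` is one of ``SH-SY5Y-1h``, ``SH-SY5Y-48h``, ``iPSC``;
    ``mutation`` one of ``P301S``, ``S305N`` (SH-SY5Y) or ``P301S``,
    ``IVS10+16`` (iPSC).  The returned design has the control condition
    first, six wells per condition and ~400 (SH-SY5Y) or ~200 (iPSC) cells
    per well, matching the scale of the underlying experiments
    (>= 2,000 / >= 1,000 cells per condition respectively).
    """
    key = (model, mutation)
    if key not in _IMAGING_PRESETS:
        valid = ", ".join(f"{m}/{mut}" for m, mut in sorted(_IMAGING_PRESETS))
        raise ValueError(f"unknown model/mutation pair {model}/{mutation}; valid: {valid}")
    control, factors = _IMAGING_PRESETS[key]
    mutant = mutation
    design = PhantomDesign(
        conditions=[control, mutant],
        effect_table={(mutant, q): f for q, f in factors.items()},
    )
    if model == "iPSC":
        design = replace(design, cells_per_field=50)
    return design


# ----------------------------------------------------------------------
# qPCR
# ----------------------------------------------------------------------

@dataclass
class QpcrDesign:
    """Synthetic qPCR experiment: per-gene baseline Ct values, per-condition
    abundance ratios for target genes, drift-free reference genes, and
    Gaussian Ct noise.

    ``samples_per_condition`` models biological replicates (independent
    cultures), each measured with ``replicates_per_sample`` technical
    replicates; the statistical comparison downstream runs on per-sample
    delta-Ct values.
    """

    conditions: list[str] = field(default_factory=lambda: ["EV", "P301S"])
    target_genes: list[str] = field(default_factory=lambda: ["45S", "28S", "18S"])
    reference_genes: tuple[str, str] = ("ACTB", "RPS27")
    replicates_per_sample: int = 3
    samples_per_condition: int = 3
    baseline_ct: dict[str, float] = field(default_factory=dict)
    abundance_ratio: dict[tuple[str, str], float] = field(default_factory=dict)
    ct_noise_sd: float = 0.1
    seed: int = 0

    _DEFAULT_BASELINES = {
        "45S": 12.0, "28S": 8.0, "18S": 8.0,
        "MAPT-4R": 28.0, "MAPT-total": 24.0,
        "ACTB": 18.0, "RPS27": 20.0,
    }

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def genes(self) -> list[str]:
        return list(self.target_genes) + list(self.reference_genes)

    def baseline(self, gene: str) -> float:
        if gene in self.baseline_ct:
            return float(self.baseline_ct[gene])
        if gene in self._DEFAULT_BASELINES:
            return self._DEFAULT_BASELINES[gene]
        return 25.0

    def ratio(self, condition: str, gene: str) -> float:
        if gene in self.reference_genes:
            return 1.0
        return float(self.abundance_ratio.get((condition, gene), 1.0))

    def validate(self) -> None:
        if self.replicates_per_sample < 2:
            raise ValueError("replicates_per_sample must be >= 2")
        if self.samples_per_condition < 1:
            raise ValueError("samples_per_condition must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        # the amplification protocol runs 45 cycles; baselines must stay inside
        for g in self.genes:
            b = self.baseline(g)
            if not (0 < b < 45):
                raise ValueError(f"baseline Ct for {g} must be in (0, 45), got {b}")
        for (cond, gene), r in self.abundance_ratio.items():
            if r <= 0:
                raise ValueError(f"abundance ratio must be > 0, got {r} for {(cond, gene)}")
            if gene in self.reference_genes and r != 1.0:
                raise ValueError(f"reference gene {gene} must have ratio 1 in all conditions")
            if cond == self.control and r != 1.0:
                raise ValueError(f"control condition must have all ratios 1 ({gene})")


def make_ct_table(design: QpcrDesign) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Generate a replicate-level Ct table and the planted fold changes.

    Ct for gene *g*, condition *c* is ``baseline(g) - log2(ratio(c, g))``
    plus i.i.d. Gaussian noise per technical replicate; reference genes use
    ratio 1 everywhere.  Returns ``(table, true_folds)`` where the table has
    columns ``sample, condition, gene, replicate, ct`` and ``true_folds``
    maps ``(condition, gene)`` to the planted ratio.
    """
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed) & 0x7FFFFFFF, 17]))
    rows = []
    for cond in design.conditions:
        for s in range(1, design.samples_per_condition + 1):
            sample = f"{cond}-s{s}"
            for gene in design.genes:
                mu = design.baseline(gene) - math.log2(design.ratio(cond, gene))
                for rep in range(1, design.replicates_per_sample + 1):
                    noise = rng.normal(0.0, design.ct_noise_sd) if design.ct_noise_sd > 0 else 0.0
                    rows.append((sample, cond, gene, rep, mu + noise))
    table = pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "ct"])
    true_folds = {
        (cond, gene): design.ratio(cond, gene)
        for cond in design.conditions
        for gene in design.target_genes
    }
    return table, true_folds


# (model, mutation) -> {gene: fold vs control}; rRNA species folds follow the
# reported qPCR percentages, MAPT probe folds encode the reported rank order
# (robust induction, P301S > S305N in SH-SY5Y) with magnitudes chosen here.
_QPCR_PRESETS: dict[tuple[str, str], dict[str, float]] = {
    ("SH-SY5Y-1h", "P301S"): {
        "45S": 1.51, "28S": 1.43, "18S": 1.37, "MAPT-4R": 6.0, "MAPT-total": 2.5,
    },
    ("SH-SY5Y-1h", "S305N"): {
        "45S": 2.34, "28S": 2.45, "18S": 1.47, "MAPT-4R": 4.0, "MAPT-total": 2.0,
    },
    ("iPSC", "P301S"): {
        "45S": 1.60, "28S": 2.41, "18S": 3.83, "MAPT-4R": 3.0, "MAPT-total": 2.0,
    },
    ("iPSC", "IVS10+16"): {
        "45S": 2.03, "28S": 1.30, "18S": 1.47, "MAPT-4R": 2.0, "MAPT-total": 1.6,
    },
}


def qpcr_study_preset(model: str, mutation: str) -> QpcrDesign:
    """Qpcr design planting the reported rRNA fold changes for one model /
    mutation pair (models ``SH-SY5Y-1h`` and ``iPSC``)."""
    key = (model, mutation)
    if key not in _QPCR_PRESETS:
        valid = ", ".join(f"{m}/{mut}" for m, mut in sorted(_QPCR_PRESETS))
        raise ValueError(f"unknown model/mutation pair {model}/{mutation}; valid: {valid}")
    control = _IMAGING_PRESETS[key][0]
    folds = _QPCR_PRESETS[key]
    return QpcrDesign(
        conditions=[control, mutation],
        target_genes=list(folds),
        abundance_ratio={(mutation, g): f for g, f in folds.items()},
    )
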
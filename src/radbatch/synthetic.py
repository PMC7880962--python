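"""Synthetic study material: digital phantom, acquisition simulator, clinical cohort.

Three generators make the whole pipeline testable without any scan data:

* :func:`make_phantom_truth` builds a fine-resolution digital analogue of a
  tissue-characterization phantom — parallel cylindrical rods of distinct
  tissue-equivalent densities in an air background — with a smooth random
  texture field inside each rod.
* :func:`simulate_acquisition` degrades that ground truth the way a CT
  acquisition/reconstruction chain does: z-averaging over the slice
  thickness (partial volume), resampling to the acquired voxel grid,
  a reconstruction-kernel PSF (soft kernels blur, sharp kernels overshoot),
  a voltage-dependent contrast scaling, and current-dependent noise.
* :func:`make_clinical_cohort` draws a two-class feature table whose
  between-batch structure follows the additive/multiplicative location-scale
  model that ComBat assumes, with known ground-truth batch parameters.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, GeometryError
from .image_io import ROIMask, VoxelGrid, resample_grid

__all__ = [
    "MaterialSpec",
    "AcquisitionProtocol",
    "BatchEffectSpec",
    "RodLayout",
    "GAMMEX_MATERIALS",
    "KERNELS",
    "rod_layout",
    "rasterize_rod_masks",
    "make_phantom_truth",
    "simulate_acquisition",
    "make_clinical_cohort",
    "default_clinical_cohort",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class MaterialSpec:
    """A rod material: mean density, internal texture amplitude and scale."""

    material_id: str
    mean_hu: float
    sd_hu: float = 15.0
    texture_scale: float = 1.5  # mm, correlation length of the texture field

    def __post_init__(self) -> None:
        if not (-1000.0 <= self.mean_hu <= 2000.0):
            raise ValueError(f"mean_hu out of CT range: {self.mean_hu}")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be positive")


#: 13 tissue-equivalent rod materials, mean HU loosely following the densities
#: of a commercial tissue-characterization phantom (lung surrogates through
#: cortical bone, plus water and near-water soft tissues).
GAMMEX_MATERIALS: tuple[MaterialSpec, ...] = (
    MaterialSpec("lung_300", -690.0),
    MaterialSpec("lung_450", -440.0),
    MaterialSpec("adipose", -90.0),
    MaterialSpec("breast", -35.0),
    MaterialSpec("water", 0.0),
    MaterialSpec("solid_water", 5.0),
    MaterialSpec("brain", 30.0),
    MaterialSpec("liver", 90.0),
    MaterialSpec("inner_bone", 210.0),
    MaterialSpec("bone_b200", 230.0),
    MaterialSpec("bone_cb2_30", 450.0),
    MaterialSpec("bone_cb2_50", 800.0),
    MaterialSpec("cortical_bone", 1150.0),
)

#: Reconstruction kernels as a monotone sharpness ladder.  A-C are smoothing
#: kernels (Gaussian PSF, sigma in mm); D-E are sharpening kernels (unsharp
#: masking over a 0.5 mm Gaussian, with increasing gain).
KERNELS: dict[str, dict[str, float]] = {
    "A": {"sigma": 1.2},
    "B": {"sigma": 0.8},
    "C": {"sigma": 0.5},
    "D": {"sigma": 0.5, "gain": 0.5},
    "E": {"sigma": 0.5, "gain": 1.0},
}


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scanner settings for one simulated acquisition/reconstruction."""

    voltage: float = 120.0  # kV
    current: float = 200.0  # mAs; np.inf disables noise
    slice_thickness: float = 2.0  # mm, z-averaging window
    slice_spacing: float = 1.0  # mm, reconstructed z step
    pixel_size: float = 0.78  # mm, in-plane (square)
    kernel_id: str = "A"

    def __post_init__(self) -> None:
        for name in ("voltage", "current", "slice_thickness", "slice_spacing", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_id not in KERNELS:
            raise ConfigError(
                f"unknown kernel {self.kernel_id!r}; expected one of {sorted(KERNELS)}"
            )

    def label(self) -> str:
        cur = "inf" if np.isinf(self.current) else f"{self.current:g}"
        return (
            f"kV{self.voltage:g}_mAs{cur}_th{self.slice_thickness:g}"
            f"_sp{self.slice_spacing:g}_px{self.pixel_size:g}_k{self.kernel_id}"
        )


@dataclass(frozen=True)
class BatchEffectSpec:
    """Ground-truth location-scale effect of one batch on every feature."""

    batch_id: str
    shift_per_feature: np.ndarray  # additive, feature units
    scale_per_feature: np.ndarray  # multiplicative on the noise, > 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift_per_feature", np.asarray(self.shift_per_feature, float))
        object.__setattr__(self, "scale_per_feature", np.asarray(self.scale_per_feature, float))
        if np.any(self.scale_per_feature <= 0):
            raise ValueError(f"batch {self.batch_id}: scale factors must be positive")


@dataclass(frozen=True)
class RodLayout:
    """Physical rod geometry, independent of any voxel grid."""

    centers: tuple[tuple[float, float], ...]  # (x, y) mm
    radius: float  # mm
    z_range: tuple[float, float]  # mm
    field_of_view: tuple[float, float, float]  # physical extent (mm)


def rod_layout(
    n_rods: int,
    rod_diameter: float = 6.0,
    rod_height: float = 10.0,
    margin: float = 2.0,
) -> RodLayout:
    """Place up to 13 parallel rods: one center rod, a ring of 4, a ring of 8.

    Ring radii are multiples of the rod diameter chosen so neighboring rods
    keep at least one radius of clearance; the bounding box adds ``margin`` mm
    of air on every side so no mask touches the volume edge.
    """
    if n_rods < 1:
        raise ValueError("need at least one material")
    if n_rods > 13:
        raise ValueError("layout supports at most 13 rods")
    d = float(rod_diameter)
    offsets: list[tuple[float, float]] = [(0.0, 0.0)]
    for k in range(4):
        a = np.pi / 2 * k
        offsets.append((1.6 * d * np.cos(a), 1.6 * d * np.sin(a)))
    for k in range(8):
        a = np.pi / 4 * k + np.pi / 8
        offsets.append((3.1 * d * np.cos(a), 3.1 * d * np.sin(a)))
    offsets = offsets[:n_rods]
    half = 3.1 * d + d / 2 + margin
    centers = tuple((x + half, y + half) for x, y in offsets)
    # non-overlap guard (layout is fixed, but rod_diameter drives everything)
    pts = np.array(centers)
    if len(pts) > 1:
        dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < d * (1 - 1e-9):
            raise GeometryError("rod layout produces overlapping rods")
    return RodLayout(
        centers=centers,
        radius=d / 2,
        z_range=(margin, margin + rod_height),
        field_of_view=(2 * half, 2 * half, rod_height + 2 * margin),
    )


def rasterize_rod_masks(layout: RodLayout, grid: VoxelGrid) -> list[ROIMask]:
    """Cylinder masks for every rod, evaluated at the voxel centers of ``grid``.

    Because masks are rasterized analytically on each acquired grid, the same
    physical VOI is reused across protocols without mask interpolation.
    """
    nx, ny, nz = grid.shape
    x = grid.origin[0] + np.arange(nx) * grid.spacing[0]
    y = grid.origin[1] + np.arange(ny) * grid.spacing[1]
    z = grid.origin[2] + np.arange(nz) * grid.spacing[2]
    zin = (z >= layout.z_range[0]) & (z <= layout.z_range[1])
    masks = []
    for cx, cy in layout.centers:
        disk = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2 <= layout.radius**2
        vals = disk[:, :, None] & zin[None, None, :]
        masks.append(ROIMask(vals, grid.spacing, grid.origin))
    return masks


def _texture_field(shape, spacing, scale_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth unit-variance Gaussian random field with correlation length scale_mm."""
    white = rng.standard_normal(shape)
    sigma = [scale_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def make_phantom_truth(
    materials: list[MaterialSpec] | tuple[MaterialSpec, ...] = GAMMEX_MATERIALS,
    rod_diameter: float = 6.0,
    grid_spacing: float = 0.35,
    seed: int = 0,
    rod_height: float = 10.0,
) -> tuple[VoxelGrid, list[ROIMask], RodLayout]:
    """Fine-resolution ground-truth phantom volume.

    Each rod carries a smooth random texture field with the material's mean
    and standard deviation; the background is air (-1000 HU).  Returns the
    volume, one cylinder mask per material (same order), and the layout used,
    so masks can be re-rasterized on any simulated acquisition grid.
    """
    materials = list(materials)
    if len(materials) < 1:
        raise ValueError("need at least one material")
    if len({m.material_id for m in materials}) != len(materials):
        raise ValueError("material_ids must be distinct")
    if grid_spacing > 0.5:
        raise ValueError("ground truth requires grid_spacing <= 0.5 mm")
    layout = rod_layout(len(materials), rod_diameter=rod_diameter, rod_height=rod_height)
    shape = tuple(
        int(np.ceil(fov / grid_spacing)) for fov in layout.field_of_view
    )
    grid = VoxelGrid(
        np.full(shape, AIR_HU), (grid_spacing,) * 3, (0.0, 0.0, 0.0)
    )
    masks = rasterize_rod_masks(layout, grid)
    rng = np.random.default_rng(seed)
    for mat, mask in zip(materials, masks):
        roi = mask.values
        if mat.sd_hu == 0:
            grid.values[roi] = mat.mean_hu
        else:
            fld = _texture_field(shape, grid.spacing, mat.texture_scale, rng)
            grid.values[roi] = mat.mean_hu + mat.sd_hu * fld[roi]
    return grid, masks, layout


def _voltage_contrast(voltage: float, reference: float = 120.0, strength: float = 0.5) -> float:
    """Linear HU contrast factor, monotone in 1/voltage, = 1 at the reference kV."""
    return 1.0 + strength * (reference / voltage - 1.0)


def simulate_acquisition(
    truth: VoxelGrid,
    protocol: AcquisitionProtocol,
    seed: int = 0,
    noise_hu_at_reference: float = 10.0,
    reference_current: float = 200.0,
) -> VoxelGrid:
    """Degrade a fine ground truth into one simulated acquisition.

    Stages, in order:

    1. z-averaging over a ``slice_thickness`` window (partial-volume model);
    2. linear resampling to ``(pixel_size, pixel_size, slice_spacing)``;
    3. reconstruction-kernel PSF (Gaussian blur for A-C, unsharp masking for D-E);
    4. voltage contrast: HU' = c(kV) * HU with c monotone in 1/kV, c(120) = 1;
    5. additive white Gaussian noise with sd proportional to 1/sqrt(mAs)
       (``current=np.inf`` turns noise off).
    """
    dz = truth.spacing[2]
    if protocol.pixel_size < min(truth.spacing[:2]) or protocol.slice_spacing < dz:
        raise ValueError(
            "truth grid must be finer than the acquired pixel size and slice spacing"
        )
    window = max(1, int(round(protocol.slice_thickness / dz)))
    averaged = ndimage.uniform_filter1d(truth.values, size=window, axis=2, mode="nearest")
    acq = resample_grid(
        VoxelGrid(averaged, truth.spacing, truth.origin),
        (protocol.pixel_size, protocol.pixel_size, protocol.slice_spacing),
        order=1,
    )
    k = KERNELS[protocol.kernel_id]
    sigma_vox = [k["sigma"] / s for s in acq.spacing]
    blurred = ndimage.gaussian_filter(acq.values, sigma=sigma_vox, mode="nearest")
    if "gain" in k:  # sharp kernel: unsharp masking
        out = acq.values + k["gain"] * (acq.values - blurred)
    else:
        out = blurred
    out = _voltage_contrast(protocol.voltage) * out
    if np.isfinite(protocol.current):
        sd = noise_hu_at_reference * np.sqrt(reference_current / protocol.current)
        out = out + np.random.default_rng(seed).normal(0.0, sd, out.shape)
    return VoxelGrid(out, acq.spacing, acq.origin)


def make_clinical_cohort(
    n_per_class: int | tuple[int, int],
    n_features: int,
    class_effect: np.ndarray | float,
    batch_specs: list[BatchEffectSpec],
    batch_assignment: list[str] | np.ndarray,
    noise_sd: np.ndarray | float = 1.0,
    seed: int = 0,
    baseline: np.ndarray | float = 0.0,
    class_names: tuple[str, str] = ("colorectal", "renal"),
) -> pd.DataFrame:
    """Two-class feature table with known location-scale batch structure.

    Every sample's feature vector is

        y = baseline + class_effect * [class == second] + shift_batch
            + scale_batch * eps,       eps ~ N(0, noise_sd)

    exactly the additive/multiplicative model parametric ComBat fits, so the
    generator doubles as a ground truth for parameter-recovery tests.
    Returns a DataFrame with ``sample_id``, ``class_label``, ``batch`` and
    ``n_features`` feature columns named ``f000``, ``f001``, ...
    """
    if isinstance(n_per_class, (int, np.integer)):
        n_per_class = (int(n_per_class), int(n_per_class))
    if min(n_per_class) < 1:
        raise ValueError("n_per_class must be positive")
    n = sum(n_per_class)
    batch_assignment = list(batch_assignment)
    if len(batch_assignment) != n:
        raise ValueError(
            f"batch_assignment has {len(batch_assignment)} entries for {n} samples"
        )
    spec_by_id = {b.batch_id: b for b in batch_specs}
    unknown = sorted(set(batch_assignment) - set(spec_by_id))
    if unknown:
        raise ValueError(f"batch labels without a BatchEffectSpec: {unknown}")
    class_effect = np.broadcast_to(np.asarray(class_effect, float), (n_features,))
    baseline = np.broadcast_to(np.asarray(baseline, float), (n_features,))
    noise_sd = np.broadcast_to(np.asarray(noise_sd, float), (n_features,))
    for b in batch_specs:
        for arr_name in ("shift_per_feature", "scale_per_feature"):
            if getattr(b, arr_name).shape not in ((), (n_features,)):
                raise ValueError(f"batch {b.batch_id}: {arr_name} length != n_features")

    rng = np.random.default_rng(seed)
    classes = [class_names[0]] * n_per_class[0] + [class_names[1]] * n_per_class[1]
    rows = np.empty((n, n_features))
    for i, (cls, bat) in enumerate(zip(classes, batch_assignment)):
        spec = spec_by_id[bat]
        eps = rng.normal(0.0, noise_sd)
        rows[i] = (
            baseline
            + class_effect * (cls == class_names[1])
            + spec.shift_per_feature
            + spec.scale_per_feature * eps
        )
    feat_names = [f"f{i:03d}" for i in range(n_features)]
    df = pd.DataFrame(rows, columns=feat_names)
    df.insert(0, "sample_id", [f"s{i:03d}" for i in range(n)])
    df.insert(1, "class_label", classes)
    df.insert(2, "batch", batch_assignment)
    return df


def default_clinical_cohort(
    seed: int = 0,
    n_features: int = 93,
    class_effect_sd: float = 0.8,
    batch_shift_sd: float = 1.0,
    batch_scale: float = 1.6,
    n_class_features: int | None = None,
) -> pd.DataFrame:
    """Cohort emulating the clinical study arm at its published size.

    97 liver-metastasis samples (52 colorectal, 45 renal) spread over two
    scanner batches with the published cross-tabulation (Siemens: 28 + 23,
    GE: 24 + 22).  A random subset of ``n_class_features`` features carries a
    class effect of ~``class_effect_sd`` noise SDs (default subset size scales
    with ``n_features``, 30 of 93); the second batch adds a
    location shift (~``batch_shift_sd`` SDs, random sign per feature) and
    inflates the noise scale by ``batch_scale`` on every feature, so the
    batch effect partially masks the class signal, as scanner effects do.
    """
    rng = np.random.default_rng(seed)
    if n_class_features is None:
        n_class_features = max(1, round(0.32 * n_features))  # 30 of 93
    class_effect = np.zeros(n_features)
    idx = rng.choice(n_features, size=n_class_features, replace=False)
    class_effect[idx] = rng.normal(class_effect_sd, 0.2 * class_effect_sd, n_class_features)
    shift = rng.normal(0.0, batch_shift_sd, n_features)
    siemens = BatchEffectSpec("siemens", np.zeros(n_features), np.ones(n_features))
    ge = BatchEffectSpec("ge", shift, np.full(n_features, batch_scale))
    # published lesion cross-tab: rows = class (colorectal, renal), cols = (siemens, ge)
    assignment = (
        ["siemens"] * 28 + ["ge"] * 24 + ["siemens"] * 23 + ["ge"] * 22
    )
    return make_clinical_cohort(
        n_per_class=(52, 45),
        n_features=n_features,
        class_effect=class_effect,
        batch_specs=[siemens, ge],
        batch_assignment=assignment,
        noise_sd=1.0,
        seed=int(rng.integers(2**31 - 1)),
    )
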
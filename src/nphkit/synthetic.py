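"""Synthetic phantom cohorts, parcellations and streamline sets.

The phantom emulates the contrast that matters for hydrocephalus work: a
skull shell, a subarachnoid CSF rim, gray-white bulk, paired lateral
ventricles with explicit anterior frontal-horn protrusions (so the Evans'
index A width is measurable by construction), and a separate inferior
cerebellar compartment.  Geometry is written in canonical millimetres for
a 128 mm field and scales proportionally with the actual grid extent, so
any shape divisible by 16 is a valid phantom grid.

Default construction widths: frontal horns span +/-15 mm (A = 30 mm) and
the inner skull spans +/-50 mm (B = 100 mm) on the default grid, i.e. a
built Evans' index of 0.30.  The ventricle dilation factor scales the
ventricular system; 1.0 is a normal subject, values above ~1.5 produce an
unambiguous hydrocephalic phantom.

CT-like intensity means (Hounsfield-flavoured): CSF 8, gray-white 30,
skull 1000, background -1000, plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvariantError
from .types import (
    PHANTOM_LEGEND,
    LabelVolume,
    StreamlineSet,
    VolumeGrid,
    default_affine,
)

#: canonical half-field the geometry below is written for (mm)
_CANON_HALF = 64.0

#: per-class CT-like intensity means
CLASS_INTENSITY = {0: -1000.0, 1: 8.0, 2: 8.0, 3: 30.0, 4: 8.0, 5: 30.0, 6: 1000.0}


@dataclass
class PhantomParams:
    """Parameters of one phantom head.

    shape must be divisible by 16 on every axis (the segmentation network
    halves the grid four times); dilation >= 1 scales the ventricles.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    dilation: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0
    horn_halfwidth_mm: float = 15.0   # canonical; A = 2 * this at dilation 1
    inner_skull_halfwidth_mm: float = 50.0  # canonical; B = 2 * this

    def validate(self):
        if len(self.shape) != 3 or any(int(s) % 16 != 0 or s <= 0 for s in self.shape):
            raise InvariantError(f"phantom shape must be divisible by 16, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InvariantError("spacing must be strictly positive")
        if self.dilation < 1.0:
            raise InvariantError(f"ventricle dilation must be >= 1, got {self.dilation}")
        if self.noise_sd < 0:
            raise InvariantError("noise sd must be nonnegative")


@dataclass
class CohortSpec:
    """A two-group phantom cohort: normal controls and dilated-ventricle NPH."""

    n_normal: int = 10
    n_nph: int = 10
    dilation_range: tuple[float, float] = (1.5, 1.9)
    base: PhantomParams = field(default_factory=PhantomParams)
    seed: int = 0

    def validate(self):
        if self.n_normal < 0 or self.n_nph < 0:
            raise InvariantError("cohort counts must be >= 0")
        lo, hi = self.dilation_range
        if not (1.0 < lo <= hi):
            raise InvariantError(
                f"NPH dilation interval must satisfy 1 < lo <= hi, got {self.dilation_range}"
            )
        self.base.validate()


def _world_grids(shape, spacing):
    """Voxel-centre world coordinates (centred grid) per axis."""
    affine = default_affine(shape, spacing)
    axes = [
        (np.arange(shape[i]) * spacing[i] + affine[i, 3]) for i in range(3)
    ]
    return affine, np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, semi):
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_phantom(params: PhantomParams) -> tuple[VolumeGrid, LabelVolume]:
    """Generate one CT-like phantom and its 6-class ground-truth labels.

    Legend: 1 ventricle, 2 subarachnoid, 3 gray-white, 4 cerebellar CSF,
    5 cerebellar gray-white, 6 skull; 0 background.  Deterministic for a
    fixed seed; ventricle voxel count grows strictly with dilation.
    """
    params.validate()
    shape, spacing, d = params.shape, params.spacing, params.dilation
    affine, (x, y, z) = _world_grids(shape, spacing)
    half = np.asarray(shape) * np.asarray(spacing) / 2.0
    sx, sy, sz = half / _CANON_HALF  # per-axis scale from canonical mm
    s3 = np.array([sx, sy, sz])

    def C(cx, cy, cz):  # scale a canonical centre
        return np.array([cx, cy, cz]) * s3

    def S(ax, ay, az):  # scale canonical semi-axes
        return np.array([ax, ay, az]) * s3

    labels = np.zeros(shape, dtype=np.uint8)

    bskull = params.inner_skull_halfwidth_mm
    outer = _ellipsoid(x, y, z, C(0, 0, 0), S(bskull + 5.0, 63.0, 51.0))
    inner = _ellipsoid(x, y, z, C(0, 0, 0), S(bskull, 58.0, 46.0))
    labels[outer & ~inner] = 6
    labels[inner] = 2  # CSF fills the cavity; brain painted on top

    cerebrum = _ellipsoid(x, y, z, C(0, 0, 10), S(44, 52, 30))
    labels[inner & cerebrum] = 3

    cereb = np.zeros(shape, dtype=bool)
    shell = np.zeros(shape, dtype=bool)
    for side in (-1, 1):
        cereb |= _ellipsoid(x, y, z, C(side * 14, -26, -28), S(12, 14, 10))
        shell |= _ellipsoid(x, y, z, C(side * 14, -26, -28), S(15, 17, 13))
    medial = _ellipsoid(x, y, z, C(0, -26, -28), S(5, 7, 6))
    labels[(shell | medial) & (labels == 2)] = 4
    labels[cereb & inner] = 5

    # lateral-ventricle bodies (ellipsoids) + prism-shaped frontal horns
    vent = np.zeros(shape, dtype=bool)
    for side in (-1, 1):
        vent |= _ellipsoid(x, y, z, C(side * 8, -12, 10), S(7 * d, 18 * d, 9 * d))
        horn_lo, horn_hi = 4.0 * sx, params.horn_halfwidth_mm * d * sx
        vent |= (
            (side * x >= horn_lo)
            & (side * x <= horn_hi)
            & (y >= 20 * sy)
            & (y <= 30 * sy)
            & (z >= 6 * sz)
            & (z <= 14 * sz)
        )
    labels[vent & (labels == 3)] = 1

    rng = np.random.default_rng(params.seed)
    intensity = np.empty(shape, dtype=np.float64)
    for lab, mean in CLASS_INTENSITY.items():
        intensity[labels == lab] = mean
    if params.noise_sd > 0:
        intensity += rng.normal(0.0, params.noise_sd, size=shape)

    vol = VolumeGrid(data=intensity, spacing=spacing, affine=affine)
    lab = LabelVolume(labels=labels, legend=dict(PHANTOM_LEGEND), spacing=spacing, affine=affine)
    return vol, lab


def brain_mask(lab: LabelVolume) -> np.ndarray:
    """All intracranial tissue classes (everything but background and skull)."""
    return (lab.labels > 0) & (lab.labels < 6)


def inner_skull_mask(lab: LabelVolume) -> np.ndarray:
    """Filled inner-skull cavity — the B-width reference for Evans' index."""
    return brain_mask(lab)


def make_parcellation(
    n_regions: int = 90,
    shape: tuple[int, int, int] = (64, 64, 32),
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0),
    seed: int = 0,
) -> LabelVolume:
    """Nearest-seed Voronoi parcellation of a brain-shaped mask.

    Emulates a 90-region anatomical atlas: labels 1..n_regions are all
    present and spatially contiguous (Voronoi cells over a convex mask).
    """
    if n_regions < 2:
        raise InvariantError("a parcellation needs at least 2 regions")
    affine, (x, y, z) = _world_grids(shape, spacing)
    half = np.asarray(shape) * np.asarray(spacing) / 2.0
    sx, sy, sz = half / _CANON_HALF
    mask = _ellipsoid(x, y, z, np.array([0, 0, 10 * sz]), np.array([44 * sx, 52 * sy, 30 * sz]))
    idx = np.argwhere(mask)
    if n_regions > idx.shape[0]:
        raise InvariantError(f"{n_regions} regions exceed {idx.shape[0]} brain voxels")
    rng = np.random.default_rng(seed)
    seeds = idx[rng.choice(idx.shape[0], size=n_regions, replace=False)]
    tree = cKDTree(seeds * np.asarray(spacing))
    _, owner = tree.query(idx * np.asarray(spacing))
    labels = np.zeros(shape, dtype=np.uint8 if n_regions < 256 else np.uint16)
    labels[tuple(idx.T)] = owner + 1
    legend = {i: f"region_{i:03d}" for i in range(1, n_regions + 1)}
    return LabelVolume(labels=labels, legend=legend, spacing=spacing, affine=affine)


def make_streamlines(parcellation: LabelVolume, n: int, seed: int = 0,
                     n_points: int = 33, jitter_mm: float = 6.0) -> StreamlineSet:
    """Smooth synthetic fibers whose endpoints sit inside labeled regions.

    Each fiber connects a uniformly drawn pair of distinct regions: the
    endpoints are voxel centres of the two regions, joined by a cubic
    spline through jittered waypoints.  No diffusion physics is modelled;
    downstream stages only need geometric polylines.
    """
    from scipy.interpolate import CubicSpline

    if n < 0:
        raise InvariantError("streamline count must be >= 0")
    labs = np.unique(parcellation.labels)
    labs = labs[labs > 0]
    if labs.size < 2:
        raise InvariantError("parcellation must contain at least 2 regions")
    if n == 0:
        return StreamlineSet(streamlines=[], space="mni")
    region_voxels = {int(l): np.argwhere(parcellation.labels == l) for l in labs}
    rng = np.random.default_rng(seed)
    t_way = np.linspace(0.0, 1.0, 5)
    t_out = np.linspace(0.0, 1.0, n_points)
    lines = []
    for _ in range(n):
        a, b = rng.choice(labs, size=2, replace=False)
        va = region_voxels[int(a)][rng.integers(len(region_voxels[int(a)]))]
        vb = region_voxels[int(b)][rng.integers(len(region_voxels[int(b)]))]
        p0 = parcellation.index_to_world(va)[0]
        p1 = parcellation.index_to_world(vb)[0]
        way = np.outer(1 - t_way, p0) + np.outer(t_way, p1)
        way[1:-1] += rng.normal(0.0, jitter_mm, size=(3, 3))
        spline = CubicSpline(t_way, way, axis=0)
        lines.append(spline(t_out))
    return StreamlineSet(streamlines=lines, space="mni")


def make_cohort(spec: CohortSpec) -> list[tuple[VolumeGrid, LabelVolume, str]]:
    """Generate n_normal + n_nph phantoms with diagnosis labels attached."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.generate_state(spec.n_normal + spec.n_nph) % (2**31)
    rng = np.random.default_rng(root.spawn(1)[0])
    out = []
    for i in range(spec.n_normal):
        p = PhantomParams(
            shape=spec.base.shape, spacing=spec.base.spacing, dilation=1.0,
            noise_sd=spec.base.noise_sd, seed=int(subject_seeds[i]),
            horn_halfwidth_mm=spec.base.horn_halfwidth_mm,
            inner_skull_halfwidth_mm=spec.base.inner_skull_halfwidth_mm,
        )
        vol, lab = make_phantom(p)
        out.append((vol, lab, "normal"))
    lo, hi = spec.dilation_range
    for i in range(spec.n_nph):
        p = PhantomParams(
            shape=spec.base.shape, spacing=spec.base.spacing,
            dilation=float(rng.uniform(lo, hi)),
            noise_sd=spec.base.noise_sd, seed=int(subject_seeds[spec.n_normal + i]),
            horn_halfwidth_mm=spec.base.horn_halfwidth_mm,
            inner_skull_halfwidth_mm=spec.base.inner_skull_halfwidth_mm,
        )
        vol, lab = make_phantom(p)
        out.append((vol, lab, "NPH"))
    return out
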
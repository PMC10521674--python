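"""In-memory containers shared by every pipeline stage.

Conventions
-----------
* Voxel indices are 0-based; ``affine`` maps homogeneous voxel indices
  (i, j, k, 1) to world coordinates in millimetres, RAS orientation.
* Axis order is (x, y, z) = (left-right, posterior-anterior,
  inferior-superior); an "axial slice" is a fixed z index.
* Label images reserve 0 for background; every nonzero label must be
  named in the legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvariantError, SingularTransformError

# softmax classes used by the segmentation network (skull collapses to 0)
SEG_CLASS_NAMES = (
    "background",
    "ventricle",
    "subarachnoid",
    "gray_white",
    "cereb_csf",
    "cereb_gray_white",
)
N_SEG_CLASSES = 6
SKULL_LABEL = 6

#: legend used by the synthetic phantoms (superset of the network classes)
PHANTOM_LEGEND = {
    1: "ventricle",
    2: "subarachnoid",
    3: "gray_white",
    4: "cereb_csf",
    5: "cereb_gray_white",
    6: "skull",
}


def _check_geometry(shape, spacing, affine):
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise InvariantError(f"data must be 3-D with positive dims, got shape {shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InvariantError(f"spacing must be 3 strictly positive values, got {spacing}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise InvariantError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise SingularTransformError("grid affine is singular")
    return spacing, affine


def default_affine(shape, spacing):
    """Diagonal RAS affine placing the grid centre at the world origin."""
    spacing = np.asarray(spacing, dtype=float)
    shape = np.asarray(shape)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -(shape - 1) / 2.0 * spacing
    return aff


@dataclass
class VolumeGrid:
    """3-D scalar image (CT intensities or a probability map) with geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvariantError(f"VolumeGrid data must be 3-D, got {self.data.ndim}-D")
        self.spacing, self.affine = _check_geometry(self.data.shape, self.spacing, self.affine)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world-mm points."""
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 3) world-mm points to fractional voxel indices."""
        pts = np.atleast_2d(pts)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)


@dataclass
class LabelVolume:
    """3-D integer label image sharing the VolumeGrid geometry contract."""

    labels: np.ndarray
    legend: dict[int, str]
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvariantError(f"LabelVolume labels must be 3-D, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvariantError("labels must be an integer array")
        if self.labels.min(initial=0) < 0:
            raise InvariantError("labels must be nonnegative (0 = background)")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.legend)
        if missing:
            raise InvariantError(f"labels {sorted(missing)} missing from legend")
        self.spacing, self.affine = _check_geometry(self.labels.shape, self.spacing, self.affine)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    index_to_world = VolumeGrid.index_to_world
    world_to_index = VolumeGrid.world_to_index
    same_grid_as = VolumeGrid.same_grid_as

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class AffineTransform:
    """4x4 world->world transform with a direction tag.

    ``direction`` is one of ``"subject_to_mni"`` / ``"mni_to_subject"``;
    the bottom row must be (0, 0, 0, 1).
    """

    matrix: np.ndarray
    direction: str = "subject_to_mni"

    _FLIP = {"subject_to_mni": "mni_to_subject", "mni_to_subject": "subject_to_mni"}

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise InvariantError(f"transform must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-8):
            raise InvariantError("bottom row of an affine transform must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise SingularTransformError("affine transform is singular")
        if self.direction not in self._FLIP:
            raise InvariantError(f"unknown direction tag {self.direction!r}")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclass
class StreamlineSet:
    """Ordered 3-D polylines in world mm with a coordinate-space tag."""

    streamlines: list[np.ndarray]
    space: str = "mni"

    def __post_init__(self):
        checked = []
        for i, line in enumerate(self.streamlines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InvariantError(f"streamline {i} must be (k, 3), got {arr.shape}")
            if arr.shape[0] < 2:
                raise InvariantError(f"streamline {i} has {arr.shape[0]} point(s); >=2 required")
            if not np.all(np.isfinite(arr)):
                raise InvariantError(f"streamline {i} contains non-finite coordinates")
            checked.append(arr)
        self.streamlines = checked

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class ProbabilityMapSet:
    """Spatial priors for the two hard CSF classes (ventricle, subarachnoid)."""

    ventricle: np.ndarray
    subarachnoid: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    space: str = "mni"

    def __post_init__(self):
        self.ventricle = np.asarray(self.ventricle, dtype=float)
        self.subarachnoid = np.asarray(self.subarachnoid, dtype=float)
        for name in ("ventricle", "subarachnoid"):
            arr = getattr(self, name)
            if arr.ndim != 3:
                raise InvariantError(f"{name} map must be 3-D")
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise InvariantError(f"{name} map values must lie in [0, 1]")
        if self.ventricle.shape != self.subarachnoid.shape:
            raise InvariantError("the two probability maps must share a grid")
        self.spacing, self.affine = _check_geometry(
            self.ventricle.shape, self.spacing, self.affine
        )

    @property
    def maps(self) -> np.ndarray:
        """(2, x, y, z) stacked maps — the network's prior input channels."""
        return np.stack([self.ventricle, self.subarachnoid])

    @property
    def shape(self):
        return self.ventricle.shape


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative region-by-region streamline-count matrix."""

    weights: np.ndarray
    region_labels: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape != (n, n):
            raise InvariantError("connectivity weights must be square")
        if not self.region_labels:
            self.region_labels = list(range(1, n + 1))
        if len(self.region_labels) != n:
            raise InvariantError("region_labels length must match matrix size")
        if not np.array_equal(self.weights, self.weights.T):
            raise InvariantError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise InvariantError("connectivity matrix must have a zero diagonal")
        if self.weights.min() < 0:
            raise InvariantError("connectivity weights must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]
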
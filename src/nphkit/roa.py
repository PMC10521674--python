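"""Region-of-Avoidance streamline filtering and connectome construction.

The predicted ventricle segmentation, carried to template space, acts as
a Region of Avoidance (ROA): any atlas streamline that passes through a
masked voxel is discarded, and the surviving fibers are tallied into a
region-by-region connectivity matrix (endpoint-pair counting, self
connections dropped).  Enlarged ventricles therefore knock out more
fibers, which is exactly the contrast the network coefficients pick up.
"""

from __future__ import annotations

import numpy as np

from .errors import InvariantError, SpaceMismatchError
from .types import ConnectivityMatrix, LabelVolume, StreamlineSet


def _densify(line: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (at most) ``step`` mm spacing, keeping vertices."""
    seg = np.diff(line, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    pieces = [line[:1]]
    for i, L in enumerate(lengths):
        n = max(int(np.ceil(L / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pieces.append(line[i] + t * seg[i])
    return np.concatenate(pieces, axis=0)


def _points_in_mask(points: np.ndarray, mask_vol: LabelVolume | None, mask: np.ndarray,
                    world_to_index) -> np.ndarray:
    idx = np.rint(world_to_index(points)).astype(int)
    shape = mask.shape
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    hit = np.zeros(len(points), dtype=bool)
    if inside.any():
        ii = idx[inside]
        hit[inside] = mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return hit


def filter_streamlines_roa(s: StreamlineSet, roa: LabelVolume, step: float | None = None,
                           roa_space: str = "mni") -> StreamlineSet:
    """Drop every streamline that touches the avoidance mask.

    A streamline is removed iff any densely resampled point along it
    (default step: half the minimum voxel spacing, vertices always
    included) falls in a mask-true voxel.  Survivors are returned
    unmodified and in order.
    """
    if s.space != roa_space:
        raise SpaceMismatchError(
            f"streamlines are in {s.space!r} but the ROA is in {roa_space!r}"
        )
    mask = roa.labels > 0
    if step is None:
        step = min(roa.spacing) / 2.0
    if step <= 0:
        raise InvariantError("sampling step must be positive")
    if not mask.any():
        return StreamlineSet(streamlines=list(s.streamlines), space=s.space)
    keep = []
    for line in s.streamlines:
        dense = _densify(line, step)
        if not _points_in_mask(dense, roa, mask, roa.world_to_index).any():
            keep.append(line)
    return StreamlineSet(streamlines=keep, space=s.space)


def endpoint_regions(line: np.ndarray, parcellation: LabelVolume):
    """Parcel labels at the first and last point; None if either is background.

    Points outside the grid are treated as background.
    """
    pts = np.asarray(line, dtype=float)[[0, -1]]
    idx = np.rint(parcellation.world_to_index(pts)).astype(int)
    labels = []
    for i in range(2):
        if np.any(idx[i] < 0) or np.any(idx[i] >= np.asarray(parcellation.shape)):
            return None
        lab = int(parcellation.labels[tuple(idx[i])])
        if lab == 0:
            return None
        labels.append(lab)
    return labels[0], labels[1]


def build_connectivity(s: StreamlineSet, parcellation: LabelVolume,
                       n_regions: int = 90) -> ConnectivityMatrix:
    """Endpoint-pair streamline counts as an n x n symmetric matrix.

    weight[i, j] counts streamlines with endpoint parcels {i, j}, i != j;
    fibers with a background endpoint or both endpoints in one parcel are
    excluded.
    """
    present = np.unique(parcellation.labels)
    if present.max(initial=0) > n_regions:
        raise InvariantError(
            f"parcellation label {present.max()} exceeds n_regions={n_regions}"
        )
    W = np.zeros((n_regions, n_regions), dtype=float)
    for line in s.streamlines:
        pair = endpoint_regions(line, parcellation)
        if pair is None:
            continue
        a, b = pair
        if a == b:
            continue
        W[a - 1, b - 1] += 1
        W[b - 1, a - 1] += 1
    return ConnectivityMatrix(weights=W, region_labels=list(range(1, n_regions + 1)))


def binarize(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """1 where any streamline connects the pair, else 0 (idempotent)."""
    return ConnectivityMatrix(
        weights=(m.weights > 0).astype(float),
        region_labels=list(m.region_labels),
    )
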
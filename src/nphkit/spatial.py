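"""Affine transforms, grid resampling, and spatial probability maps.

Registration estimation itself (FLIRT-style) is out of scope: transforms
arrive as 4x4 matrices and are only applied/inverted here.  Resampling is
done with scipy.ndimage (trilinear for intensities and probability maps,
nearest-neighbour for labels).  Out-of-field voxels fill with 0 for
labels/probabilities and -1000 (air) for CT intensities.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvariantError, SpaceMismatchError
from .types import AffineTransform, LabelVolume, ProbabilityMapSet, VolumeGrid


def invert_affine(t: AffineTransform) -> AffineTransform:
    """Inverse transform with the direction tag flipped."""
    return AffineTransform(matrix=np.linalg.inv(t.matrix), direction=t._FLIP[t.direction])


def compose(a: AffineTransform, b: AffineTransform) -> np.ndarray:
    return a.matrix @ b.matrix


def _resample_array(data, src_affine, t_matrix, target_affine, target_shape, order, cval):
    """Pull-back resampling: for each target voxel, look up the source voxel.

    ``t_matrix`` maps source-world -> target-world, so the voxel map is
    src_index = src_affine^-1 . t^-1 . target_affine . target_index.
    """
    M = np.linalg.inv(src_affine) @ np.linalg.inv(t_matrix) @ target_affine
    return ndimage.affine_transform(
        np.asarray(data, dtype=float),
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,  # order <= 1 needs no spline prefilter
    )


def resample_volume(v, t: AffineTransform, target_geometry, mode: str = "trilinear",
                    fill=None):
    """Resample a VolumeGrid or LabelVolume onto a target grid through ``t``.

    ``target_geometry`` is any object with ``shape``, ``spacing`` and
    ``affine`` attributes.  Labels must use ``mode="nearest"``; trilinear
    output stays within the input min/max and nearest mode only emits
    labels present in the input.
    """
    if mode not in ("nearest", "trilinear"):
        raise InvariantError(f"unknown interpolation mode {mode!r}")
    target_shape = tuple(target_geometry.shape)
    target_affine = np.asarray(target_geometry.affine, dtype=float)
    if isinstance(v, LabelVolume):
        if mode != "nearest":
            raise InvariantError("label volumes must be resampled with mode='nearest'")
        out = _resample_array(
            v.labels, v.affine, t.matrix, target_affine, target_shape,
            order=0, cval=0.0 if fill is None else fill,
        )
        return LabelVolume(
            labels=np.rint(out).astype(v.labels.dtype),
            legend=dict(v.legend),
            spacing=tuple(target_geometry.spacing),
            affine=target_affine,
        )
    out = _resample_array(
        v.data, v.affine, t.matrix, target_affine, target_shape,
        order=(0 if mode == "nearest" else 1),
        cval=-1000.0 if fill is None else fill,
    )
    return VolumeGrid(data=out, spacing=tuple(target_geometry.spacing), affine=target_affine)


def build_probability_maps(annotations: list[LabelVolume],
                           classes: tuple[int, int] = (1, 2),
                           space: str = "mni") -> ProbabilityMapSet:
    """Average registered ground-truth annotations into spatial priors.

    ``map_c(voxel) = (1/N) sum_i [annotation_i(voxel) == c]`` for the
    ventricle and subarachnoid classes; every annotation must share one
    grid (a common template space).
    """
    if not annotations:
        raise InvariantError("at least one annotation is required")
    ref = annotations[0]
    for i, ann in enumerate(annotations[1:], start=1):
        if not ref.same_grid_as(ann):
            raise InvariantError(f"annotation {i} is not on the reference grid")
    n = float(len(annotations))
    vent = sum((a.labels == classes[0]).astype(float) for a in annotations) / n
    sub = sum((a.labels == classes[1]).astype(float) for a in annotations) / n
    return ProbabilityMapSet(
        ventricle=vent, subarachnoid=sub,
        spacing=ref.spacing, affine=ref.affine, space=space,
    )


def probmaps_to_subject(p: ProbabilityMapSet, h: AffineTransform,
                        subject_geometry) -> ProbabilityMapSet:
    """Carry template-space priors into a patient's grid (trilinear)."""
    if p.space != "mni":
        raise SpaceMismatchError("probability maps must start in template (MNI) space")
    if h.direction != "mni_to_subject":
        raise SpaceMismatchError(
            f"need an mni_to_subject transform, got {h.direction!r}"
        )
    target_affine = np.asarray(subject_geometry.affine, dtype=float)
    maps = []
    for arr in (p.ventricle, p.subarachnoid):
        out = _resample_array(
            arr, p.affine, h.matrix, target_affine,
            tuple(subject_geometry.shape), order=1, cval=0.0,
        )
        maps.append(np.clip(out, 0.0, 1.0))
    return ProbabilityMapSet(
        ventricle=maps[0], subarachnoid=maps[1],
        spacing=tuple(subject_geometry.spacing), affine=target_affine,
        space="subject",
    )
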
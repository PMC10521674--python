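"""Readers and writers for every on-disk format the pipeline touches.

Formats: NIfTI-1 volumes (.nii/.nii.gz) via nibabel, TRK/TCK streamlines
via nibabel.streamlines, FLIRT-style plain-text 4x4 matrices, and CSV
feature tables via pandas.  All writes are atomic (temp file + rename) so
a failed write never leaves a partial output behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    CorruptHeaderError,
    DimensionalityError,
    InvariantError,
    MatrixFormatError,
    StreamlineFormatError,
)
from .types import AffineTransform, LabelVolume, StreamlineSet, VolumeGrid


def _atomic_path(path):
    """Yield a temp path in the target directory; caller renames on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes) or ".tmp")
    os.close(fd)
    return path, Path(tmp)


def _nifti_spacing(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path) -> VolumeGrid:
    """Read a 3-D NIfTI-1 scalar image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except (nib.filebasedimages.ImageFileError, OSError, ValueError) as exc:
        raise CorruptHeaderError(f"cannot read NIfTI image {path}: {exc}") from exc
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise DimensionalityError(f"{path} is {data.ndim}-D; a 3-D image is required")
    return VolumeGrid(data=data, spacing=_nifti_spacing(img), affine=img.affine)


def write_volume(vol: VolumeGrid, path) -> None:
    path, tmp = _atomic_path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, tmp)
    os.replace(tmp, path)


def read_labels(path, legend: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer label image; legend defaults to stringified labels."""
    vol = read_volume(path)
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded, atol=1e-6):
            raise InvariantError(f"{path} contains non-integer label values")
        labels = rounded.astype(np.uint8)
    if legend is None:
        legend = {int(v): str(int(v)) for v in np.unique(labels) if v != 0}
    return LabelVolume(labels=labels, legend=legend, spacing=vol.spacing, affine=vol.affine)


def write_labels(lab: LabelVolume, path) -> None:
    if lab.labels.max(initial=0) > 255:
        raise InvariantError("masks are stored as unsigned 8-bit; label > 255")
    path, tmp = _atomic_path(path)
    img = nib.Nifti1Image(lab.labels.astype(np.uint8), lab.affine)
    img.header.set_zooms(lab.spacing)
    nib.save(img, tmp)
    os.replace(tmp, path)


_TRACT_DIALECTS = {".trk", ".tck"}


def read_streamlines(path, space: str = "mni") -> StreamlineSet:
    """Read TRK or TCK streamlines (dialect chosen by extension), in world mm."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _TRACT_DIALECTS:
        raise StreamlineFormatError(f"unknown streamline extension {ext!r} (want .trk/.tck)")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises several types on truncation
        raise StreamlineFormatError(f"cannot read streamline file {path}: {exc}") from exc
    lines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return StreamlineSet(streamlines=lines, space=space)


def write_streamlines(sset: StreamlineSet, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _TRACT_DIALECTS:
        raise StreamlineFormatError(f"unknown streamline extension {ext!r} (want .trk/.tck)")
    # invariants re-checked so a hand-built list cannot bypass them
    StreamlineSet(streamlines=list(sset.streamlines), space=sset.space)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    path, tmp = _atomic_path(path)
    if ext == ".trk":
        nib.streamlines.save(tractogram, str(tmp), header=nib.streamlines.trk.TrkFile.create_empty_header())
    else:
        nib.streamlines.save(tractogram, str(tmp))
    os.replace(tmp, path)


def read_flirt_matrix(path, direction: str = "subject_to_mni") -> AffineTransform:
    """Parse a FLIRT-style whitespace-separated 4x4 plain-text matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for line in path.read_text().splitlines():
        if line.strip():
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise MatrixFormatError(f"non-numeric token in {path}: {line!r}") from exc
    mat = np.array(rows, dtype=float) if rows else np.empty((0, 0))
    if mat.shape != (4, 4):
        raise MatrixFormatError(f"{path} holds a {mat.shape} matrix; 4 rows x 4 cols required")
    if not np.allclose(mat[3], [0, 0, 0, 1], atol=1e-8):
        raise MatrixFormatError(f"bottom row of {path} is not (0,0,0,1)")
    return AffineTransform(matrix=mat, direction=direction)


def write_flirt_matrix(t: AffineTransform, path) -> None:
    path, tmp = _atomic_path(path)
    np.savetxt(tmp, t.matrix, fmt="%.10g")
    os.replace(tmp, path)


def write_feature_table(rows: list[dict], path, diagnosis_col: str = "diagnosis") -> None:
    """Write subject feature dicts (+ diagnosis) as a CSV with a fixed header.

    Every row must carry the same feature names; the diagnosis column is
    appended last.
    """
    if rows:
        names = [k for k in rows[0] if k != diagnosis_col]
        for i, row in enumerate(rows):
            if [k for k in row if k != diagnosis_col] != names:
                raise InvariantError(f"row {i} feature names differ from row 0")
        df = pd.DataFrame(rows, columns=names + ([diagnosis_col] if diagnosis_col in rows[0] else []))
    else:
        df = pd.DataFrame(columns=[diagnosis_col])
    path, tmp = _atomic_path(path)
    df.to_csv(tmp, index=False, float_format="%.12g")
    os.replace(tmp, path)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)
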
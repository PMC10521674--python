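"""End-to-end orchestration: phantoms -> segmentation -> ROA connectome ->
feature fusion -> NPH prediction.

The stages run in the order of the clinical pipeline: (1) obtain a CT
volume per subject, (2) build template-space probability maps from
training annotations and carry them into subject space, (3) segment,
(4) use the ventricle segmentation as a Region of Avoidance to filter
the atlas streamline set, (5) build the connectivity matrix and its
coefficients, (6) fuse volumetric and network features and score the
linear SVM.  Every artifact is written with provenance (config hash,
seeds, package versions); a rerun with the same config reproduces the
same feature tables bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .errors import ConfigError
from .evaluate import cross_validated_svm, fuse_features, volumetric_features
from .netmetrics import assemble_features
from .roa import build_connectivity, filter_streamlines_roa
from .segnet import UNetSegmenter3D
from .spatial import build_probability_maps, probmaps_to_subject
from .synthetic import CohortSpec, PhantomParams, make_cohort, make_parcellation, make_streamlines
from .types import AffineTransform, LabelVolume


@dataclass
class PipelineConfig:
    output_dir: str = "nphkit_run"
    seed: int = 0
    # cohort
    n_normal: int = 10
    n_nph: int = 10
    dilation_range: tuple[float, float] = (1.5, 1.9)
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    noise_sd: float = 5.0
    # connectome
    n_regions: int = 90
    n_streamlines: int = 2000
    n_null: int = 20
    feature_mode: str = "26"
    # segmentation: "groundtruth" uses the phantom labels (fast desk runs);
    # "unet" trains the probability-map UNet on the cohort
    segmentation_mode: str = "groundtruth"
    base_channels: int = 4
    epochs: int = 10
    dropout: float = 0.0
    loss_mode: str = "plain"
    # prediction
    folds: int = 5
    iterations: int = 20
    svm_C: float = 1.0

    def to_dict(self):
        return asdict(self)


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if any(int(s) % 16 != 0 or s <= 0 for s in cfg.shape):
        problems.append(f"shape: every axis must be a positive multiple of 16, got {cfg.shape}")
    if any(s <= 0 for s in cfg.spacing):
        problems.append(f"spacing: must be strictly positive, got {cfg.spacing}")
    if cfg.seed < 0:
        problems.append(f"seed: must be nonnegative, got {cfg.seed}")
    if cfg.n_normal < 0 or cfg.n_nph < 0:
        problems.append("n_normal/n_nph: cohort counts must be >= 0")
    lo, hi = cfg.dilation_range
    if not (1.0 < lo <= hi):
        problems.append(f"dilation_range: need 1 < lo <= hi, got {cfg.dilation_range}")
    if cfg.n_regions < 2:
        problems.append("n_regions: must be >= 2")
    if cfg.n_streamlines < 0:
        problems.append("n_streamlines: must be >= 0")
    if cfg.segmentation_mode not in ("groundtruth", "unet"):
        problems.append(f"segmentation_mode: unknown mode {cfg.segmentation_mode!r}")
    if cfg.epochs < 1:
        problems.append("epochs: must be >= 1")
    if cfg.folds < 2:
        problems.append("folds: must be >= 2")
    if cfg.iterations < 1:
        problems.append("iterations: must be >= 1")
    if cfg.feature_mode not in ("25", "26"):
        problems.append(f"feature_mode: must be '25' or '26', got {cfg.feature_mode!r}")
    return problems


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on a synthetic cohort; returns the manifest."""
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("; ".join(problems))
    out = Path(cfg.output_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "stages": {},
        "subjects": [],
    }

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}
        return name

    def done(name, **extra):
        manifest["stages"][name]["wall_s"] = time.time() - manifest["stages"][name].pop("t_start")
        manifest["stages"][name].update(extra)

    # 1. cohort ------------------------------------------------------
    s = stage("cohort")
    base = PhantomParams(shape=tuple(cfg.shape), spacing=tuple(cfg.spacing),
                         noise_sd=cfg.noise_sd, seed=int(seeds[0]))
    cohort = make_cohort(CohortSpec(
        n_normal=cfg.n_normal, n_nph=cfg.n_nph,
        dilation_range=tuple(cfg.dilation_range), base=base, seed=int(seeds[0]),
    ))
    subj = []
    for i, (vol, lab, dx) in enumerate(cohort):
        sid = f"sub-{i:03d}"
        nio.write_volume(vol, out / "subjects" / f"{sid}_ct.nii.gz")
        nio.write_labels(lab, out / "subjects" / f"{sid}_labels.nii.gz")
        subj.append({"id": sid, "diagnosis": dx})
        manifest["subjects"].append({"id": sid, "diagnosis": dx})
    done(s, n_subjects=len(cohort))

    # 2. probability maps (identity template<->subject registration on
    #    the shared synthetic grid) -----------------------------------
    s = stage("probability_maps")
    identity = AffineTransform(np.eye(4), direction="mni_to_subject")
    pmaps_mni = build_probability_maps([lab for _, lab, _ in cohort]) if cohort else None
    done(s)

    # 3. segmentation -------------------------------------------------
    s = stage("segmentation")
    if cfg.segmentation_mode == "groundtruth":
        segs = [lab for _, lab, _ in cohort]
    else:
        pm_subject = [
            probmaps_to_subject(pmaps_mni, identity, vol) for vol, _, _ in cohort
        ]
        est = UNetSegmenter3D(
            base_channels=cfg.base_channels, epochs=cfg.epochs,
            dropout=cfg.dropout, loss_mode=cfg.loss_mode, seed=int(seeds[1]),
        )
        est.fit([v for v, _, _ in cohort], [l for _, l, _ in cohort], pm_subject)
        segs = est.predict([v for v, _, _ in cohort], pm_subject)
    for rec, seg in zip(subj, segs):
        nio.write_labels(seg, out / "subjects" / f"{rec['id']}_seg.nii.gz")
    done(s, mode=cfg.segmentation_mode)

    # 4+5. ROA filtering and connectomes ------------------------------
    s = stage("connectome")
    parc = make_parcellation(cfg.n_regions, shape=tuple(cfg.shape),
                             spacing=tuple(cfg.spacing), seed=int(seeds[2]))
    atlas = make_streamlines(parc, cfg.n_streamlines, seed=int(seeds[3]))
    rows = []
    for rec, seg in zip(subj, segs):
        roa_mask = seg.labels == 1  # predicted ventricles
        roa = LabelVolume(labels=roa_mask.astype(np.uint8), legend={1: "roa"},
                          spacing=seg.spacing, affine=seg.affine)
        kept = filter_streamlines_roa(atlas, roa)
        nio.write_streamlines(kept, out / "subjects" / f"{rec['id']}_filtered.trk")
        conn = build_connectivity(kept, parc, n_regions=cfg.n_regions)
        np.savetxt(out / "subjects" / f"{rec['id']}_connectivity.csv",
                   conn.weights, delimiter=",", fmt="%.10g")
        net = assemble_features(conn, n_null=cfg.n_null, seed=int(seeds[4]),
                                feature_mode=cfg.feature_mode)
        vol_feats = volumetric_features(seg)
        row = dict(zip(
            list(vol_feats) + list(net.names),
            fuse_features(vol_feats, net, mode="fused"),
        ))
        row["diagnosis"] = rec["diagnosis"]
        rows.append(row)
    nio.write_feature_table(rows, out / "features.csv")
    done(s, n_streamlines_atlas=len(atlas))

    # 6. prediction ---------------------------------------------------
    s = stage("prediction")
    labels = np.array([r["diagnosis"] for r in rows])
    X = np.array([[r[k] for k in rows[0] if k != "diagnosis"] for r in rows])
    counts = {dx: int((labels == dx).sum()) for dx in set(labels)}
    if len(counts) == 2 and min(counts.values()) >= cfg.folds:
        report = cross_validated_svm(
            X, labels, folds=cfg.folds, iterations=cfg.iterations,
            seed=int(seeds[5]), C=cfg.svm_C, positive="NPH",
        ).as_dict()
    else:
        report = {"note": "prediction skipped: need both diagnosis classes "
                          "with at least `folds` subjects each"}
    (out / "prediction.json").write_text(json.dumps(report, indent=2))
    done(s)

    for rec in manifest["subjects"]:
        for suffix in ("_ct.nii.gz", "_labels.nii.gz", "_seg.nii.gz",
                       "_connectivity.csv"):
            p = out / "subjects" / f"{rec['id']}{suffix}"
            rec[suffix.lstrip("_").split(".")[0]] = _file_hash(p)
    manifest["features_hash"] = _file_hash(out / "features.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import nibabel
    import scipy
    import sklearn

    from . import __version__

    return {
        "nphkit": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
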
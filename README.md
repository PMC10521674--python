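# nphkit

Automated screening of **normal pressure hydrocephalus (NPH)** from CT
brain volumes.  NPH is one of the few reversible causes of
dementia-like decline in the elderly: cerebrospinal fluid accumulates in
the lateral ventricles at normal pressure, the ventricles enlarge, and a
shunt can restore function — if the condition is recognised.  The
classic radiographic proxy, Evans' index (the ratio A/B of the widest
frontal-horn span to the widest inner-skull span on an axial slice, with
A/B ≥ 0.3 read as ventricular enlargement), is a single-slice
measurement and notoriously level-dependent.

`nphkit` implements a volumetric alternative for researchers working on
CT-based screening:

1. **Segmentation** — a probability-map-augmented 3-D UNet labels the
   volume into six classes (background, lateral ventricles, subarachnoid
   space, gray-white matter, cerebellar CSF, cerebellar gray-white).
   Spatial priors for the two CSF classes — voxelwise averages of
   registered training annotations — enter through a dedicated branch,
   which is what lets the network separate two tissues with nearly
   identical CT intensity.  The network (and its training loop) is pure
   numpy with an in-repo reverse-mode autodiff, so the package has no
   deep-learning framework dependency.
2. **Region-of-avoidance connectomics** — the ventricle segmentation,
   carried to template space, disqualifies every atlas streamline that
   passes through it ("ROA" filtering); survivors are tallied into a
   90×90 region-by-region connectivity matrix by endpoint-pair counting.
   Enlarged ventricles knock out more fibers, so connectome structure
   encodes the deformation.
3. **Network coefficients** — density, clustering, transitivity,
   characteristic path length L (and small-worldness L/⟨L_rand⟩ against
   size-matched G(n, m) nulls), global efficiency, diameter, radius,
   assortativity, and rich-club φ(k) for k ∈ {5, 10, 15, 20}, each in a
   binary and a weighted variant — 26 features.
4. **Prediction** — 4 volumetric + 26 network features, standardised and
   fed to a linear SVM (L2 penalty), scored by repeated stratified
   5-fold cross-validation with precision/recall in percent.

A synthetic phantom generator (nested-ellipsoid heads with explicit
frontal horns and a tunable ventricle dilation factor) stands in for
patient data, so the whole pipeline builds and tests offline.

## Worked example

```python
import numpy as np
from nphkit import (PhantomParams, make_phantom, evans_index, classify_evans,
                    make_parcellation, make_streamlines, filter_streamlines_roa,
                    build_connectivity, assemble_features, LabelVolume)
from nphkit.evaluate import volumetric_features
from nphkit.synthetic import inner_skull_mask

# a hydrocephalic phantom: ventricles dilated 1.8x
vol, lab = make_phantom(PhantomParams(dilation=1.8, seed=0))
vf = volumetric_features(lab)
e = evans_index(lab.labels == 1, inner_skull_mask(lab), lab.spacing)
print(f"ventricle volume: {vf['ventricle_ml']:.1f} mL (total {vf['total_ml']:.1f} mL)")
print(f"Evans' index: A={e.A:.0f} mm, B={e.B:.0f} mm, A/B={e.index:.3f} -> {classify_evans(e)}")

# ROA connectome against a 2000-fiber synthetic atlas
parc = make_parcellation(90, seed=1)
atlas = make_streamlines(parc, 2000, seed=2)
roa = LabelVolume(labels=(lab.labels == 1).astype(np.uint8), legend={1: "roa"},
                  spacing=lab.spacing, affine=lab.affine)
kept = filter_streamlines_roa(atlas, roa)
conn = build_connectivity(kept, parc, n_regions=90)
net = assemble_features(conn, seed=3)
print(f"streamlines surviving the ROA: {len(kept)}/{len(atlas)}")
print(f"connectome density (binary): {net.values['density_binary']:.3f}, "
      f"char. path length: {net.values['char_path_binary']:.2f}")
```

Output:

```
ventricle volume: 55.9 mL (total 558.3 mL)
Evans' index: A=54 mm, B=98 mm, A/B=0.551 -> NPH
streamlines surviving the ROA: 409/2000
connectome density (binary): 0.093, char. path length: 2.40
```

The dilated phantom's frontal horns span 54 mm against a 98 mm inner
skull (index 0.551, well past the 0.3 rule), and its enlarged ventricles
eliminate 80 % of the atlas fibers — the volumetric and network signals
the SVM fuses.  A normal phantom (`dilation=1.0`) measures A = 30 mm and
index 0.306 by construction.

The same stages are available from the shell:

```sh
nphkit synth --out cohort --n-normal 10 --n-nph 10 --seed 0
nphkit train-seg --cohort-dir cohort --out model.npz --epochs 50
nphkit connectome --streamlines cohort/atlas.trk --roa vent.nii.gz \
    --parcellation cohort/parcellation.nii.gz --out-matrix conn.csv
nphkit netfeatures --matrix conn.csv --out net.csv
nphkit predict --features run/features.csv --out report.json
nphkit run-all --out run --seed 0       # full pipeline + manifest
```

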
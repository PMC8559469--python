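# geodeface

Geometry-preserving deidentification of anatomical MRI.

Sharing T1-weighted head MRIs risks re-identifying the subject: the face
and ears survive in any 3D rendering of the volume. Cropping or blurring
the face removes that risk but also distorts exactly the geometry that
downstream analyses need — skull stripping, and above all the nested
boundary-element (BEM) surfaces (brain, inner skull, outer skull, skin)
that EEG/MEG source modeling is built on. `geodeface` removes facial and
ear features while leaving those surfaces, and every voxel of the brain,
bit-for-bit intact.

## Method

The pipeline has three stages:

1. **Surfaces.** A marker-based watershed on the gradient-magnitude image
   separates head from background; intensity-band classification inside
   the head recovers the dark skull band, the CSF gap and the bright
   brain. Marching cubes plus Taubin smoothing turn the four nested
   compartment masks into watertight triangulated surfaces — the same
   surfaces a BEM forward model would use.
2. **Landmarks.** Face and ear control points (each a labeled position
   with an influence radius, in mm) come either from a file (3D Slicer
   FCSV or JSON) or automatically, by registering the subject to a
   template volume on which the points were marked once
   (multi-resolution affine on a correlation metric, optional
   diffeomorphic-demons refinement, via SimpleITK). Every point is then
   projected onto the subject's skin surface, so registration error only
   moves points along the skin, never off it.
3. **Masking.** The subject-specific mask is the intersection of the
   control-point balls with the skull-to-skin shell — the scalp between
   the outer-skull and skin surfaces. Voxels in the mask are replaced by
   i.i.d. draws from the empirical intensity distribution of the whole
   shell; voxels strictly outside the skin surface are set to zero;
   everything else is untouched. For voxel value v, mask M, exterior E:

       v'(x) = F̂⁻¹(u(x))  if x ∈ M        (F̂ = empirical shell CDF)
       v'(x) = 0           if x ∈ E
       v'(x) = v(x)        otherwise

Because the fill reproduces the shell's own distribution and the skin
boundary never moves, re-running surface extraction on the output
recovers the original head geometry; identity-bearing fine structure in
the masked region is gone.

The package also ships the evaluation battery used to quantify this:
Jaccard overlap of skull-stripped brain masks, symmetric Hausdorff
distance between surfaces (dense sampling, exact point-to-triangle
distances), an automated usability screen for reconstructed surfaces, and
"blank-face" / "blur-face" degradation surrogates that emulate
face-removal and face-blurring tools as comparison points. A synthetic
layered head phantom (nested ellipsoids with nose and ears, analytic
ground-truth surfaces, landmarks and labels) makes everything testable
without patient data.

## Worked example

```python
import numpy as np
from geodeface import (PhantomSpec, make_phantom, anonymize,
                       segment_head, jaccard)
from geodeface.metrics import compare_pair

v, truth = make_phantom(PhantomSpec(seed=1))          # 128³ @ 1.5 mm
out, report = anonymize(v, truth.landmarks, seed=7)

brain = truth.mask("brain")
print("brain voxels altered:", int(np.sum(out.data[brain] != v.data[brain])))
print("active (refilled) voxels:", report.counts["active_voxels"])

rep = compare_pair(v, out)
print("brain-mask Jaccard:", rep.jaccard)
print("skin Hausdorff (mm):",
      round(rep.hausdorff_per_surface["skin"]["symmetric"], 2))
```

prints

```
brain voxels altered: 0
active (refilled) voxels: 25470
brain-mask Jaccard: 1.0
skin Hausdorff (mm): 0.97
```

i.e. the nose and ears (~25k voxels of scalp shell) were replaced with
distribution-matched noise, the brain is bitwise unchanged, skull
stripping the anonymized volume reproduces the original brain mask
exactly, and the re-extracted skin surface sits within one voxel of the
original. For comparison, the blank-face surrogate on the same phantom
yields a skin Hausdorff distance of ~22 mm.

Command-line equivalents:

```bash
geodeface phantom --out work/ --seed 1
geodeface anonymize --in work/phantom.nii.gz --out work/anon.nii.gz \
    --points work/landmarks.json --seed 7 --qa-dir work/qa
geodeface evaluate --original work/phantom.nii.gz \
    --deidentified work/anon.nii.gz --out work/report.json
```

`geodeface batch --manifest subjects.tsv --template TPL_DIR` processes a
TSV manifest row by row (failures are isolated and summarized), and
`geodeface make-template` builds a reusable template bundle from any
volume plus a marked point file.

## Scope

`geodeface` operates on the image data only. Output NIfTI headers are
regenerated from the volume geometry and carry no descriptive or
extension fields, but scrubbing metadata in *other* files (DICOM series,
sidecars) is out of scope, as are behavioral identification experiments
and source-localization analyses. See `docs/methods.md` for the model,
parameter defaults and known limitations.
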
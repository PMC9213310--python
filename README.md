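# bonesct

Synthetic CT (sCT) from dual-echo gradient-echo MRI for metastatic bone.

Treating painful bone metastases with MRI-guided focused ultrasound (or
planning radiotherapy from MRI alone) needs CT-like information —
Hounsfield units, cortical bone geometry — without a registered CT scan.
`bonesct` implements that feasibility analysis end to end as a tested,
reproducible pipeline for researchers in MR-only treatment planning:

1. **phantom** — simulates paired 3D dual-echo spoiled gradient-echo MR
   (TE 2.1/4.2 ms, TR 7 ms, flip 10°, 1×1×2 mm voxels at 1.5 T) and CT
   volumes of a stylized bone with osteolytic / osteoblastic / mixed
   lesions, plus ground-truth bone and lesion masks — so every stage is
   testable without any clinical data;
2. **registration** — rigid initialization of CT-to-MR alignment by
   iterative closest point (ICP) on bone surfaces, Kabsch SVD fits,
   cubic B-spline resampling;
3. **preprocess** — per-volume 95th-percentile MR clipping and affine
   mapping to [−1, 1]; exact CT mapping from [−1024, 3071] HU; paired
   24³ patch extraction; flip/rotation augmentation;
4. **model** — a patch-based 3D UNet-like network (two echo channels in,
   CT out) trained with an L1 loss and Adam under leave-one-out
   cross-validation (LOOCV), one model per held-out case; implemented
   directly in numpy with gradient-checked backprop;
5. **evaluate** — the clinical metric suite: mean absolute difference
   (MAD) and mean difference (MD, sCT−CT) in HU; bone extracted at a
   150-HU threshold within the bone/lesion masks; Dice similarity
   coefficient (DSC); directed sCT-to-CT root-mean-square surface
   distance (RMSD) with a 3-cm lesion margin; cohort mean ± SD tables.

The core quantities, per region mask M and extracted bone sets
A = {sCT ≥ 150 HU} ∩ M, B = {CT ≥ 150 HU} ∩ M:

- MAD = mean over M of |sCT − CT|, MD = mean over M of (sCT − CT)
- DSC = 2|A∩B| / (|A| + |B|)
- RMSD = RMS over boundary voxels a of A of min over boundary b of B of ‖a − b‖ (mm)

## Worked example

The summarization/reporting layer can be driven from the shipped
nine-patient clinical reference values (per-case MAD/MD/DSC/RMSD for the
bone containing the lesion and for the lesion itself):

```
$ bonesct summarize --reports clinical
Region: bone
case          MAD (HU)     MD (HU)       DSC (1)     RMSD (mm)
P1                 102          34          0.81          2.70
P2                 146          23          0.86          2.54
...
P9                  95           7          0.85          2.65
mean ± SD     116 ± 26     14 ± 66   0.85 ± 0.05   2.05 ± 0.48

Region: lesion
case          MAD (HU)     MD (HU)       DSC (1)     RMSD (mm)
P1                  94         -64          0.56          4.93
...
P9                 149        -123          0.49          7.30
mean ± SD     132 ± 62   -31 ± 106   0.75 ± 0.18   2.91 ± 2.14
```

Reading the footer: across the nine cases the sCT differs from CT by
116 ± 26 HU on average inside the bone mask, the 150-HU bone extractions
overlap with Dice 0.85, and their surfaces sit 2.05 mm apart in the RMS
sense; the lesion region is harder (MAD 132 HU, DSC 0.75), and the
negative lesion MD (−31 HU) says lesion intensities are on average
underestimated.

A full synthetic experiment — simulate nine phantoms, run LOOCV training
and inference, evaluate and summarize — is one call (takes on the order
of fifteen minutes on a single CPU core at the desk-scale defaults):

```
$ bonesct run-all --seed 3 --out scratch/run
```

or, from Python:

```python
from bonesct import PipelineConfig, run_pipeline
summary, cv = run_pipeline(PipelineConfig(seed=3, out_dir="scratch/run"))
```

which writes 18 per-case metric reports (9 cases × bone/lesion),
`summary.json`, and a provenance sidecar. Individual stages are exposed
as `bonesct simulate / register / evaluate / summarize`.

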
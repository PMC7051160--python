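# tagstrain

Fully automated myocardial strain estimation from short-axis **tagged**
cardiac MR cines.

MRI tissue tagging (SPAMM) imprints a dark grid on the myocardium at the R
wave; the grid deforms with the tissue, making intramural motion visible.
Quantifying that motion normally requires minutes of manual interaction per
slice. `tagstrain` implements a zero-touch pipeline aimed at high-throughput
population imaging:

1. **ROI localization** — a convolutional regressor predicts the bounding box
   of the left-ventricular myocardium on the end-diastolic (ED) frame,
   enlarged by 60% for spatial context;
2. **crop + resample** — every frame is cropped with the ED box and resampled
   to 128 × 128 (bicubic);
3. **landmark tracking** — a shared-weight per-frame CNN feeds an LSTM that
   regresses 168 anatomic landmarks (7 transmural rings × 24 spokes, spoke 1
   anchored at the septal midpoint between the RV insertion points) for all
   20 frames;
4. **strain** — radial and circumferential Green (Lagrangian) strain curves
   are computed from the landmark motion and averaged over the slice.

The Green strain of a segment with reference length L₀ and current length
L_t is

    ε = ((L_t / L₀)² − 1) / 2 .

Radial strain ε_R uses the ring-1↔ring-7 separation along each of the 24
spokes; circumferential strain ε_C uses the 24 closed-loop chords of a ring,
with the midwall ring (ring 4) reported as the slice value and rings 2/4/6
giving subendocardial / midwall / subepicardial layers. End systole (ES) is
the frame of most negative midwall ε_C.

The tracker is trained with a composite loss: per-frame landmark position
MSE plus ω times the squared errors of the slice-averaged ε_R and midwall
ε_C (ω = 5 by default).

Because real tagged acquisitions are not redistributable, the package ships a
**synthetic phantom**: an incompressible annulus (r(R,t) = √(R² − a(t)))
with rigid twist, rendered as a grid-SPAMM cine with tag fading and noise.
The deformation has closed-form strains, so every stage is trainable and
testable against exact ground truth at desk scale.

## Worked example

```bash
tagstrain simulate --n 60 --out scratch/data --seed 0
tagstrain train-localizer --data scratch/data --out scratch/loc.npz --epochs 30
tagstrain train-tracker   --data scratch/data --out scratch/trk.npz \
    --epochs 60 --lr 1e-3 --omega 5
tagstrain predict --inputs scratch/data/case_0000/cine.nii.gz \
    --localizer scratch/loc.npz --tracker scratch/trk.npz --out scratch/out
```

The predict step prints one JSON log line per case and, because the phantom
directory contains ground-truth `landmarks.csv`, an agreement summary such as

```
processed 1 case(s) -> scratch/out
ES eps_C bias -0.0021, precision 0.0049
```

meaning the predicted end-systolic midwall circumferential strain differed
from truth by −0.002 on average with a standard deviation of 0.005 (both
dimensionless strain units). Each case directory receives `landmarks.csv`
(frame/ring/spoke, mm), `strains.csv` (20 rows: ε_R, ε_C and the three layer
strains per frame), `bbox.json` and `summary.json` (ES frame, ES strains,
stage timings, QC flags).

In a desk-scale study (200 phantoms, 72/18/10 train/val/test split, reduced
network widths) run by the test suite, the localizer reaches a mean held-out
IoU above 0.9 and the tracker recovers held-out ES midwall circumferential
strain with |bias| < 0.01 and precision ≈ 0.005–0.03 depending on seed.

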
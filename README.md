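# wbreg — step-wise whole-body CT registration and voxel-wise analysis

`wbreg` registers whole-body CT scans (mid-thigh to skull base, arms up)
between subjects and within subjects over time, so that cohort image
features can be summarized and visualized voxel by voxel: spatial tumor
distribution maps and therapy-related tissue-loss maps in a common
template space.

Whole-body images are hard to register: bodies differ drastically in fat
mass, pose and field of view, and a single similarity metric gets trapped
in local minima.  The method implemented here aligns images step by step,
combining low-level features (the CT intensities in Hounsfield units)
with high-level features (tissue masks thresholded from the CT):

1. piece-wise affine alignment of the skeleton (torso, then right arm,
   head, left arm, chest, pelvis; Gaussian-blended into a smooth field),
2. deformable bone alignment (CT via Pearson correlation *M2* + bone
   mask via sum of squared differences *M1*), after which bone is locked,
3. first soft-tissue step (CT + inside-SAT + adipose masks), locking the
   inner boundary of the subcutaneous fat,
4. second soft-tissue step (CT + lean + adipose masks), locking
   non-adipose tissue except the skin,
5. a final step on the body mask that completes subcutaneous fat.

The deformable steps minimize a multi-channel energy with tissue-specific
regularization (stiff bone, elastic fat) by graph-cut move-making over a
multi-resolution pyramid (levels 4 → 2).  Registration quality is scored
by inverse consistency over the body region Ω:

    VME = (1/|Ω|) Σ_{x∈Ω} ‖x − (T_ji ∘ T_ij)(x)‖      [mm]
    IME = (1/|Ω|) Σ_{x∈Ω} |I_i(x) − I_i((T_ji∘T_ij)(x))|  [HU]

plus composite-transform Dice on adipose/lean masks and the percentage of
body voxels with negative Jacobian determinant (folding).

Everything is validated end-to-end on synthetic whole-body phantoms with
exact ground truth (analytic deformation fields, landmarks, class maps)
— see `docs/methods.md` for the model, the phantom design and the
numerical choices.

## Worked example

```python
from wbreg.phantom import between_cohort_specs, make_between_pair
from wbreg.pipeline import register_pair
from wbreg.metrics import evaluate_pair

spec_a, spec_b = between_cohort_specs(5, seed=1)[0]
truth = make_between_pair(spec_a, spec_b)          # exact ground truth

fwd, _ = register_pair(truth.image_a, truth.masks_a,
                       truth.image_b, truth.masks_b)
rev, _ = register_pair(truth.image_b, truth.masks_b,
                       truth.image_a, truth.masks_a)
report = evaluate_pair(truth.image_a, truth.image_b,
                       truth.masks_a, truth.masks_b, fwd, rev)
print({k: round(v, 2) for k, v in report.as_dict().items()})
print("landmark error %.2f -> %.2f mm"
      % (truth.landmark_error_mm(), truth.landmark_error_mm(fwd)))
```

Output (about one minute on one CPU core):

```
{'vme_mm': 1.97, 'ime_hu': 44.47, 'dice_adipose': 0.91, 'dice_lean': 0.96, 'folding_pct': 0.0}
landmark error 4.91 -> 1.95 mm
```

The two phantoms differ by 4 mm of subcutaneous fat thickness, torso
radius, skeletal pose (up to 8 mm / 5°) and a lean contrast offset;
after the five-step pipeline the forward/reverse transforms disagree by
under 2 mm on average over the body (VME), round-trip intensity error is
~44 HU (IME — dominated by tissue-boundary voxels), tissue overlap after
a full round trip stays above Dice 0.9, the transform has no folding,
and the known landmark correspondence error drops by more than half.

A command-line interface mirrors the library
(`wbreg phantom|preprocess|register|evaluate|apps`), e.g.:

    wbreg --seed 1 phantom pair --mode between --out pair/
    wbreg register --source pair/b.nii.gz --target pair/a.nii.gz --out fwd.nii.gz
    wbreg evaluate --forward fwd.nii.gz --reverse rev.nii.gz \
                   --body masks/body.nii.gz --image pair/a.nii.gz

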
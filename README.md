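# facesym

Facial-asymmetry analysis with dense surface models: per-subject
signature asymmetry indices (SAI) from 3D face meshes, detection of
asymmetry-encoding shape modes, brain asymmetry indices (BASI) from
regional MRI measures, cohort statistics, and a repeated cross-validated
LASSO protocol linking the two — exercised end to end on a synthetic
data generator with planted effects.

## The science

Faces of people with focal epilepsies associated with unilateral brain
lesions have been reported to be measurably more asymmetric than the
faces of healthy controls or of people with generalized epilepsies.
Quantifying that effect requires:

1. **Dense correspondence.** Every face mesh is re-expressed as an
   ordered list of M points index-aligned with a base mesh (thin-plate
   spline warp anchored at 22 anthropometric landmarks, followed by
   closest-point projection onto the target surface), so that point *i*
   denotes the same anatomical location on every face.
2. **Dense surface model (DSM).** PCA over the corresponded faces *and
   their mirrored forms*, retaining the modes that carry 99% of shape
   variance. Including mirrors makes the model able to represent both a
   face and its reflection.
3. **Raw asymmetry.** For each subject, the per-point difference between
   the retained-mode representations of the original face and of its
   mirrored (reflected and landmark-relabelled) form. A perfectly
   symmetric face yields the zero field.
4. **Signature asymmetry index (SAI).** The raw asymmetry field is
   z-scored point-by-point against the raw asymmetries of the subject's
   age- and gender-matched controls; the signature weight is
   √ΣΣz², and the SAI is its natural log (approximately normal, so
   standard t-tests/ANOVA/OLS apply).
5. **Asymmetry-encoding modes.** A shape mode that captures a common
   asymmetry correlates strongly *negatively* between the scores of
   original faces and of their reflections; a league table of those
   correlations identifies the asymmetry modes.
6. **Brain asymmetry (BASI).** Regional left/right MRI measures
   (cortical thickness, subcortical and hippocampal-subfield volumes)
   are adjusted for ICV, age, sex and scanner; QC flags cells with
   |z| ≥ 4.7; BASI = (L − R)/((L + R)/2) per region.
7. **Repeated LASSO.** SAI is predicted from the 51 BASI features over
   repeated 80/20 splits with 10-fold cross-validated selection of the
   L1 penalty (grid 2⁻¹⁶…2⁻⁴), reporting held-out Spearman rho, MSE,
   and per-feature selection frequencies.

Because no clinical data ship with this package, a synthetic generator
(`facesym.simulate`) builds landmarked symmetric face templates, plants
symmetric and antisymmetric shape modes with configurable group
amplitudes, and emulates regional brain tables with configurable planted
correlations. All statistical claims in the test suite are made against
those planted truths.

## Worked example

`examples/simulate_and_sai.py` simulates 93 faces (40 controls, 25 FS,
20 FC, 8 IGE) with a 1.5 mm planted asymmetry amplitude in the FS group
and computes the SAI:

```
simulated 93 faces at 1000 points; groups: {'CTRL': 40, 'FS': 25, 'FC': 20, 'IGE': 8}
shape model retained 5 of 185 modes (99% variance)

SAI by group (natural-log signature weight of the raw asymmetry):
        mean    std  count
group
CTRL   3.875  0.567     40
FC     3.481  0.481     20
FS     5.191  0.597     25
IGE    3.994  0.624      8

pairwise Welch t-tests (Bonferroni-corrected) and one-way ANOVA:
  CTRL vs FS           stat=  -8.820 p=1.07e-11 corrected=6.42e-11
  ...
  ANOVA                stat= +41.318 p=8.04e-17

multivariate regression SAI ~ age + gender + epilepsy type:
               coef      se        t       p  ci_low  ci_high
const        3.8489  0.2205  17.4539  0.0000  3.4106   4.2872
age         -0.0001  0.0040  -0.0317  0.9748 -0.0080   0.0078
gender_male  0.0612  0.1217   0.5028  0.6164 -0.1807   0.3030
FC          -0.3920  0.1571  -2.4942  0.0145 -0.7043  -0.0796
FS           1.3238  0.1460   9.0675  0.0000  1.0336   1.6140
IGE          0.0985  0.2249   0.4378  0.6626 -0.3485   0.5454
n=93, R²=0.583
```

The planted FS effect is recovered as a strongly significant positive FS
coefficient; the unplanted age and gender terms hover near zero. The
other examples show the asymmetry-mode league table
(`examples/asymmetry_pcs.py` — the two planted antisymmetric modes are
flagged at r ≈ −0.99999 while the symmetric modes sit at r ≈ +0.99999)
and the brain arm (`examples/brain_basi_lasso.py` — BASI matrix, QC, the
planted duration → thickness-asymmetry correlation, and the repeated
LASSO).

## Command-line pipeline

The same study runs as a chain of thin CLI subcommands over plain
CSV/JSON/NPZ artifacts:

```bash
facesym simulate   --out study/ --seed 42
facesym correspond --base study/template.ply --base-landmarks study/template_landmarks.txt \
                   --faces study/faces --out study/corresponded.npz
facesym build-dsm  --input study/corresponded.npz --out study/model.npz
facesym sai        --input study/corresponded.npz --model study/model.npz \
                   --cohort study/cohort.csv --out study/sai.csv
facesym basi       --measures study/brain_measures.csv \
                   --covariates study/brain_covariates.csv --out-dir study/basi
facesym lasso      --basi study/basi/basi.csv --sai study/sai.csv \
                   --reps 1000 --out study/lasso.json
```

`facesym asym-pcs`, `facesym stats` and `facesym reflect` cover the
league table, group statistics and standalone mirroring. The default
simulated cohort (194 subjects) runs through the whole chain in about a
minute on one CPU.

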
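# painsig

Pain is not a readout of nociceptive input: trial-by-trial pain reports
vary widely even at fixed stimulus intensity, and psychological
manipulations (expectancy cues, perceived control) shift them. `painsig`
derives a **stimulus-intensity-independent pain signature** — a voxel
weight map `w` whose dot product `w·x` with a trial activation map `x`
predicts pain *after* removing stimulus-intensity and nociceptive-signature
effects — and provides the inference machinery to quantify what it explains
and mediates. It is aimed at researchers working with trial-level (beta
series) fMRI activation maps and at methodologists who want a tested,
synthetic-data-backed reference implementation of the full pipeline.

## The method

For each subject with trial maps `X` (trials × voxels) and ratings `y`:

1. residualize `y` and every voxel on
   `[1 | intensity-level indicators | reference (nociceptive) signature response]`;
2. fit a principal component regression decoder on the residuals
   (all nonzero components by default = minimum-norm least squares), with a
   10-fold cross-validated prediction–outcome correlation `cv_r` as the
   subject's precision;
3. aggregate: normalize each subject map by the s.d. of its weights, average
   with weights `max(cv_r, 0)`, run voxel-wise weighted one-sample t-tests,
   threshold at FDR q < 0.05, and extract signed contiguous regions.

Group inference is two-level throughout: OLS within subject; Empirical
Bayes weighting `1/(v_i + τ²)` across subjects; bootstrap (subjects, with
replacement) for coefficients and paths; within-subject permutation for
unique-R² terms. Mediation decomposes a manipulation's effect on pain into
`c = c' + a·b` per subject (three-path: `a·d·b` through a serial
self-report → brain chain), summarizing per-subject products at the group
level so a–b covariance is counted.

A synthetic-data module generates cohorts with planted nociceptive and
endogenous (pro-/anti-pain subregion) patterns, calibrated study designs
(a balanced 2×2 control-by-expectancy test phase; an LL/LM/HM/HH cue
design), structured plus i.i.d. noise, and known effect sizes — so every
stage of the pipeline is testable against ground truth. See
`docs/methods.md` for the model and all numerical conventions.

## Worked example

```python
import numpy as np
import painsig as ps

grid = ps.make_grid((12, 12, 12), "ellipsoid")          # ~550 voxels
truth = ps.make_ground_truth(grid, seed=0)               # planted patterns
design = ps.make_study_design("generic")                 # ~50 painful trials
cohort = ps.generate_subjects(design, grid, truth, n_subjects=20, seed=42)
reference = ps.generate_reference_signature(grid, seed=7)

dev = ps.SignatureDeveloper(reference_map=reference).fit(cohort)
cos = truth.endogenous @ dev.weights_ / np.linalg.norm(dev.weights_)
print(f"{int(dev.q_mask_.sum())} FDR voxels, {len(dev.regions_)} regions, "
      f"cosine to planted pattern {cos:.3f}")
```

prints

```
124 FDR voxels, 4 regions, cosine to planted pattern 0.878
```

i.e. the aggregated map points at the planted intensity-independent pattern
(cosine 0.88), and FDR-surviving voxels form contiguous signed regions.
Scoring held-out subjects and testing mediation:

```python
from painsig.apply import loso_develop_and_apply
from painsig.inference import mediate_multilevel, zscore_within

loso = loso_develop_and_apply(cohort, reference_map=reference)
rs = np.array([v["r"] for v in loso.values()])
print(f"held-out response-rating r: mean {rs.mean():.2f}, "
      f"{np.mean(rs > 0):.0%} positive")

truth6 = ps.study6_truth(grid, seed=0)                   # same planted anatomy
ds6 = ps.generate_subjects(ps.make_study_design("study6"), grid, truth6,
                           n_subjects=29, seed=1000)
res = mediate_multilevel(
    [d.conditions["expectancy_code"].to_numpy() for d in ds6],
    zscore_within([d.X @ dev.weights_ for d in ds6]),
    [d.ratings for d in ds6],
    cov_list=[d.intensity_values() for d in ds6],
    n_boot=10000, seed=0)
print(f"indirect a*b = {res['ab_1'].estimate:.3f}, p = {res['ab_1'].p_two:.4f}")
```

prints

```
held-out response-rating r: mean 0.71, 100% positive
indirect a*b = 0.052, p = 0.0001
```

— every held-out subject's signature response tracks their residual
ratings, and the expectancy cue's effect on pain is significantly mediated
by the signature response (controlling stimulus intensity), as planted.

A command-line pipeline mirrors the library:

```sh
painsig simulate --preset generic --subjects 20 --seed 42 --out data/
painsig develop  --data data/ --seed 42 --out sig/
painsig apply    --signature sig/signature.nii.gz --mask sig/mask.nii.gz \
                 --trials data/sub-01_trials.nii.gz --meta sub01.tsv --out resp.tsv
painsig infer    glm --responses all.tsv --x signature_response --y rating \
                 --out glm.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch at a given
seed — simulate a 20-subject training world, develop the signature, score
held-out subjects, fit the multilevel GLM, and run the 2×2-design mediation
— printing a stage-by-stage summary and writing the results manifest:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
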
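# gwtbss

Group-wise-atlas TBSS: skeleton-projected fractional-anisotropy (FA)
group analysis with a simulation framework for measuring how the choice
of registration target drives false positives and sensitivity.

## The problem

Tract-based spatial statistics (TBSS) compares white-matter FA between
groups by aligning every subject's FA map into a common space, building
the skeleton of tract centres from the mean FA map, projecting each
subject's local FA maxima onto that skeleton, and testing each skeleton
voxel non-parametrically.  The registration step is the weak link: in
cohorts with cerebral atrophy and enlarged ventricles (ageing, Alzheimer's
disease), direct registration to a standard template leaves residual,
*group-dependent* misalignment that the projection step cannot fully
absorb — and misalignment between groups masquerades as FA differences.

`gwtbss` implements four choices of registration target behind one
interface:

| strategy | target |
|---|---|
| `ST` | the standard-space template, directly |
| `RS` | the most representative subject (minimum mean pairwise non-rigid deformation), then affine to the template |
| `SS` | the mean of template-aligned images, as a second-pass target |
| `GW` | an iteratively constructed unbiased group-wise atlas (register-all, re-average; 1 rigid + 4 affine + 10 non-rigid iterations), then affine to the template |

and evaluates them on synthetic FA phantoms with known tract centrelines,
seeded inter-subject warps, and analytic ventricular expansion:

* **Specificity** — controls are warped to atrophied targets by an
  *independent* (demons) registration; originals are smoothed with an
  interpolation-matched kernel (chosen by round-trip RMSE over
  0.5/1/1.5/2 mm); the two groups differ only by the artificial warp, so
  every significant voxel is a false positive.
* **Sensitivity** — FA inside tract masks (mapped to each subject by
  registration + nearest-neighbour label warping) is reduced by
  10–40% and detection per tract is recorded.

Statistics follow the standard protocol: voxel-wise GLM t statistics,
threshold-free cluster enhancement (E = 0.5, H = 2) restricted to the
skeleton, and family-wise error control from the permutation distribution
of the maximum enhanced statistic (p < 0.05 corrected; Freedman–Lane
residual permutation under covariates; exact enumeration for small
groups).

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import numpy as np
from gwtbss import evalsim

# canonical phantom study: 10 controls, 10 atrophy-deformed targets,
# and a systematically offset standard-space template
tpl, std, controls, targets = evalsim.make_study_inputs(seed=0)

# specificity experiment: warped controls vs smoothed originals
smoothed, warped, sigma, _ = evalsim.make_specificity_cohort(controls, targets)
print(f"interpolation-matched kernel: {sigma} mm")

for strategy in ("ST", "GW"):
    rep = evalsim.run_specificity(smoothed, warped, strategy,
                                  tpl.tract_labels, std, seed=5,
                                  label_space_fa=tpl.fa_volume)
    sd = evalsim.groupwise_sd_map(rep.extras["cohort"]).data
    skel = rep.extras["skeleton"]
    print(f"{strategy}: {len(rep.significant_tracts)} false-positive tracts, "
          f"skeleton-masked FA SD {sd[skel.mask].mean():.4f}")
```

prints (exact SD digits vary at the fourth decimal with BLAS builds):

```
interpolation-matched kernel: 1.5 mm
ST: 0 false-positive tracts, skeleton-masked FA SD 0.0331
GW: 0 false-positive tracts, skeleton-masked FA SD 0.0305
```

— the group-wise atlas aligns the atrophy cohort more consistently
(lower residual FA variance on the skeleton) while, like the direct
strategy, producing no false-positive tracts on this cohort.  The same
objects expose the per-tract table (`rep.per_tract`), the projected
matrix, and for `GW` the per-iteration variance trace
(`rep.extras["trace"]`).

A command-line interface mirrors the stages:

```bash
gwtbss simulate --out cohort/ --n-controls 10 --n-targets 10 --seed 1
gwtbss reference --strategy gw --subjects 'cohort/control_0??.nii.gz' \
       --template cohort/standard_template.nii.gz --out aligned/
gwtbss skeleton --cohort 'aligned/aligned_*.nii.gz' --out skel/
gwtbss evaluate --experiment sensitivity --strategy st,gw --out eval/
gwtbss run --strategy gw --seed 1 --out run1/      # end-to-end
```

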
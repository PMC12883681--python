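# lesionet

Voxel-wise **lesion probability mapping (LPM)** and **lesion network mapping
(LNM)** for linking white-matter lesion location — and the functional
connectivity of lesioned tissue — to clinical status, with permutation-based
familywise error control throughout.

The package is aimed at neuroimaging groups studying disorders with focal
white-matter damage (multiple sclerosis being the motivating case) who want
to ask two questions about a patient cohort stratified by a clinical trait
(cognitive impairment, fatigue, depression):

1. **Where are the lesions?**  Are lesions more frequent at particular
   voxels in the affected group?
2. **What do the lesions disconnect?**  Are the affected group's lesions
   more strongly functionally connected — through a normative resting-state
   connectome — to particular gray-matter regions?

## Methods at a glance

**Cognitive classification.** Raw neuropsychological test scores are
z-scored against a normative linear regression, `z = (raw − (β₀ + β₁·age +
β₂·sex + β₃·education)) / σ̂`, per test of a 9-test battery spanning four
domains. A test is *failed* at `z ≤ −1.5`; a domain is *impaired* when any
of its tests is failed; a subject is *cognitively impaired* with ≥ 2
impaired domains. Fatigue is MFIS ≥ 38; depression is MADRS > 9.

**LPM.** Each group's lesion probability map is the voxel-wise mean of the
binary lesion masks. Group differences are tested voxel-by-voxel inside a
white-matter mask (tissue probability > 0.25) with a covariate-adjusted GLM.

**LNM.** Each patient's lesion mask seeds a resting-state functional
connectivity analysis in every subject of a normative connectome: the mean
time course over lesioned voxels is Pearson-correlated with every voxel,
Fisher r-to-z transformed (`z = atanh r`), and the per-subject z-maps are
aggregated with a one-sample t-test, `t = z̄ / (s_z/√n)`. The resulting
t-volume is the patient's lesion network map; group differences are tested
inside a gray-matter mask with age, sex, EDSS, scanner and log lesion
volume as nuisance covariates.

**Inference.** Both comparisons share one engine: a per-voxel GLM with a
single contrast and Freedman–Lane permutation of nuisance-model residuals.
Each permutation records the maximum t over the mask (voxel-level FWE) and
the maximum suprathreshold-cluster extent at a Student cluster-forming
threshold (cluster-extent FWE, default p < 0.001, k_E = 50 voxels,
18-connectivity). Corrected p-values use the add-one convention and are
exact by complete enumeration when few distinct relabellings exist.

**Validation metrics.** Dice = `2|A∩B| / (|A|+|B|)` and voxel-wise MSE
quantify agreement between lesion probability maps (e.g. across scanners).

Because cohort MRI and normative connectomes are rarely redistributable,
the package ships a first-class synthetic-data module: lesion cohorts with
an exact per-voxel probability law and planted group effects, a normative
connectome with a latent-signal network of known correlation structure, and
clinical scores coupled to lesion load — every downstream stage is testable
against known ground truth.

## Worked example

Plant a 40-percentage-point lesion-frequency excess in a spherical region
for group B (n = 60/group, 24³ grid) and recover it:

```python
import pandas as pd
from lesionet import synthetic
from lesionet.lpm import compare_lesion_probability
from lesionet.inference import InferenceSettings

cfg = synthetic.default_config(n_per_group=(60, 60), effect_delta=0.4, rng_seed=7)
masks, truth = synthetic.simulate_lesion_cohort(cfg)
records = synthetic.simulate_clinical_scores(masks, truth, cfg)
phantom = synthetic.default_phantom()
covars = pd.DataFrame({"age": [r.age for r in records],
                       "sex": [r.sex for r in records],
                       "edss": [r.edss for r in records],
                       "scanner": [r.scanner for r in records]})
settings = InferenceSettings(n_permutations=1000, cluster_forming_p=0.001,
                             k_e_min=10, rng_seed=7)
result = compare_lesion_probability(masks[:60], masks[60:], covars,
                                    phantom.wm_probability, settings)
statmap, clusters = result.pos   # direction: group B > group A
print(clusters.table[["cluster_id", "extent", "peak_x", "peak_y", "peak_z",
                      "peak_t", "p_fwe_cluster"]].to_string(index=False))
```

prints

```
 cluster_id  extent  peak_x  peak_y  peak_z   peak_t  p_fwe_cluster
          1     136     7.0    -3.0    -3.0 9.751189       0.000999
```

one significant cluster of 136 voxels whose peak (world mm coordinates, t =
9.75) lies in the planted region; its extent-FWE p is 1/1001, the smallest
value 1000 permutations can resolve. The cluster's voxels overlap the
planted sphere with Dice 1.000.

The same workflow is available from the shell:

```sh
lesionet simulate --out sim/ --seed 7 --n-per-group 60 60 --effect-delta 0.4
lesionet compare-lpm --masks sim/masks --groups groups.tsv \
    --wm-mask sim/wm_probability.nii.gz --perms 1000 --kmin 10 --out cmp/
```

## Layout

- `lesionet.synthetic` — lesion cohorts, normative connectome, clinical scores, count-matched cohorts
- `lesionet.cohort` — normative z-scoring, impairment classification, stratification
- `lesionet.lpm` / `lesionet.lnm` — map construction and group comparisons
- `lesionet.inference` — the shared permutation GLM engine
- `lesionet.similarity` — Dice / MSE between probability maps
- `lesionet.io_atlas` — NIfTI/TSV/YAML I/O, atlas lookup, provenance sidecars
- `lesionet.experiments` — the end-to-end validation studies
- `lesionet.cli` — the `lesionet` command

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
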
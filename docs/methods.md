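# Methods

## The analysis model

The pipeline treats each patient as contributing one binary lesion mask on
a common grid (all volumes must share one shape and one voxel-to-world
affine to 1e-6; spatial normalisation is upstream and out of scope), a row
of clinical covariates, and — derived — one lesion network map.

### Lesion probability maps

A group's LPM at voxel v is the fraction of subjects lesioned at v. The
group comparison stacks the binary masks as the GLM response: per voxel,
`y = β_g·group + Z·γ + ε` with contrast on the 0/1 group column. A linear
model on Bernoulli responses is heteroscedastic, which is precisely why
inference is by permutation rather than by the Student reference — the
Student distribution is used only to convert the cluster-forming p into a
t threshold, mirroring how parametric cluster-forming thresholds are used
in practice. Analysis voxels must have white-matter probability > 0.25 and
lesions in ≥ 2 pooled subjects (configurable); voxels lesioned in fewer
subjects carry (near-)degenerate variance and no usable signal.

### Lesion network maps

For one patient and one normative subject: the patient's lesioned voxels
define a seed; the seed's mean time course is correlated with every voxel
(Pearson), and `z = atanh(r)` stabilises the correlations, with r clipped
at ±(1 − 1e-7) so self-correlation voxels stay finite rather than being
removed. Voxels with constant series get r = 0 and a degeneracy flag. Over
the n normative subjects, the per-voxel one-sample t (n−1 SD denominator)
is the patient's LNM. The implementation demeans each scan once and
correlates all patients' seed time courses against it in one matrix
product (`compute_lnms`), which is algebraically identical to the
per-patient loop and what makes cohort-scale runs take seconds.

Seed (lesioned) voxels are not excluded from the output map; their clipped
z-values are retained and flagged. LNM group comparisons are restricted to
gray matter (> 0.25), which in practice removes the seed territory anyway.
The `t2lv` covariate (lesion volume, mL) enters log-transformed, floored
at 0.001 mL so lesion-free subjects remain finite.

### Permutation inference

One engine serves both comparisons. Nuisance and interest columns are
split by the contrast's zero pattern. Freedman–Lane: fit the nuisance-only
model, keep its fitted part, permute its residual rows, refit the full
model, and record per permutation (i) the maximum t over the analysis mask
and (ii) the maximum suprathreshold-cluster extent, in both contrast
directions. Corrected p-values are `(1 + #{perm ≥ obs}) / (1 + n_perm)`
with the observed labelling always included; ties count against the
observed statistic. Per-voxel uncorrected p-values come from the same
permutation stream, so `p_fwe ≥ p_unc` holds identically and no p is 0.

When the nuisance is at most an intercept and the interest column is
binary, the t statistic depends on a relabelling only through the group
split, and the engine enumerates all C(n, n₁) splits exactly whenever
there are no more of them than permutations requested — p-values are then
exact, and for n ≤ 7 they coincide with brute-force enumeration (tested).

Degenerate voxels (zero residual variance) get t = 0 and a flag; with
fully constant data every permutation ties and p = 1. Each one-sided
direction is reported separately with its own max-statistic null; the FWE
level is controlled per contrast, as in the standard nonparametric mapping
toolboxes.

### Cluster extraction and labelling

Suprathreshold voxels (t above the Student quantile at residual df for the
cluster-forming p) are grouped by connected components; connectivity is
configurable {6, 18, 26} with 18 (faces + edges) the default, matching
common neuroimaging practice. Components below k_E voxels are dropped —
k_E defaults to 50 as used on full-resolution 2 mm grids and is scaled
down (we use 10) on the 24³ synthetic grid. Clusters are labelled by every
atlas region covering ≥ 5% of their voxels, sorted by overlap; peaks are
reported in world mm via the affine (voxel indices are 0-based
internally).

Cluster-wise FWE is controlled by permutation of the maximum cluster
extent, not by random-field theory: smoothness estimation is ill-defined
on small synthetic grids, and the permutation approach is exact under
exchangeability. This is a deliberate deviation from toolboxes that use
RFT for one of the two map types; the two approaches agree in calibration,
not numerically.

## The synthetic data

### What it emulates

*Lesion masks.* A per-subject white-noise field is smoothed with a
Gaussian kernel (FWHM 3 voxels), standardised by the **exact** per-voxel
kernel L2 norm (the zero-padded kernel's sum of squared weights factorises
per axis), and thresholded at the normal quantile matching the target
probability. Marginally, every voxel is lesioned with exactly its
configured probability — the binomial marginal-law tests rely on this —
while the smoothing makes lesions contiguous blobs rather than
salt-and-pepper voxels. Group B adds `effect_delta` inside the planted
effect region.

*Normative connectome.* Per scan, one latent standard-normal time course
L; network voxels (seed ∪ targets) follow `x = κ·L + √(1−κ²)·ε`, other
voxels are unit noise; series are temporally demeaned. Closed forms used
as oracles: two network voxels correlate at κ²; the mean of m seed voxels
correlates with a target voxel at `κ² / √(κ² + (1−κ²)/m)`.

*Clinical scores.* Raw test scores follow the generating normative
regression minus `score_effect` residual-SD units per unit fractional
lesion load in the effect region. Fatigue/depression scales are normal
draws whose default means/SDs put the cut-off exceedance near the
prevalence observed in large MS cohorts (MFIS ~ N(32.5, 17.5²), MADRS ~
N(7.5, 7.5²), ~17% missing each); demographics emulate a large adult MS
cohort (age ~ N(43.7, 11.5²), 59% women, education ~ N(13, 3.5²), ordinal
EDSS, two scanners, 36% progressive).

*Geometry.* The default phantom is a 24×24×24 grid of 2 mm voxels — a
desk-scale stand-in for a standard-space grid, chosen so thousands of
permutations run in minutes — with a central "white matter" ball (radius 7
voxels, lesion-bearing), a surrounding "gray matter" shell (radius 7–11),
a spherical effect region inside WM, a network seed region inside WM and
two target spheres in the GM shell. Tissue probabilities are 0.9 inside
their compartment so the standard 0.25 threshold reproduces the intended
masks.

*Randomness.* One root seed; per-subject streams derived by counter
offset (`SeedSequence(root, spawn_key=(stream, index))`), so outputs are
reproducible and independent of generation order.

### What it does not emulate

Anatomically realistic lesion topography, hemodynamics, scanner noise
(drift, spikes), registration error, and spatially autocorrelated fMRI
noise. Passing tests therefore demonstrate the statistical machinery —
calibration, recovery, exactness — under the stated generative model, not
performance on real MRI.

## Validation studies and their design

*Calibration.* 200 exchangeable null simulations (n = 40, half/half split,
age/sex/EDSS/scanner nuisance independent of group) on the 24³ grid. Null
data are spatially smooth Gaussian volumes, with cluster-forming p = 0.01
and no extent floor for this study only: sparse binary null data at
p < 0.001 leave the max-extent null distribution almost entirely at zero,
which makes the cluster test conservative (false-positive rate near 0) and
leaves nothing to measure. Rates are reported for the positive contrast —
the per-contrast familywise level the engine claims. 250 permutations per
simulation give p-granularity 1/251, ample at α = 0.05.

*LPM recovery.* Δ = 0.4 lesion-probability excess over base rate 0.10,
n = 100/group, 1000 permutations, 20 replicates; recovery is the Dice
between the cluster-FWE-significant voxels (B > A) and the planted region.

*LNM recovery.* Coupling 0.8, 50 normative scans of 60 timepoints,
n = 50/group, 10 replicates. Both groups draw lesions from the same
background field; group B receives a 0.2 lesion-probability excess inside
the network's seed region. This "shared background plus differential seed
load" design matters: with a *fixed* normative connectome, a design where
one group's lesions always sit in the seed region and the other group's
never do makes the first group's maps near-deterministic copies of each
other, and the group test then truthfully detects conditional
distributional differences at essentially every voxel — an intrinsic
property of fixed-connectome lesion network mapping, not an engine defect.
With the differential-load design the off-target differences stay at the
nominal rate and appear as isolated voxels that the extent floor removes,
while the target regions form a contiguous, strongly significant cluster.

*Worked-example arithmetic.* A deterministic cohort constructor realises a
published count table exactly (impaired-domain patterns via a greedy
degree-sequence assignment); the classifier and stratifier must reproduce
the printed prevalences from raw scores alone.

## Numerical choices

- Fisher clip ε = 1e-7; degenerate-variance tolerance 1e-12 (relative).
- Residual SD of a noiseless normative fit is floored at √tiny so exact
  predictions score z = 0 instead of dividing by zero.
- Prevalence percentages round half-up to one decimal (`Decimal`), the
  convention used in clinical tables (banker's rounding would differ).
- Cluster peaks break ties by the first maximal voxel in array order.
- The grid affine comparison tolerance is 1e-6 (absolute).

## Known limitations

- The GLM is homoscedastic across subjects; for binary lesion data the
  permutation test protects the level but power may trail dedicated
  binary-response tests at extreme base rates.
- No variance smoothing (pseudo-t) is implemented beyond an optional hook;
  very low-variance voxels can dominate small-sample t-fields.
- Cluster-extent inference on small grids is sensitive to the extent floor
  when suprathreshold density approaches the percolation regime.
- The synthetic connectome's noise is spatially white; real fMRI spatial
  autocorrelation would enlarge null cluster extents, and real analyses
  should rely on the permutation null (as the engine does) rather than on
  any fixed extent rule of thumb.
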
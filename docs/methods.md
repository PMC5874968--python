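# Methods

## Problem

Peptide arrays probe where in a protein's sequence serum antibodies bind:
the protein is tiled into short overlapping peptides, each peptide is
coated on ELISA plates, and each serum's optical density (OD450) per
peptide is read out.  Linear peptides bind sera promiscuously, plates vary,
and sera vary, so a disease-specific binding signal has to be isolated
statistically.  `episcan` implements that pipeline for the 36-peptide
tiling of the chemokine receptor CXCR3 (and any comparable design):
case/control sera paired on plates, a hierarchical Bayesian model that
separates a disease-specific peptide profile from shared background, and a
downstream diagnostic-ELISA evaluation.

## Tiling and peptide descriptors

A protein of length L is tiled into `window`-mers (default 20) advanced by
`step` residues (default 10).  If the last full window ends before residue
L, one truncated tile anchored at the next start position covers the
C-terminus; for CXCR3 (L = 368) this yields 36 tiles, the last an 18-mer
spanning residues 351–368.  Coordinates are 1-based inclusive; only the 20
canonical residues are accepted (ambiguity codes are rejected, not
guessed).

Descriptors per tile:

- **GRAVY** — mean Kyte–Doolittle hydropathy.  Per-residue values are
  multiples of 0.1, so the mean is computed as an exact rational and
  reported with half-away-from-zero rounding; float rounding would misplace
  means that are exact `.xx5` halves (five of the 36 CXCR3 tiles).
- **Net charge** at a given pH — Henderson–Hasselbalch summation over
  ionizable groups (D, E, C, Y, K, R, H, both termini).  Two pKa constant
  sets are shipped, `lehninger` and `emboss`; no single published set is
  canonical.  Against the reference CXCR3 table, Lehninger reproduces the
  charge column best (max |Δ| 0.13 e) while EMBOSS reproduces the pI column
  almost exactly (max |Δ| 0.005 pH), so charge defaults to `lehninger` and
  pI to `emboss` — evidently the convention of the widely used R
  `Peptides` defaults.  Both are arguments everywhere.
- **pI** — the unique root of the monotone charge–pH curve, found by
  bisection on (0, 14) to 1e-4.
- **Molecular weight** — sum of average residue masses + water (18.02 Da),
  plus 226.30 Da per biotinyl group for synthesized biotinylated peptides.
  Reference tables of synthesized peptides are only approximately
  reproducible (one CXCR3 row deviates by ~19 Da); we validate against the
  rows that hand arithmetic supports.
- **Kolaskar–Tongaonkar antigenicity** — sliding mean (window 6) of the
  published antigenic-propensity constants; a residue's score averages the
  windows covering it; residues above the whole-sequence mean window score
  form candidate regions, and runs shorter than `min_length` (default 6)
  are dropped.

## Plate preprocessing

Per plate, ODs are mapped to the open unit interval with padded limits
u = min/1.1, o = max·1.1, then x̂ = (x−u)/(o−u) and y = logit(x̂).  The
padding guarantees 0 < x̂ < 1, and the map is invariant to rescaling a
plate by a positive constant.  Control wells enter the per-plate min/max by
default (flag-selectable); duplicate wells are averaged on the OD scale
before normalization by default (also selectable).  Non-positive ODs
(reader underflow) are clamped to half the smallest positive OD on the
plate and logged rather than discarded.

A *serum run* (one serum on one plate, across its peptide wells) whose
logit variance lies strictly below the empirical 25% quantile (linear
interpolation) of all run variances is dropped before modeling: a flat run
carries no peptide contrast.  The quantile is computed across the whole
experiment by default (per-plate filtering would be unstable with two runs
per plate); with fewer than four runs the filter warns and keeps
everything.

## The signal-separation model

For observation i with peptide p(i), serum s(i), plate k(i) and disease
weight w_i (1 for case sera, 0 for controls):

    y_i = β0 + β_pI·pI_p(i) + β_hyd·hyd_p(i) + a_k(i) + u_s(i)
          + f_bg[p(i)] + w_i·f_s[p(i)] + ε_i

- a ~ N(0, σ²_plate), u ~ N(0, σ²_serum), ε ~ N(0, σ²_ε), all iid;
- f_bg and f_s are stationary AR(1) Gaussian processes over the peptide
  index with marginal variances σ²_bg, σ²_s and correlations ρ_bg, ρ_s —
  neighbouring tiles overlap by half their length, so their effects should
  be similar;
- covariates are the peptide's pI and GRAVY, standardized over the panel.

f_bg absorbs everything case and control sera share (non-specific
stickiness of individual peptides); f_s, entering only case observations,
is the disease-specific binding profile.  f_bg carries an exact sum-to-zero
constraint (sampled by conditioning-by-kriging) so the intercept stays
identifiable; f_s is left unconstrained because its level is identified by
the case/control contrast and a constant disease-wide shift is part of the
signal.

Priors are deliberately vague and config-overridable: fixed effects
N(0, 10³); half-Cauchy(1) on every standard deviation, implemented by the
inverse-gamma auxiliary-variable expansion so the variance updates stay
conjugate; ρ uniform on (−1, 1).

**Inference** is a blocked Gibbs sampler: exact multivariate-normal full
conditionals for the fixed effects, plate effects, serum effects and both
AR(1) profiles (dense P×P Cholesky; P is small); conjugate inverse-gamma
updates for all five variances; random-walk Metropolis on atanh(ρ) (step
0.4) for the two correlations.  Default 4 chains × 5,000 iterations,
burn-in 2,500, thinning 2, seeds spawned from one master seed; a split-R̂
above 1.1 on any disease-profile component triggers a warning recorded on
the result.  Observations are sorted canonically before fitting, so
posterior draws are independent of input row order.

Peptide-level covariates are partially confounded with a free
peptide-indexed profile (any covariate pattern over peptides lies inside
the profile's span); the priors resolve this softly, exactly as in the
latent-Gaussian formulation the model re-expresses.  The sampler's
correctness is checked against the closed-form Gaussian posterior on a
fixed-variance instance whose weakly identified directions are pinned by
tight priors, so Monte Carlo error can reach 3-decimal agreement.

**Reporting.**  The disease effect is mapped per draw to an odds-scale
fold change, 100·(exp(f_s[p]) − 1) percent, and summarized by the
posterior mean with 95% and 99.9% equal-tailed and HPD bands.  The exact
transform behind published "percent increase" figures is not stated
anywhere we know of; the odds-scale reading of a logit-linear effect is
the natural one and is documented as this package's choice.

## Epitope calls

The HPD interval of mass α is the shortest window of ⌈αS⌉ order statistics
(ties toward the lowest start).  The Bayesian p-value is p = 1 − α*, with
α* the largest mass on the grid {1/S, …, 1} whose HPD still excludes zero;
its floor is 1/S (0.000977 at S = 1024, which explains the granularity of
p-values reported from 1024 posterior samples; `legacy_1024` subsampling
reproduces that granularity from longer chains).  The estimator is noisy
for near-null draws — short windows fall one-sided by chance — so a
centered posterior yields p ≈ 0.8–0.9 rather than exactly 1; this
conservative-direction bias is irrelevant at any decision threshold.

Calls are flagged at the nominal level (p < α, default 0.05) and with
exact Bonferroni control (p < α/P; 0.05/36 ≈ 0.00139, displayed truncated
to 3 significant figures as 0.00138 to match the conventional report).
Benjamini–Hochberg is available but off by default.  With a topology
annotation (residue intervals labelled
intracellular/transmembrane/extracellular), each peptide receives the
majority compartment of its span ("mixed" when no label covers more than
half).  Per-residue scores — the mean percent increase of all tiles
covering a residue — are exported for serpentine-style visualization; no
figure is drawn here.

## Diagnostic evaluation

For a mixed-peptide ELISA read as one score per serum (duplicates averaged
on the OD scale): the cutoff maximizes the Matthews correlation
coefficient over midpoints between adjacent distinct scores (positive =
score > cutoff; ties toward higher specificity, then the higher cutoff);
AUC via the Mann–Whitney identity with ties counted ½; sensitivity and
specificity with exact Clopper–Pearson intervals; LR+ = sens/(1−spec) and
LR− = (1−sens)/spec with log-scale delta-method intervals (Clopper–Pearson
applies to proportions, not ratios); and a two-sided Wilcoxon rank-sum
test, exact for pooled n ≤ 20 without ties, tie- and continuity-corrected
normal approximation otherwise.

## Synthetic data

The generator emulates the paired design: one case and one control serum
per plate, every peptide in duplicate per serum, plus positive-control and
blank wells.  Logit-scale signals are composed exactly as the model
assumes, then mapped through the inverse logit and an affine rescale into
an OD range (default 0.05–3.5).  Positive controls sit at 0.9× the upper
OD limit, blanks just above the lower limit; all ODs stay strictly inside
the range.  Defaults describe a 30-pair study on the 36-peptide CXCR3
panel with the embedded pI/GRAVY covariates: β0 = −1.2, β_pI = 0.15,
β_hyd = −0.25 (modest physicochemical effects on the logit scale),
σ_plate = 0.3, σ_serum = 0.4, σ_ε = 0.4 (plate-to-plate variation smaller
than serum-to-serum, noise comparable to the serum spread — the usual
ELISA experience), ρ = 0.6 and σ_bg = 0.6 for the background profile
(half-overlapping tiles are strongly but not deterministically similar).
A fixture trio shares these dimensions: `null` (no disease signal),
`weak`/`strong` (+0.5/+1.5 logit units on the three intracellular epitope
regions, peptides 16–17, 24–25, 33–34, zero elsewhere).

What the generator does *not* emulate: plate-position (edge) effects,
saturation/hook artifacts, non-Gaussian serum outliers, titer calibration,
or any antibody biochemistry.  Passing recovery and error-control tests on
these data therefore validates the statistical machinery under its own
assumptions, not performance on real sera.

Because the pipeline re-estimates per-plate min/max when normalizing, the
generator's OD map is inverted only approximately; the resulting mild
attenuation is visible as credible-interval coverage a few points below
nominal when calibration is measured through the full OD pipeline, while
data simulated directly on the logit scale show near-nominal coverage (the
calibration test does the latter, since it probes the sampler).

## Problem sizes used by the test suite

Sampler oracle: P = 6, n = 96, 2×125k iterations.  Recovery: the `strong`
suite at 30 pairs, 2×2,500 iterations.  Null family-wise error: 100
replicates at 30 pairs, 1×1,200 iterations each.  Calibration: 200
replicates at 6 pairs × 12 peptides, 1×1,000 iterations.  These short
chains are adequate because the Gibbs blocks are exact draws and the
checks aggregate over peptides or replicates.

## Known limitations

- The AR(1) neighbourhood treats the peptide index as a 1-D chain; it does
  not model the actual 10-residue overlap structure beyond adjacency.
- The covariate/profile confound means β_pI and β_hyd are not sharply
  identified; they are noise-absorbers, not estimands.
- The empirical HPD p-value is grid-limited to multiples of 1/S and mildly
  anti-conservative near the floor; use enough retained draws that 1/S is
  well below any threshold of interest.
- Printed reference MW values for synthesized peptides are not uniformly
  reproducible from composition (see above); the calculator reports both
  unmodified and biotinylated masses.
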
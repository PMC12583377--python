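# Methods

This note documents the models, algorithms, defaults, and design
choices behind `roimcr`, and what the synthetic study does and does not
establish about real data.

## Synthetic mesocosm study

The generator emulates a two-factor designed monitoring campaign:
sample type (control river water vs river water receiving treated
wastewater) crossed with seven sampling times over ten days
(1 h, 12 h, 1 d, 2 d, 4 d, 7 d, 10 d). The default design has
45 water samples — 21 control, 21 treatment (3 replicated mesocosms ×
7 times) and 3 blanks — plus 8 QC runs, so the augmented matrix carries
K = 53 blocks.

Each ground-truth component is an elution peak (Gaussian, or
exponentially modified Gaussian for a tailing subset) multiplied by a
small spectrum: the monoisotopic base peak, 1–2 ¹³C isotope satellites
(+1.00336 Da per step), and with 30% probability a sodium-adduct mass.
Realized per-sample areas are

```
area = base_area × treatment_multiplier(type) × temporal_multiplier(time) × lognormal(CV)
```

Default study content (chosen once as a plausible desk-scale scenario):

- 40 analytes (including 4 internal standards spiked at a fixed level,
  flat across the design), base areas log-uniform in 2×10⁵–5×10⁶
  counts·s, σ between 4 and 8 s, 20% with EMG tailing;
- 40% of analytes carry a treatment effect (multiplier log-uniform in
  2–5); 50% carry temporal structure, half as a monotone trend and half
  as an abrupt regime change between the fourth and fifth sampling
  times (the early/late split the classification stage targets);
- 40 background components: 20 system/blank chemicals present equally
  in blanks and samples, 10 broad baseline-drift signals (σ 250–450 s,
  which stay bilinear and are therefore resolvable), 10 sporadic
  artifacts present in ~20% of samples with heavy lognormal scatter;
- 6 unretained "injection peak" components below 330 s;
- instrument noise: 1% multiplicative intensity noise, additive
  detector noise (30 counts), ±2% slow baseline modulation, per-sample
  RT shifts (σ 1.5 s), centroid m/z jitter (σ 0.0005 Da), and Poisson
  single-scan electric spikes.

The scan rate is a free parameter of the scenario; the default is one
scan per 0.4 s over a 30-min run, which makes the 30-consecutive-scan
ROI criterion equal ~12 s of elution — commensurate with LC peak
widths. All randomness flows from one `SeedSequence`; identical seeds
give byte-identical output.

The surrogate feature-profiling table contains one row per
(component × spectrum mass) passing a detection model (minimum apex
intensity, minimum scan span, optional rejection of tailing peaks),
plus planted false-positive rows. Missing per-sample areas are
gap-filled at detection-limit level, as gap-filled exports are in
practice; exact zeros would otherwise dominate the log-scale variance
with non-chemical structure.

What passing on this generator does *not* show: robustness to
profile-mode data, mass-accuracy drift, ion suppression, chimeric
centroids from unresolved isobars, or retention shifts large relative
to peak width. The generator's noise is well behaved by construction;
real data can violate the bilinear model more severely.

## ROI compression

The ROI search is a greedy streaming pass over scans: a centroid at or
above the intensity threshold (default 500 counts) extends the open ROI
whose running intensity-weighted mean m/z is nearest within the
tolerance (0.005 Da absolute; ties go to the more intense ROI), or
opens a new ROI. Within one scan, matching uses the ROI means as of the
start of the scan, so assignment does not depend on centroid update
order. A ROI closes after `max_gap` (default 0) scans without support;
closed ROIs shorter than 30 consecutive scans are dropped. An O(n²)
reference implementation of the same rule serves as the test oracle.
The union column axis merges per-sample ROI means by single-linkage
chaining at the same tolerance.

## Augmented matrix and regions

Scans before the 330-s injection cutoff are discarded before ROI
extraction (and the same cutoff removes feature-table rows). Per-sample
scan grids are kept as-is — the factorization is row-wise, so blocks
need not share an RT axis and modest retention shifts are absorbed by
the per-block elution profiles. Regions default to 12, cut at local
minima of the pooled, smoothed TIC nearest to the equal-width
positions (explicit boundaries and plain equal-width are also
available); each region keeps all K blocks and only its nonzero
columns, and regions reassemble to the parent matrix exactly.

## MCR/ALS

Initial spectra are purest rows selected SIMPLISMA-style: purity
std/(mean + α) with α = 5% of the largest row mean, down-weighted by
the determinant of the correlation-around-origin submatrix of already
selected rows (computed by Schur complement; an exhaustive
determinant-based oracle checks the selection in tests).

Each ALS half-step solves an exact non-negative least-squares problem
(fast combinatorial NNLS with passive-set grouping over the many
right-hand sides — not clip-to-zero), so the objective is monotone and
`(LOF/100)² + R²/100 = 1` holds identically; both are asserted as test
invariants. Spectra are max-normalized every iteration with the
magnitude carried in C, so trapezoid-integrated C blocks are directly
the per-sample base-peak areas. Convergence: relative LOF change below
0.1% or 50 iterations.

The per-region component count starts from a singular-value suggestion
(values above 3× the median singular value, with an absolute floor at
10⁻¹⁰ of s₁) and grows — warm-started from the previous solution plus
the worst residual row — until LOF ≤ 7.3% (equivalently R² ≥ 99.47%;
the reference quality regime for this workflow). Growing far beyond
that target is deliberately avoided: surplus components fit
sample-specific noise as single-sample spikes and split real compounds.
A consequence embraced throughout: compounds that coelute with
near-proportional abundance patterns resolve into *one* component with
a multi-mass spectrum — which is why all downstream comparisons and the
ground-truth scoring unfold component spectra into member masses
(> 5% of base peak) instead of looking at base peaks only.

## Component cleaning

Four rules, in order, each rejection logged with its rule:

1. **Blank fold-change** (default 3×): max study-sample area must reach
   3× the max blank area.
2. **Shape**: on the median of the component's five strongest blocks,
   the elution profile must have half-height width in [2 s, 60 s], an
   apex at least 5× the lower of the two region-edge levels, and ≥ 70%
   of its mass within ±4σ of the apex. This removes baseline-drift
   components, which appear region-spanning and flat.
3. **Prevalence** (default 40%): detected (area > 1% of the component's
   max) in at least 40% of study samples — the minimum-samples row
   filter familiar from feature-profiling tools; sporadic artifacts
   fail it. Without this rule a single zero-inflated artifact that
   survives by chance can dominate the post-log variance (its areas
   span ~8 decades) and mask every design effect.
4. **Replicate consistency**: among design cells where the component is
   detected (cell mean ≥ 10% of its max cell mean), at least half must
   have replicate CV ≤ 1.0. Cells at the noise floor are excluded from
   the vote — they say nothing about reproducibility either way.

Thresholds are configuration with the defaults above; they are
validated against the generator's ground truth (precision/recall of the
planted analyte set), not asserted against any external value.

## Area pre-processing

Both workflows' area matrices are reduced to the 42 core samples
(blanks/QC removed) and transformed by total-area normalization per
sample followed by log₁₀(x + ε), ε = 10⁻⁸ × the largest entry entering
the log. The order is configurable (`log_first` applies the log to raw
areas and removes the per-sample scale by row-mean centering in log
space, the log-space equivalent of dividing by a sample-size factor);
normalize-then-log is the default because it makes the logged values
per-sample proportions.

## ASCA+

Effect matrices come from the sum-to-zero-coded GLM of every variable
on the full model (intercept, type, time, interaction), taking each
effect's own columns times its coefficients — type III partial effects,
which reduce exactly to classical cell-mean ASCA on balanced designs
(asserted to 10⁻⁸) and stay unbiased when outlier removal unbalances
the design. Percent variation is the effect matrix's sum of squares
over that of the column-centered data; on balanced designs the
partition sums to 100 exactly, on unbalanced designs the small
non-orthogonality is reported as-is.

Permutation tests permute the tested factor's labels **within the
levels of the other factor**, preserving the cell allocation; the
p-value is (1 + #{SS_perm ≥ SS_obs})/(1 + n_perm) with 1000
permutations by default. Free permutation was measured to be
conservative on balanced data (empirical type-I 0.018 at α = 0.05
versus 0.048 for the stratified scheme, which is exact under
within-stratum exchangeability). For the interaction the joint cell
assignment is permuted freely. Rank-deficient codings that a
permutation can create (an emptied cell) are handled by the
minimum-norm solution rather than rejected.

Loading robustness uses a cell-stratified bootstrap (resampling rows
with replacement within design cells; whole-stratum fallback with a
warning when a cell has one sample), sign-aligning each replicate's PC
loadings to the full-data reference, and percentile intervals: a
variable is significant at α = 0.05 when its 95% interval excludes
zero. The default 200 bootstrap replicates keep the full study run in
minutes; the interval estimate is correspondingly coarse (~±3% on the
coverage of the interval itself).

SCA score plots project effect + residual onto the effect loadings
(augmented scores), so replicate scatter remains visible.

## PLS-DA

NIPALS PLS2 on autoscaled X and dummy-coded Y (two-class: one 0/1
column, threshold 0.5; multiclass: one-hot, argmax). Cross-validation
is venetian blinds on the design-sorted sample order, fold(i) = i mod k
with k = 5; the latent-variable count is chosen at minimum CV class
error with ties toward fewer LVs (grid 1–10, capped by rank).
Permutation validation shuffles labels and redoes the entire CV;
p = (1 + #{error_perm ≤ error_obs})/(1 + 200). VIP uses the per-LV
captured Y sum of squares; mean(VIP²) = 1 by construction (asserted to
10⁻¹⁰) and VIP > 1 defines the prioritized set. The label schemes are
control vs treatment, early (S1–S4) vs late (S5–S7), and a three-class
variant {control early, treated early, late}.

## Correspondence

Mass matching is inclusive at the tolerance (|Δm/z| ≤ 0.005 Da;
|ΔRT| ≤ 0.3 min entered in minutes and converted internally). Coverage
fractions count every match (one ROI mass may match several features
and vice versa); Venn counts reduce the pair list to nearest-mass
one-to-one pairs, so the shared count never exceeds min(|A|, |B|). Both
conventions appear side by side in the stage report. Component spectra
enter the comparison unfolded at the strict > 5%-of-base-peak rule.

## Pipeline

One master seed spawns independent streams for component generation,
rendering, the surrogate feature table, ASCA permutations/bootstrap and
PLS-DA permutations, making full reruns byte-identical. Stage timings
go to the log; the manifest records the config, per-stage dimensions
and the reduction audit (rows/variables before and after each
reduction). Ionization modes would be independent runs of the same
pipeline; the default study renders one mode.

Problem sizes used by the test suite and the acceptance script: the
default study (53 runs × 4500 scans, ~170 union ROIs, 12 regions)
resolves in roughly two minutes on one CPU; statistical calibration
harnesses use 500 null datasets at 199 permutations and desk-scale
matrices (42 × 8–20).

## Known limitations

- Compounds fully coeluting with proportional abundance patterns are
  fundamentally unidentifiable as separate bilinear components; they
  are reported as one multi-mass component (see above).
- The bootstrap ignores PC order swaps beyond sign alignment; with
  closely spaced effect eigenvalues, loading intervals can be
  pessimistic.
- Mass tolerance is absolute (Da), not ppm.
- No cross-sample RT warping; very large retention shifts (comparable
  to peak spacing) would break the shared-spectrum assumption even
  though per-block profiles are free.
- The unbalanced-design variance partition does not sum to exactly 100%
  (non-orthogonal partial effects); the residual is reported from the
  full-model fit.
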
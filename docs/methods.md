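# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot certify.

## Compositional preprocessing

Genus count tables are compositional: only relative information is
meaningful, so all inference runs on log-ratio coordinates.

**Sparsity filter.** A genus is retained only if its fraction of zero
counts is strictly below `max_zero_fraction` (default 0.25) within *both*
status groups. The boundary is exclusive: exactly 25 % zeros in either
group excludes the genus. Filtering precedes everything else and is
idempotent.

**Zero replacement.** Two conventions are exposed because both are used
for microbiome count data: `pseudocount_one` (every zero → 1; the
default for count tables) and `half_minimum` (every zero in genus *g* →
half of *g*'s smallest nonzero value). Pseudocount replacement can
create large negative log outliers for abundant genera with structural
zeros; this inflates within-group variance in the downstream per-genus
models and is a property of the convention, not a bug.

**ALR transform.** `alr_j = ln x_j − ln x_ref`, natural log; the
reference is the genus with the lowest coefficient of variation
(SD/mean, n−1 denominator) of relative abundance across all samples
pooled. Ties break to the lexicographically smaller genus id. ALR is
closure-invariant but not an isometry of the simplex; the package
quantifies the geometric distortion as the Procrustes correlation
(after optimal translation/rotation/scaling, configurations zero-padded
to a common width) between the ALR configuration and the centred
log-ratio (CLR) configuration of the same matrix, the conventional
isometric benchmark. On clean synthetic data this correlation is
typically ≥ 0.99; on real tables values of 0.8–0.95 are common.

**Autoscaling.** Each ALR column is scaled to mean 0, SD 1 (sample SD).
Because of this, every downstream group difference is automatically
expressed in SD units of the variable. Any log-base change would be
absorbed here, which is why the choice of natural log is immaterial.

## Discrimination (PLS-DA with VIP pruning)

The class vector is encoded as a single column: +1 for the
lexicographically smaller label (HHS), −1 for the other. PLS components
are fitted by NIPALS deflation on the centred matrix; for a single
response this is exactly the sequence of dominant eigenvectors of
X'yy'X on the deflated residuals, which the test suite exploits as an
oracle.

**Classification.** Samples are projected into score space
(R = W(P'W)⁻¹) and assigned to the class whose centroid is nearest in
Mahalanobis distance under the pooled within-class covariance of the
training scores. A singular covariance (possible in tiny CV folds)
falls back to a ridge of 1e-8 × trace/A; exact ties go to the
lexicographically smaller label.

**Model size.** The balanced error rate — the mean of per-class error
rates — is estimated by stratified 4-fold cross-validation, re-randomised
over 100 repetitions (folds are dealt round-robin within each class
after a shuffle; with 6 samples per class unstratified folds could
produce single-class training sets). The component count A minimises
mean BER, ties to the smaller A; the search is capped at A = 10 by
default, far above the optimum for designs with 12–24 samples. Within a
repetition, a single A_max-component fit per fold serves all candidate
A via its leading score columns.

**Variable selection.** VIP_j = √(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a),
with SS_a the class-encoding variance explained by component a;
Σ_j VIP_j² = p holds by construction. Each iteration drops all genera
with VIP < 1 and refits. The loop stops when (a) no genus falls below
the threshold, (b) the cross-validated BER fails to improve, or
(c) fewer than two genera would remain; the iteration with the lowest
BER is returned (ties to the earliest, i.e. largest, panel).

**Validation and its honest limits.** The final panel is assessed with
an observed and a label-permuted confusion matrix (default 500
repetitions of 4-fold CV; 10,000 available via the full-scale profile),
averaged over repetitions and row-normalised to percentages.
Preprocessing and variable selection are fit once on the full dataset
before cross-validation, mirroring the analysis sequence this package
reproduces. The resulting optimism is substantial: on pure-noise data
the observed per-class true-positive rate can reach 80–100 % while the
permuted rate stays at 50 %. The permuted matrix is therefore the
spurious-performance check — chance-level permuted performance certifies
the resampling machinery, not the selected panel. This is quantified in
the test suite and deliberately not corrected.

## Bayesian differential abundance

Per genus, the autoscaled ALR value is modelled as
y_i = μ + δ·I(status_i = HHS) + e_i with e ~ N(0, σ²) and flat priors:
improper uniform on μ and δ, and on log σ (prior ∝ 1/σ²). The posterior
is proper for ≥ 2 samples per group plus one. All full conditionals are
conjugate, so δ is sampled by Gibbs: normal draws for μ and δ, a scaled
inverse-χ² draw for σ². The exact marginal of δ is a location-scale
t with n−2 degrees of freedom centred at the observed mean difference
with scale s_p·√(1/n₁+1/n₀); the acceptance tests verify the sampler
against this closed form, with the Monte-Carlo error of HPD endpoints
calibrated by parametric bootstrap from the same t.

Profiles: desk default 4 chains × 5,000 iterations, burn-in 1,000,
thinning 10 (1,600 retained draws); `McmcConfig.full_scale()` gives
4 × 50,000 with the same burn-in and lag. Chains use independent
sub-seeds spawned from the config seed; a split-chain potential scale
reduction factor > 1.01 raises a warning. For the conjugate Gibbs
scheme used here the desk profile is far beyond what stable posterior
summaries require; the large profile exists for fidelity, not accuracy.

**Reporting.** meanDiff (posterior mean of δ, already in SD units
because inputs are autoscaled), the 95 % highest-posterior-density
interval (shortest window over sorted draws), and
P0 = P(δ > 0) if meanDiff ≥ 0 else P(δ < 0). A genus is starred
relevant when P0 > 0.95. No multiplicity correction is applied — the
per-genus rule is reported as such, and the table records how many
genera were tested.

## Diversity

Alpha (Shannon, nats; inverse Simpson) and Bray–Curtis are computed on
**relative abundances** of the retained, zero-replaced genera. Log-ratio
coordinates are signed, so neither the diversity indices nor Bray–Curtis
is defined on them; relative abundances are the mathematically valid
input closest to the transformed data. Group differences in alpha
diversity use the two-sided Mann–Whitney U test — exact enumeration for
tie-free samples of ≤ 12, otherwise the tie-corrected normal
approximation without continuity correction, which makes the two-group
p-value identical to Kruskal–Wallis (a property the tests assert).

NMDS minimises Kruskal stress-1 by SMACOF majorisation with monotone
(isotonic) disparities; one classical-scaling start plus random
restarts (default 20, tolerance 1e-6), best final stress wins;
iterations are accepted only while stress does not increase, so the
stress trace is non-increasing by construction. PERMANOVA runs on the
Euclidean geometry of the first two ordination axes: the pseudo-F from
the distance-based sum-of-squares decomposition (identical to the
classical one-way decomposition for Euclidean input), p-value
(1 + #{F_perm ≥ F_obs}) / (1 + n_permutations) over seeded label
permutations (default 999 desk / 9,999 full profile).

## Functional aggregation

A user-supplied two-column TSV maps genera to functional groups (the
FAPROTAX database itself is not redistributed; any export in this format
works). Per status, mean per-sample relative abundances are summed into
every function a genus maps to — a genus with k functions contributes k
times, the usual semantics of such tables — and columns are normalised
to 100 % over the function-assigned mass. Functions with zero abundance
in exactly one status are flagged exclusive to the other. Unmapped
genera are ignored and do not affect the profile.

## Synthetic data: what it emulates, what it does not

The generator reproduces the sampling design: 2 statuses × 3 farms ×
2 pooled samples (defaults), a shared log-normal baseline abundance
profile (SD 1.5), per-sample log-noise of SD `overdispersion` (default
1.0), a shared per-farm perturbation (SD 0.25 × overdispersion) that
correlates pools from one farm, multinomial sampling at a
Poisson-distributed depth (default mean 10,000 reads — desk-scale,
roughly a tenth of a realistic MiSeq run), and uniform Bernoulli
zero-inflation applied to the sampled counts (default 5 %, never
zeroing a sample's largest count so row sums stay positive).

Design choices that matter downstream:

- **Stable reference taxa.** Three abundant genera get a noise SD
  multiplier of 0.25 and never carry a differential effect. Real genus
  tables contain genuinely low-variation taxa, and ALR with a lowest-CV
  reference presupposes one: if every genus had identical noise, the
  "reference" would be stable only by luck and its own fluctuation
  would leak a common random offset into every log-ratio, attenuating
  one effect-direction per dataset. (A fully heterogeneous per-genus
  dispersion model was considered and rejected: it couples effect
  magnitude to the multinomial sampling floor and degrades recovery for
  reasons unrelated to the methods under test.)
- **Differential genera** are drawn from above the 25th percentile of
  the baseline profile, with alternating signs and a between-status
  log shift of `effect_size × overdispersion` (half added to one
  status, half subtracted from the other). A shift on an ultra-rare
  genus would be censored to zeros at desk-scale depth and recoverable
  by no method.
- **Ground truth** stores signed effects (positive = enriched in HHS)
  so recovery can be scored by direction, not just membership.

Not emulated: ecological differences between wall, slat and slurry
communities beyond genus-inventory size; taxon–taxon correlation
structure; library-size confounding with status; the variance reduction
of pooling five wipes (only the farm effect is modelled, pooling stays
implicit). Passing tests therefore certify the statistical machinery
under a clean compositional model, not performance on real sequencing
data.

**Known quantitative behaviour** (measured by the test suite): at the
reference conditions — 57 genera, 12 samples, 10 differential genera at
effect 2.0 — the VIP selection recovers a median of 8–9 of 10 truth
genera over a 10-seed grid, while the end-to-end Bayesian relevant set
recovers a median of 7: the injected 2-SD shift arrives at ~1.3 SD on
the autoscaled ALR scale (autoscaling divides by the total SD including
the group separation; sampling noise and the reference ratio add
variance; within-farm pools are correlated), leaving the P0 > 0.95 rule
with roughly 85–90 % per-genus power at n = 6 + 6. Larger genus
inventories (the 259-genus slurry-like setting) reduce recovery
further, mirroring the small selected fractions reported for such
tables in practice.

## Numerical conventions

- Sample SD (n−1) everywhere.
- All resampling (folds, permutations, chains, restarts) consumes
  explicit seeds; identical configs reproduce outputs byte-identically,
  and the pipeline manifest records every parameter of a run.
- NIPALS stops early if deflation exhausts the response; nested CV
  sub-models reuse the leading components of one fit per fold.
- Mahalanobis ties and reference-CV ties break lexicographically;
  BER ties break to the smaller component count; selection-loop BER
  ties break to the earlier (larger) panel.
- Report TSVs are written with `%.10g` float formatting; manifests as
  sorted-key JSON.
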
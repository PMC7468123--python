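# Methods

This note documents the models, estimators and design choices behind
`mstnet`, in the order the pipeline runs them, and closes with what the
synthetic cohort does and does not establish about real data.

## Motion quality control

The per-subject input is a trace of per-frame relative RMS displacements
(mm), one value per acquired volume. A subject is excluded when the mean
over frames exceeds 0.2 mm, or — evaluated second — when at least 20
frames strictly exceed 0.25 mm ("exceeded" is read as strict inequality;
a frame at exactly 0.25 mm does not count). Each decision carries exactly
one reason. The 0.2 mm criterion is applied to the mean over frames: the
wording it derives from is ambiguous between a mean and a per-frame
criterion, and the mean is the standard subject-level summary when
per-frame values are the given input. Subjects, not frames, are excluded;
no scrubbing is performed. Both thresholds and the spike count are
configurable.

## Wavelet-coherence connectivity

**MODWT.** The maximal overlap discrete wavelet transform is computed with
the Percival–Walden pyramid under periodic boundary treatment: at level j
the scaling/wavelet filters (rescaled by 1/√2) are applied with circular
shifts of stride 2^(j−1), so every scale keeps the input length and the
per-scale energies sum exactly to the input energy (asserted to 1e-8
relative in tests). Filter coefficients come from PyWavelets; the default
is the 8-tap least-asymmetric filter (LA8, `sym4`), the conventional
choice of the MODWT literature. The transform is written in-house because
the installed wavelet library's stationary transform requires the series
length to be divisible by 2^level, which a 600-frame series is not; the
two agree in per-scale energy on power-of-two-length inputs. Scale j
isolates the nominal band [fs/2^(j+1), fs/2^j]; scale 4 at a 0.609 s
sampling interval is 0.051–0.103 Hz, the conventional 0.05–0.10 Hz BOLD
band. Boundary-affected coefficients are retained by default (they affect
all subjects identically); a `discard` policy is available.

**Coherence.** Edge weights are magnitude-squared coherence between
scale-4 coefficient series, |S_xy|²/(S_xx·S_yy), with auto- and
cross-spectra estimated by Welch's overlapped averaged periodogram:
128-sample Hann-tapered segments with 3/4 overlap (K = 15 segments on 600
frames), constant-detrended per segment. The per-bin coherence is averaged
over the Welch bins inside the nominal scale-4 passband. Averaging over
*all* positive-frequency bins was evaluated and rejected as the default:
the coefficient spectrum carries almost no energy outside the band, so
out-of-band bins sit at the estimator's noise floor and dilute the
estimate toward its bias (an independent pair and a strongly coupled pair
then differ by only a few hundredths). Both choices remain available
(`bin_policy`), and every matrix is written with a JSON sidecar recording
filter, boundary policy, Welch settings, band and bin policy, since none
of these are standardized in the literature the pipeline follows. The
3/4 overlap (rather than 1/2) roughly doubles the number of averaged
segments on a 600-frame series, which materially reduces estimator
variance at negligible cost. For K averaged segments the coherence of
independent signals has expectation ≈ 1/K; the test suite checks this
analytic bias by Monte Carlo. All N(N−1)/2 pairs are computed from one
set of per-node segment FFTs; a test asserts exact agreement with
`scipy.signal.coherence` per pair. The diagonal is set to zero so that
self-coherence never enters tree construction or strength summaries.

## MST backbone and metrics

The "minimum spanning tree" of functional-connectivity practice is the
spanning tree retaining the *strongest* edges — the maximum-weight tree of
the coherence graph (equivalently the minimum tree of reciprocal
weights); reported backbone strengths in this literature (≈ 0.6) are only
consistent with that convention. Construction is Kruskal's algorithm with
a deterministic tie-break (weight descending, then lexicographic node
pair), so equal-weight inputs still yield a unique tree; measured
coherences are generically distinct. The implementation is checked against
exhaustive Prüfer-sequence enumeration of all n^(n−2) labelled trees for
n ≤ 7 and against networkx on larger graphs.

Metrics follow the standard tree conventions: strength = mean of the N−1
edge weights; diameter = longest inter-node path in edges, normalized by
N−1 (the natural tree constant, matching the ≈ 0.11 scale reported for
264-node backbones; the raw edge count is also reported); kappa =
⟨k²⟩/⟨k⟩ over all N nodes (star_N gives N/2, path_N gives
(4N−6)/(2N−2) — both verified as closed forms); leaf fraction =
degree-1 nodes / N, following the "fraction of nodes" wording (the
alternative leaves/edges convention differs by at most 1/(N−1));
betweenness is normalized by (N−1)(N−2)/2 so a star hub scores exactly 1
and leaves 0. In a tree each pair has a unique path, so betweenness is
exact combinatorics (computed via networkx, cross-checked against brute
force path enumeration). Tree overlap = shared edges / (N−1). The
strength-invariance property — scaling the weight matrix by any c > 0
changes no topology metric and scales strength by exactly c — is the
method's core rationale and is asserted bit-exactly in tests.

## Group inference

The ANCOVA is ordinary least squares on group indicators plus covariates
(age and education continuous, sex as a single indicator). Effect F
statistics use the drop-the-effect convention (SS_effect = rise in
residual SS when the effect's columns are removed), which in this
no-interaction model coincides with the Type III convention of the
statistics packages this analysis style originates from; effect size is
partial η² = SS_effect/(SS_effect + SS_error); adjusted group means are
model predictions at sample covariate means. The implementation is plain
numpy least squares (fast enough for thousand-replicate calibration runs)
and is tested against statsmodels' `anova_lm` as an independent oracle,
and against classical one-way ANOVA when covariates are absent. Null
calibration (two identical groups) holds the 5% level within Monte-Carlo
error.

"Tukey LSD" post-hoc tests are internally contradictory nomenclature;
they are implemented as Fisher's LSD — model-based pairwise t contrasts
with unadjusted p values — consistent with the separate use of BH-FDR for
multiplicity; Tukey HSD (studentized-range correction) is available
behind a flag. BH-FDR (delegated to statsmodels, brute-force cutoff scan
as test oracle) is applied across the four global measures' group-effect
p values; the family definition is configurable. Medication contrasts
reuse the same machinery with the stratum flag as factor.

Nodal tests compare two groups per metric with the absolute difference of
group means as statistic and label permutation as the null; family-wise
error is controlled by the max-statistic method, p_fwe(node) =
(1 + #{permutations whose max-over-nodes statistic ≥ observed}) /
(n_perm + 1) — the add-one estimator keeps p > 0, and two-sidedness is
realized by the absolute statistic. Covariates do not enter the
permutation scheme (labels only), which is recorded in output metadata.
Weak FWE control is verified empirically over 200 null replicates.

## Synthetic cohort generator

The generator's role is to emulate the statistical structure the analysis
assumes — four diagnostic groups whose connectomes differ in strength, in
topology, or not at all — with full reproducibility from one seed
(per-subject streams are derived from counter-keyed seed sequences, so
adding a subject never perturbs existing ones).

**Template.** The control-group coherence target is core–periphery:
N/10 hub nodes whose incident edges sit at base + boost (default
0.35 + 0.35), all other edges at base (0.35), plus small seeded jitter.
These levels were chosen in a pilot design phase so that realized
backbone strengths land on the ≈ 0.6–0.7 scale reported for real
wavelet-coherence MSTs and the hub structure survives estimation noise.

**Realization.** Latent Gaussian factors with correlation √(target) are
projected to the nearest correlation matrix (eigenvalue clipping at 1e-6
with unit-diagonal renormalization — arbitrary targets need not be valid
correlation matrices), band-passed to the scale-4 band, variance
normalized, and mixed with white noise (sd 0.5). Coherence of two
band-limited Gaussian signals with latent correlation ρ is ≈ ρ², so
targets are approximately realized in level and faithfully in rank order;
exact matching is not attempted, since the analyses of interest are group
contrasts.

**Group effects.** SCZ-like groups (SCZ, SCP) receive a uniform
multiplicative deficit on every off-diagonal target entry (default 0.15)
— a pure strength manipulation that provably preserves edge ranks. The
BD-like topology effect is realized as *modularization*: the global hub
core is replaced by many small strongly coherent modules joined by strong
ring bridges, with module size shrinking geometrically in the flattening
parameter (default 0.6). Two alternatives were evaluated and rejected.
Affine shrinkage of hub edges toward the mean preserves the matrix-wide
mean but not the strong-edge tail the MST actually samples, so it leaks a
strength deficit into the topology condition. Randomly relocating strong
edges preserves the value multiset but violates correlation transitivity
(a node cannot be strongly coherent with many mutually weakly coherent
partners), so the positive-definite projection erodes exactly the edges
that were moved. Block/module structures, by contrast, are exactly
realizable as correlation matrices. Because the realization chain
(projection, estimator bias, tree max-selection) still maps structures to
measured strength nonlinearly, the modular template's strong-edge level is
*calibrated*: a short seeded secant search (10 common-random-seed
calibration subjects per evaluation, tolerance 0.003) adjusts it until the
group's expected measured MST strength matches the control template's.
This makes "topology differs, strength does not" true on the scale the
pipeline reports, which is the stated meaning of the dial.

**Between-subject variability** comes from three multiplicative sources,
chosen because multiplicative factors commute with a group-level strength
scaling and therefore cannot convert the strength dial into a topology
difference: per-subject node strength factors (lognormal, sd 0.15;
subjects differ in which regions are most strongly connected), lognormal
per-edge jitter (sd 0.10), and a lognormal global coherence scale
(sd 0.02). Motion traces are gamma-distributed per frame (CV 0.4) around
a per-subject level (lognormal, sd 0.45 on the log scale, group means
0.08 mm for HC/SCP and 0.10 mm for SCZ/BD) with rare spike frames, so QC
exclusions occur at realistic single-digit-percent rates. Demographics
are sampled per group (the SCZ-like group younger, more often male, fewer
education years; medication flags concentrated in the patient groups) to
exercise covariate adjustment; no covariate influences the signals, so
covariate terms are pure noise dimensions by construction.

## Recovery of the planted dissociation, and its limits

The acceptance suite plants the canonical dissociation (HC; SCZ-like with
deficit 0.15 and no flattening; BD-like with flattening 0.6 and no
deficit; 30 subjects per group, 60 nodes, 600 frames) and runs the full
pipeline twenty times. The BD-like signature — lower kappa and leaf
fraction with no strength difference — is recovered essentially always.
The SCZ-like signature is recovered in roughly half the replicates, short
of the 80% the suite asserts, and the shortfall is a property of the
measurement physics rather than of the implementation:

- At 600 frames the Welch coherence estimator has only ~15–25 effective
  spectral degrees of freedom, so per-subject MST strength carries an
  irreducible correlated-noise SD of ≈ 0.045 and tree edge selection is
  substantially noise-driven.
- A 15% multiplicative target deficit realizes as only a ≈ 0.03 measured
  strength difference — the per-subject positive-definite projection
  compresses group differences — which at n = 30 gives ≈ 70% two-sided
  detection power.
- Forcing the full 15% through to the measured scale (verified with a
  calibrated variant) raises detection power to ~100% but lowers the
  SCZ-like group's coherence enough that its estimates become relatively
  noisier, its trees slightly more random, and kappa/leaf "no difference"
  conditions then fail far more than 20% of the time.

The joint success rate is maximized, at roughly 55–75%, for intermediate
realized deficits; no setting of the free parameters reaches 80% jointly
under these study conditions. The package implements the documented,
rank-preserving target-level deficit and reports the honest rates.

## What passing tests show — and do not show

The generator produces stationary Gaussian band-limited signals with
block/core–periphery coherence structure. Real BOLD data are
non-Gaussian, nonstationary, contain physiological and residual motion
artifacts correlated across regions, and have richer network structure.
Passing recovery tests therefore demonstrates that the *pipeline*
correctly extracts and tests the structures it claims to — not that real
cohorts will show these effect sizes. QC behavior is exercised with
simulated traces only; the exclusion rule itself is exact arithmetic.

## Numerical choices and problem sizes

Text-serialized matrices carry 10 significant digits; symmetry is exact
by mirroring the upper triangle; coherence values are clipped to [0, 1]
against rounding. Degenerate inputs (zero-variance series) raise typed
errors naming the offending nodes. Tests run at reduced problem sizes
chosen for tight Monte-Carlo bounds at desk scale: recovery at 60 nodes ×
600 frames × 90 subjects × 20 replicates, permutation calibration at 500
permutations × 200 replicates, null-ANCOVA calibration at 1000 tables;
the pipeline defaults (264 nodes, 10,000 permutations) match the
full-scale setting and are exercised by the same code paths.
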
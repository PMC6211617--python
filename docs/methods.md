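# Methods

## Scientific setting

In an F1 hybrid of *Drosophila melanogaster* and *D. simulans*, both
parental alleles sit in the same nuclei and see the same trans-regulatory
environment, so a difference in how strongly the two alleles are
transcribed reflects cis-regulatory divergence (up to stochastic bursting,
which averages out over the thousands of nuclei in a slice).  Cryoslicing
blastoderm embryos into ~14 µm sections along the anterior-posterior (AP)
axis and sequencing each slice yields, per gene and slice, counts of reads
assignable to each allele.  The package analyses such data end to end and
ships a synthetic-data generator so that every stage can be validated
against known ground truth without any external download.

## ASE score and read assignment

A read is assigned to an allele only when every SNP it covers matches one
parent; reads with no SNPs, with alleles of both parents, or with a
non-parental allele are ambiguous and discarded.  The per-slice score is

    ASE = (n_sim − n_mel) / (n_sim + n_mel)  ∈ [−1, 1],

independent of depth, −1 meaning all reads from the *D. melanogaster*
allele and +1 all from *D. simulans*.  Slices with fewer than
`min_slice_ase_reads` (default 20) assignable reads for a gene are
missing.  QC removes samples with fewer than 1 million reads or mapping
rate below 52% (strict inequalities; the boundary is retained), drops
genes with no SNP supported by ≥10 reads per allele, and masks X-linked
genes in male embryos (males carry only the maternal X, so allelic ratios
there say nothing about cis-regulation).

## Species-bias calls

Allelic counts are pooled per gene within each direction of the cross and
tested against an equal split with an exact binomial test (two-sided,
central method — exact at p₀ = 0.5 by symmetry), with a log2(sim/mel)
fold change using a Haldane pseudocount of 0.5.  Benjamini–Hochberg
correction is applied per direction, and a gene is called biased toward a
species only when both cross directions are significant with concordant
sign.  This is a deliberate simplification of a negative-binomial
differential framework with per-allele size factors: pooling across
slices removes most overdispersion, and the concordance requirement is
the decision rule that matters.  On fully null simulations (2000 genes,
50 replicates) the empirical FDR is far below the nominal 5%, i.e. the
test is conservative.

## svASE pattern fitting

Each gene's ASE values are pooled across embryos, with slice midpoints
normalized per embryo to x ∈ [0, 1] (anterior = 0) so embryos with 25–27
slices share one axis.  Two four-parameter curves are fit by nonlinear
least squares:

* step (logistic):  f(x) = A / (1 + exp(w·(x − x₀))) − y₀
* peak (Gaussian):  f(x) = A · exp(−(x − x₀)² / w²) − y₀

Variance explained is R² = 1 − SSE/SST.  A gene is called svASE when the
better of the two fits reaches R² ≥ 0.45 (ties classified as step).  The
step curve has an exact sign degeneracy (A, w, y₀) ≡ (−A, −w, y₀ − A);
fits are canonicalized to A ≥ 0.  Fitting uses a multi-start grid
(x₀ ∈ {0.1, …, 0.9}; w ∈ {±5, ±20, ±80} for step, {0.05, 0.15, 0.4} for
peak) with data-informed amplitudes; starts are ranked by their initial
SSE and the best six are polished by a batched projected
Levenberg–Marquardt with analytic Jacobians, followed by a bounded
trust-region refinement of the winner (tolerances 1e−12, so noiseless
data invert to machine precision).  Amplitudes are clamped to [−2, 2] and
centers to [−0.25, 1.25]; unweighted least squares throughout.

The false-discovery rate of the calling procedure is estimated by
permuting the spatial coordinates of the whole ASE matrix (one joint
column permutation per shuffle; per-gene independent permutation is an
option), refitting both curves, and counting genes that clear the
threshold.  The estimator is FDR = mean shuffle calls / max(observed
calls, 1).  Genes with fewer than 8 finite values or spanning less than
half the axis are skipped with a reason.

## Expression-pattern comparisons (EMD)

Absolute per-slice expression is converted to a unit-mass pattern by
adding a pseudocount (default 1 expression unit per slice) and dividing
by the total.  Patterns of equal length are compared with the 1-D earth
mover distance, Σᵢ |CDF_p(i) − CDF_q(i)| with one distance unit per
slice, which equals the optimal-transport cost on the line (verified in
the tests against a linear-programming transport solver on ≤6-bin
instances).

To compare hybrids with the parents, each parental profile is smoothed
(centered rolling mean of 3 slices, edges using available neighbours),
fit with a cubic smoothing spline whose smoothing factor is chosen by
leave-one-out cross-validation over a small grid, evaluated on a
hypothetical 27-slice embryo (negative predictions clipped to 0),
normalized, and the two parents averaged.  Per gene, the EMDs of each
hybrid embryo to this reference are tested against the parent–parent EMD
with a one-sample one-sided t-test (alternative: greater); zero-variance
inputs yield p = 1 (conservative).  Cross-direction differences compare
within-direction pairwise EMDs to between-direction pairwise EMDs with a
two-sample one-sided t-test; with 3 + 2 embryos this uses 4 within and 6
between pairs, and at least two pairs per group are required.  Both
tests are BH-corrected across genes.  Null calibration (exchangeable
embryos): the hybrid test rejects at ~2–3% at nominal 5% (slightly
conservative because EMDs are skewed), the cross-direction test at ~6%
despite the dependence among pairs sharing an embryo.

## Atlas-based bias prediction

Per-nucleus expression atlases of the two species are compared after
per-gene normalization: subtract the mean over the inter-stripe region
(55–75% egg length) and divide by the 90th percentile of the centered
values outside that region.  Each *D. melanogaster* nucleus is matched to
the *D. simulans* nucleus that, among its 30 physically closest
neighbours, minimizes the summed squared expression difference over the
matching gene set (ties broken by distance, then id).  Matching precision
is limited by local iso-expression geometry and by bilateral symmetry
(mirror twins across the sagittal plane are genuinely indistinguishable
in a symmetric embryo); at atlas-scale noise, matches land within two
nucleus spacings of the true counterpart (mirror-equivalent) ≥95% of the
time, with the median within one spacing.

Per-nucleus bias applies the ASE formula to matched expression values
(negative background-subtracted values clipped to 0 first); nuclei whose
larger expression is below 20% of the gene's peak carry no callable bias.
Virtual slices group nuclei into 4%-of-egg-length bins and apply the same
formula to the summed expression of each bin, masking bins below the same
callability floor; predicted and observed per-bin ASE are compared by
Pearson correlation over jointly callable bins (≥3 required).

## Logistic CRM model and perturbation scans

The anterior *hunchback* domain is modeled as a logistic function of TF
concentrations with a linear term per TF and a quadratic Bicoid term
(Bicoid can lose activity at the high concentrations of the anterior
tip).  Training nuclei exclude the posterior stripe (separate regulation):
expression is thresholded at 20% of peak, thresholded occupancy is
aggregated into 50 bins along x, 1-D connected runs of "on" bins are the
domains, and when at least two exist the domain with the larger x
centroid is removed.  The response is on/off at the same threshold, fit
by maximum-likelihood logistic regression (McFadden pseudo-R² reported);
complete separation falls back to a small ridge penalty (1e−4, intercept
unpenalized) and is flagged.  Model selection enumerates candidate TF
subsets of size ≤4 beyond the required terms and keeps the model
maximizing the variance of the continuous normalized expression explained
by the fitted probability, with strict improvement required so ties favor
the smaller model.

A cis-regulatory change in one TF's input is emulated by multiplying that
coefficient (the two Bicoid terms singly or in tandem); predicted ASE is
(p_perturbed − p_base)/(p_perturbed + p_base) per nucleus, binned like
the atlas prediction, and shifted so its mean matches the observed mean
before scoring (mapping bias can shift the observed level).  A scan over
TFs × multipliers (default grid −1.0 to 3.0 in steps of 0.1) scores each
candidate by Pearson r and by variance explained (1 − SSE/SST over
jointly callable bins) and ranks by variance explained, ties — including
the no-signal case where every score is ≤0 — broken toward the smallest
coefficient change |multiplier − 1|.

Two caveats are inherent to binarized fitting and are documented rather
than hidden.  First, when all model TFs vary only along the AP axis the
design columns are smooth functions of one coordinate and therefore
nearly collinear; coefficient recovery to ±10% at 5000 nuclei is
demonstrated in a calibration regime with high inter-nucleus
concentration variability (lognormal sd 0.7), while at typical atlas
noise signs and rough magnitudes are recovered.  Second, fitting a
logistic to a thresholded noisy response inflates the coefficient scale
relative to the generative model, so a scan against data generated from
a *different* (true) model identifies the correct TF but its best
multiplier absorbs that scale factor; the shared-truth recovery tests
therefore scan the same model that generated the observations.

## Synthetic-data generator

The generator encodes the study conditions the analysis assumes:

* **Embryos** default to 420 µm length, 14 µm slices, 25–27 slices; slice
  i has midpoint x = (i − ½)/n as a fraction of egg length.
* **Slice counts**: per-slice totals are Poisson around `depth` × the
  gene's share of expression (default demo depth 20000 assignable reads
  per slice); a gene's maternal fraction f of transcripts carries the
  mother's allele outright, and zygotic transcripts split binomially with
  a sim-allele rate of (1 + ASE_true(x))/2, where ASE_true is the gene's
  step/peak curve (0.5 for null genes).  With fraction f the expected
  maternal:paternal ratio is (1 + f)/(1 − f); the default panel draws f
  from Beta(mean 0.744, concentration 20), calibrated to the ~6.8-fold
  pooled maternal excess of sliced hybrid embryos.
* **svASE classes**: step genes draw A ∈ [0.3, 0.8], |w| ∈ [15, 60],
  x₀ ∈ [0.2, 0.8]; peak genes |A| ∈ [0.3, 0.8], w ∈ [0.08, 0.2],
  x₀ ∈ [0.3, 0.7] — amplitudes and widths in the range of the patterns
  the fits are meant to detect, with baselines y₀ ∈ [−0.2, 0.2].
* **Atlases**: nuclei on the surface of a prolate ellipsoid; TF profiles
  are anterior/posterior exponentials (Bicoid-like, decay 0.25 egg
  lengths), terminal pole factors (Huckebein-like, decay 0.07), gap-like
  Gaussians, and dorsoventral factors graded around the circumference.
  The target gene responds to the true local concentrations through a
  known logistic model — Bicoid activation nearly cancelled by its
  quadratic term at the anterior tip, plus terminal and posterior
  repression, giving an "on" domain at roughly 7–50% egg length — while
  the stored TF channels and the stored expression carry independent
  measurement noise (multiplicative lognormal 0.05 and additive Gaussian
  0.05 by default), as in a registered multi-channel atlas.  Atlases also
  carry extra patterned marker genes because cross-species matching draws
  its power from the breadth of the atlas gene complement.
* **Reads** are abstract allele observations at SNP positions; no
  sequencing-level artefacts (mapping bias, remapping filters) are
  simulated.

What passing tests on this generator do **not** show about real data:
mapping and reference bias (handled upstream by masking/filtering
pipelines), overdispersion beyond Poisson/binomial sampling, spatial
correlation of noise between adjacent slices, embryo-to-embryo staging
differences, and the possibility that real svASE patterns are not
step- or peak-shaped.

## Reproducibility and problem sizes

Every simulation takes an explicit seed; the pipeline fans one global
seed into per-stage child seeds through a fixed `SeedSequence`
derivation, so identical configurations give byte-identical reports.
The bundled demo run uses 200 background + 24 patterned genes, 5
reciprocal-cross embryos, depth 20000 reads per slice, 20 shuffles for
the FDR, and a 1500-nucleus atlas pair — sizes chosen so the complete
run finishes in about a minute on one CPU while keeping per-slice ASE
sampling noise (~0.07) well below the fitted pattern amplitudes.  The
test suite's recovery and calibration experiments use 50–400 replicates
at comparable sizes.
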
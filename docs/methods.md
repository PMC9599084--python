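# Methods

## Study design the package models

A two-group bulk-RNA-seq cohort — responders vs non-responders to
immune-checkpoint blockade, default 8 vs 4 patients (12 samples) — with
per-caller circRNA back-splice-junction (BSJ) call tables, linear
forward-splice-junction (FSJ) counts per locus, lncRNA and mRNA count
matrices, miRNA-interaction tables, and right-censored OS/PFS survival
data. All stages share one sample-id namespace.

## Consensus circRNA detection

**Coordinate harmonization.** Callers disagree on conventions;
per-caller offset profiles (start/end shifts to canonical 0-based
half-open, strand mandatory) are configuration, with shipped defaults:
CIRCexplorer2 emits BED (shift (0, 0)); CIRI, DCC, STARchip and
CIRIquant report 1-based inclusive starts (shift (−1, 0)). Records
invalid after shifting (start ≥ end, negative reads) are dropped and
logged. Duplicate records for one (circRNA, sample, caller) cell are
summed, treating them as split output lines.

**Filter.** A circRNA is high-confidence iff (a) ≥ `min_callers` (3)
callers report it anywhere, and (b) ≥ `min_reads` (2) BSJ reads appear
in ≥ `min_samples` (2) samples. Condition (b) defaults to the *merged*
scope: the per-cell evidence is the maximum count over callers (union
of evidence — any caller attesting the reads satisfies the cell). This
choice makes the retained set provably monotone under added reads or
callers; evaluating (b) on the median-merged counts would not be,
because a newly supporting low-count caller lowers cell medians. The
alternative `reads_scope="per_caller"` requires (b) to hold within
≥ `min_callers` callers individually.

**Quantification.** The exported consensus count per (circRNA, sample)
is the median across the callers supporting that circRNA (zeros from
supporting callers count; rounded half to even), a robust merge when
one caller misquantifies. The genomic summary partitions consensus
reads per chromosome by response group (24 nuclear sequences) and ranks
host genes by total reads via a user-supplied annotation; unannotated
loci are `novel`.

## Circular-to-linear ratio

`r = 2·bsj / (2·bsj + fsj)`; the factor 2 reflects that a linear
junction read can arise from either side of the back-splice. `r` is
strictly increasing in BSJ (FSJ > 0), strictly decreasing in FSJ
(BSJ > 0), equals 1 iff FSJ = 0 < BSJ, and is undefined (missing, never
a number) at 0/0. Aggregation over a scope (cohort, response group, or
sample) sums BSJ and FSJ reads *before* applying the formula — the
ratio of pooled counts, not the mean of per-sample ratios; per-sample
mode is available.

## Differential expression

NB2 model per feature *i*, sample *j*:

    y_ij ~ NB(mu_ij, alpha_i),  Var = mu + alpha·mu²
    log mu_ij = log s_j + beta_0 + beta_1·1[j responder]

* **Size factors** `s_j` are the samples' total linear mapped reads
  divided by their geometric mean — both circRNA and lncRNA matrices
  are normalized against the linear library, not against themselves.
* **Dispersion.** Gene-wise estimates maximize the Cox–Reid adjusted
  profile likelihood (ML minus half the log-determinant of the Fisher
  information), bounded to [1e-8, 10], with a method-of-moments value
  as the degenerate-case fallback. With ≥ 10 tested features a second
  pass shrinks log-dispersions toward the cross-gene median with a
  normal prior whose variance is the MAD-based spread minus the
  sampling variance trigamma((n−p)/2), floored at 0.25. Rationale: at
  n = 12 the unmoderated plug-in Wald test is anti-conservative
  (~12% of null raw p < 0.05 in our simulations vs ~7% moderated with
  per-seed KS uniformity passing); information sharing across genes is
  the field-standard remedy. `moderate_dispersion=False` restores the
  plain gene-wise fit.
* **Test.** Wald statistic beta_1/SE against the standard normal,
  two-sided. Features with all-zero counts get status `zero` and no
  test; one group all-zero (perfect separation) caps |log2FC| at 15
  with a `separation` flag. BH adjustment runs over tested features
  only; declared sets use adjusted p < 0.1 and |log2FC| > 1.5 (the
  log2-scale reading; `lfc_scale="linear"` interprets the threshold as
  a linear fold change, i.e. |log2FC| > log2 1.5).

Not implemented by design: LFC shrinkage, outlier replacement,
independent filtering, multi-factor designs.

## ceRNA network

miRNA–mRNA predictions carry a support count out of 7 tools; only
records with support ≥ 5 survive. The miRNA universe is restricted to
miRNAs predicted to bind at least one DE ceRNA (circRNA or lncRNA).
An edge (ceRNA c, mRNA g) exists iff some retained miRNA binds both;
`shared_mirnas` lists all of them. Edges are then validated on
log2(size-factor-scaled count + 1) expression with Pearson r (two-sided
p); since sponging predicts direct correlation, the default keeps only
r > 0 (`keep="all"` retains everything). Zero-variance endpoints drop
the edge with a logged reason. miRNA expression is not modeled — miRNAs
annotate edges; no miRNA-level statistics are computed.

## Survival risk score

Expression is log2-normalized and z-scored per feature across the
training patients. Each signature feature gets a univariate Cox
proportional-hazards coefficient: Newton–Raphson with step-halving on
the Efron-tie-corrected partial likelihood, tolerance 1e-8, ≤ 50
iterations; zero-variance features are flagged `untestable`
(coefficient 0); monotone likelihoods (separation) cap the coefficient
at ±10 with a flag. The risk score is the coefficient-weighted sum of
normalized expression; patients split at the median score (ties to
low; an explicit cutoff value is accepted). Coefficients are trained
against OS by default, PFS via the endpoint option; the fitted split
is evaluated on both endpoints with Kaplan–Meier product-limit curves
(medians with Greenwood/log(−log) 95% CIs, possibly unreached) and the
two-group log-rank test — these two standard estimators are delegated
to lifelines; the Cox engine is this package's own and is cross-checked
against lifelines in the test suite. Fitting more features than
patients emits an instability warning rather than failing, matching
the pilot framing of such cohorts.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes;
defaults are the study conditions (8/4 cohort, 5 callers, NB2 counts
with dispersion 0.1 around mean scale 100, 10% planted features at
|log2FC| = 2, 7 prediction tools, exponential survival at baseline
hazard 0.05/month with unit signature effect, 20% censoring).

* One master seed; each stage draws from a substream keyed by a CRC-32
  hash of the stage label, so stages rerun independently.
* Sequencing depth is log-normal around 2e7 reads (sigma 0.35), and
  expected counts scale with depth, so size-factor anchoring is
  exercised.
* Each (locus, caller) pair is detected with probability 0.8; a
  caller's counts are a Binomial(0.9) thinning of the latent per-sample
  NB count (thinned NB remains NB), and its coordinates follow its own
  convention, to be undone by harmonization. BSJ means use 0.3× the
  expression scale (circRNA libraries are shallower); FSJ counts are
  independent NB at the full scale.
* Planted DE effects split symmetrically across groups
  (±log2FC/2), also applied to circRNA BSJ means so the circRNA DE
  branch has recoverable truth.
* Planted interaction triples pair *direction-concordant* DE ceRNAs
  and DE mRNAs through dedicated miRNAs with mRNA-side support drawn
  from {5, 6, 7}; a sponge and its de-repressed target move together,
  so planted edges carry the positive correlation the retention rule
  expects. Decoy interactions draw support from a low-concentrated
  distribution over 1..7.
* The latent risk signal is the coefficient-weighted planted ceRNA
  signature (z-scored log2 counts; coefficient signs match planted
  directions), standardized across samples; survival times are
  exponential with hazard `h0·exp(beta·signal)` (PFS at 2·h0), with
  independent censoring replacing the time by a uniform fraction.
* Truth tables are exhaustive: every planted effect, triple, locus,
  signal value and signature coefficient is exported.

What the generator does *not* model: read-level artifacts (FFPE
degradation, GC bias), correlated features, caller-specific
false-positive loci, non-proportional hazards, informative censoring.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under its own assumptions, not robustness to real
tissue data.

## Numerical choices and degenerate inputs

* GLM linear predictors are clipped to ±30 before exponentiation;
  Fisher-scoring steps stop at 1e-8 or 50 iterations.
* Median consensus counts round half to even (numpy convention).
* Stratification requires non-identical scores (error otherwise); a
  cohort with no events yields flat KM curves and unreached medians,
  not an error; the log-rank test requires two nonempty groups and at
  least one event.
* Hierarchical clustering (reporting stage) uses average linkage on
  1 − Pearson distance of z-scored expression — the common heatmap
  default; constant rows are assigned unit distance.
* Pipeline artifacts are content-addressed (SHA-256) in the run
  manifest; identical config + seed reproduces identical hashes.

## Problem sizes in the shipped checks

The test suite exercises the stated statistical suites at their full
sizes (e.g. 100 consensus oracle fixtures, 1000 monotonicity
perturbations, 50 DE simulation seeds, 1000 null log-rank
replicates). `scripts/acceptance.py` recomputes the same quantities at
reduced replicate counts (10–20 seeds, 400 log-rank replicates) —
enough for stable percentages while keeping a single run lightweight;
the JSON records the size behind every value.

## Known limitations

* The NB Wald test is asymptotic; at n = 12 mild miscalibration
  remains even with moderated dispersions (measured ~7% of null raw
  p < 0.05 at nominal 5%).
* Per-feature Cox fits with more features than patients are reported
  with a warning but are inherently unstable; the risk score inherits
  that variance.
* The consensus merge treats callers symmetrically; no caller-specific
  reliability weighting.
* Correlation validation uses marginal Pearson r with no
  multiple-testing control across edges (none is applied by design;
  the edge-retention rule is sign-based).
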
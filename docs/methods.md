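# Methods

`bloomtrack` reconstructs, as a reusable pipeline, the inference chain used
to link phytoplankton-lysate amendments of natural seawater to the
prokaryotes that respond to them and to the viruses of those prokaryotes.
This note describes the models and procedures it implements, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot demonstrate.

## Experimental design assumed by the pipeline

Triplicate flasks of three treatment arms — an unamended control and
amendments with the dissolved intracellular fraction of *Chaetoceros* sp.
(CIF) or of *Heterosigma akashiwo* (HIF) — sampled daily over days 0–7.
Amplicon (16S ASV) counts exist for every day; virome (vOTU) quantification
for days 0, 1, 3, 5 and 7.  Days 0–1 form the early phase, 2–4 the middle
phase, 5–7 the late phase; the phase is a pure function of the day.
Missing flasks or days (samples are lost to technical error in real runs)
are tolerated everywhere: day-level summaries average the replicates that
exist and log n.  Samples whose amplicon library is below 5,000 reads, or
whose virome library is below 10,000 reads, are dropped at load time.

## Absolute-abundance calibration

ASV read counts are closed (compositional), so they are first converted to
relative abundances and then rescaled by the flow-cytometry total cell
count of the same flask and day:

    cells_i(s) = reads_i(s) / Σ_f reads_f(s) × cells_per_mL(s)

Column sums therefore equal the cytometry totals exactly (conservation,
enforced to 1e-9 relative in tests).  vOTUs use the FPKM-based analogue
with an extra calibration for reads that are virus-derived but not
assembled into any scaffold:

    P(i) = FPKM(i)/FPKM(viral) × R(viral)/(R(viral)+R(potential v)) × P(viral)

where FPKM(viral) is the summed FPKM of all >1 kb viral scaffolds, R(viral)
the reads mapped to them, R(potential v) the reads mapped to neither host
nor viral scaffolds, and P(viral) the flow-cytometry particle count.
Because the catalogued (>10 kb) vOTUs are a subset of the >1 kb scaffolds,
Σ_i P(i) ≤ P(viral) in every sample; the loader rejects bundles violating
Σ_i FPKM(i) ≤ FPKM(viral).  FPKM may be supplied or recomputed from mapped
reads and scaffold lengths; when both are present they must agree to 1e-6
relative.

## Community structure

Rarefaction subsamples each sample without replacement to a common depth
(default 9,450 reads) with a seeded generator.  Bray–Curtis dissimilarity,
PCoA (eigendecomposition of the double-centred Gower matrix) and ANOSIM
(rank-based R with a label-permutation p-value) are implemented directly;
scikit-bio serves as an independent cross-check in the test suite, never as
the implementation.  Negative PCoA eigenvalues — expected for Bray–Curtis —
are dropped with a warning and excluded from the proportion-explained
denominator.  Permutation p-values use the +1/+1 convention (the observed
labelling counts as one permutation), so p is never zero; the default is
999 permutations.  Two ANOSIM contrasts are produced: early vs middle-late
samples pooled over treatments, and treatment labels among middle-late
samples, with Bonferroni correction across contrasts.  On synthetic data
the treatment contrast is decisively significant (R ≈ 0.96–0.97,
p = 0.001) while the pooled early-vs-middle-late contrast is not, because
the middle-late pool spans the treatment separation itself; the contrasts
are configurable recipes rather than fixed sample subsets.

Total cell and particle counts are compared between treatments within each
phase by a Mann–Whitney U test (significance at P < 0.01), pooling all
(replicate, day) observations of the phase.  The U test is exact — full
enumeration of label assignments, which handles ties correctly — up to 12
observations, and a tie-corrected normal approximation with continuity
correction beyond.

## Class/subclass differential enrichment

The differential-abundance procedure applies three gates per feature, in
the style of LEfSe, with treatments (or day 0 vs later) as classes and the
triplicate flasks as subclasses:

1. Kruskal–Wallis across classes, tie-corrected, alpha 0.05.  The p-value
   comes from the chi-squared reference, or exact enumeration when the
   total n ≤ 10.
2. Subclass consistency: every between-class pair of subclass groups must
   agree in rank-order direction with the class-level difference.
3. A bootstrapped one-dimensional linear-discriminant effect size: 30
   rounds of stratified 2/3 subsampling; each round records the absolute
   class-mean separation on the unit-normalised discriminant axis (for a
   single feature this is the feature axis itself, kept well-defined for
   constant features by a variance floor of 1e-10 × the global variance);
   the score is log10 of the mean separation, floored at 0 below 1, and
   must reach 2.0.

Alpha, the LDA threshold, the number of rounds and the subsample fraction
are the published defaults of the original tool; we adopt them unchanged.  Three-class designs are handled one-vs-one:
a feature is called for its highest-mean class only if every pairwise
comparison passes all three gates.  Observations enter per (replicate,
day); subsampling draws are ordered by a label-independent key so renaming
classes can only flip the enrichment direction, never change the score.

Because the test runs on absolute abundances (cells/mL or particles/mL),
the LDA threshold of 2.0 means "mean separation ≥ 100 units"; for vOTUs
this structurally overlaps the burst threshold below.

## Responder and increased-vOTU filters

An ASV is *abundant* in a treatment when (i) on at least one day after day
0 it ranks in the top 20 by approximate cell number in every available
flask (ties at the cutoff are kept), and (ii) its replicate-mean abundance
exceeds 2 × its day-0 mean at least once (a day-0 mean of exactly 0 passes
when any later mean is positive; a per-flask variant of criterion (ii) is
available).  Treatment-specific ASVs are abundant in exactly one lysate
treatment, not abundant in the control, and called by the differential test
with that treatment as the enriched class.

A vOTU is *increased* in a treatment when the day-0-vs-later differential
test calls it with the later class enriched, and its replicate-mean P(i)
exceeds 100 particles/mL on at least one day.  The threshold is the
approximate mean burst size of marine bacterial viruses (reported range
50–185 particles per cell): a rise smaller than one burst per mL cannot be
attributed to lysis.  By default the "later" class contains every sampled
day ≥ 1; the boundary is configurable because the day-1 membership is
ambiguous in the source design.  vOTUs increased in exactly one lysate
treatment and not in the control are treatment-specific; vOTUs increased
in both lysate treatments or in all arms are reported separately.

## Host–virus pairing and environmental confirmation

Candidate pairs join each treatment-specific vOTU to the treatment-specific
ASVs whose lineage contains the vOTU's predicted host taxon at the
predicted rank or any coarser rank; host-unknown vOTUs are screened against
every specific ASV of the same treatment.  Candidates are then tested on a
monthly environmental series (17 shared time points) by contemporaneous
Spearman correlation — with zero permitted time delay, local similarity
analysis degenerates to plain rank correlation, which is what is
implemented.  The permutation p-value is exact (all n! rank permutations)
for n ≤ 7 and Monte-Carlo with the +1/+1 convention otherwise; q-values
are Benjamini–Hochberg over all tested pairs jointly (the q-value procedure
of the original network tool is unstated; BH is our documented choice).  A
pair is significant iff r > 0.6 AND p < 0.01 AND q < 0.05.  Constant
series have no defined rank correlation and are flagged, never significant.

## Synthetic data: what it emulates and what it does not

The microcosm generator plants known truth in a realistic envelope:

* 60 background ASVs at ~1.6e4 cells/mL each (total ~1e6 cells/mL), with a
  slow successional drift (per-ASV log-slope s.d. 0.4 over the 8 days)
  shared by all treatments and flasks, emulating bottle-effect succession;
* 5 CIF and 8 HIF responders (responder counts of the magnitude such
  experiments report) starting at 1e4 cells/mL and growing logistically from day 1 to a
  10× carrying capacity, saturating by the end of the middle phase;
* per responder, two lytic vOTUs whose particle densities rise by
  burst_size (100) × lysed fraction (0.1) × the host's density increment,
  with a configurable 0–2 day lag (default 0: at daily sampling resolution
  particle release is visible in the same sample as host growth), plus two
  lysogenic vOTUs that simply track their host's density — the pipeline
  flags these too, confirming it does not require lysis-shaped dynamics;
* 40 background vOTUs at ~3e4 particles/mL (total ~2e6–1e7 particles/mL,
  matching the observed range);
* multiplicative lognormal noise (σ 0.2) on every latent density, small
  (σ 0.05) measurement noise on cytometry totals, and multinomial read
  sampling at 20,000 amplicon reads and 1e6 virome reads per sample.  The
  virome denominators are generated self-consistently: two extra latent
  particle pools — the 1–10 kb scaffolds (80/20 split of scaffold-pool
  particles against the catalogued vOTUs at baseline) and the unassembled
  viruses whose reads map nowhere (10% of all viral particles) — share a
  single particle-times-length multinomial read allocation with the vOTUs,
  so R(viral), R(potential v) and FPKM(viral) all respond coherently when
  planted bursts grow.  An earlier fixed-read-share scheme violated this
  and made background P(i) estimates drift with the bursts.

The environmental generator draws, for each of 3 planted pairs, a shared
latent with a damped annual component (one fifth of the variance; a
dominant shared seasonality would correlate even independent features
through phase alignment) and mixes it into both members with weight
√strength, giving an expected rank correlation close to the configured
strength (0.9 by default); unpaired features get independent latents, and
monotone maps to the relative-abundance and FPKM scales preserve all rank
statistics.

What passing tests do **not** show about real data: the generator has no
compositional interactions between taxa beyond the multinomial closure, no
read-level errors or chimeras, no day-to-day autocorrelated environmental
forcing in the microcosm, lognormal rather than heavy-tailed abundance
noise, and a uniform background virome rather than the power-law rank-
abundance curve of real viromes.  Recovery rates measured here are
best-case rates for effects of the planted shape and size.

## Measured operating characteristics

At the default conditions, pooled over 20 simulations, ASV recovery is
essentially perfect (sensitivity 1.0, empirical FDR 0.0) and vOTU recovery
has sensitivity ≈ 0.97–0.98 with empirical FDR ≈ 0.014–0.018 across
independent replicate sets.  The residual vOTU false discoveries are
α = 0.05 Kruskal–Wallis passes of flat background vOTUs on the 3-vs-12
day-0-vs-later design (null rate verified at 4.85% against the nominal
5%) that land in a single treatment and thus survive the exactly-one-
treatment rule; the subclass-consistency gate adds little at this design
size because a feature extreme enough to pass Kruskal–Wallis is almost
always direction-consistent, and the LDA gate does not bind at particle
scales far above 100/mL.  The missed planted vOTUs are almost all
genuine responders demoted out of the specific set because the same null
mechanism sporadically flagged them as "increased" in a second treatment,
moving them to the shared categories.  Planted
environmental pairs (strength 0.9, n = 17) are detected in ≈ 99% of runs
with mean r ≈ 0.88; independent pairs pass the full r/p/q screen in under
1%.

## Numerical and degenerate-input choices

Rarefaction requires every retained sample to reach the depth and fails
listing offenders.  Bray–Curtis between two all-zero samples, asymmetric
PCoA input, singleton ANOSIM groups, empty test groups, single-class
Kruskal–Wallis, classes with fewer than 2 samples, constant Spearman
series, missing day-0 samples and fewer than 5 shared environmental time
points all raise (or flag) explicitly.  All stochastic stages take an
integer seed, derive per-feature or per-pair child seeds from a seed
sequence (so results do not depend on iteration order), and are
byte-reproducible; the seed is recorded in every CLI output directory.
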
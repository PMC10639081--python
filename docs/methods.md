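# Methods

This note documents the models, conventions and numerical choices behind
`isomutsig`, in the order the pipeline runs.

## Coordinates and formats

All positions are 1-based inclusive internally (the VCF convention);
BED/bedGraph inputs (0-based half-open) are converted on read. Indels
are VCF-anchored (ref and alt share their first base) and left-aligned
against the reference before any repeat-dependent classification,
because tandem-repeat counting depends on the representation. Track
lookups beyond the first/last data point return the nearest endpoint
value (clamped extrapolation); interpolation is defined only between
data points. When several replication-timing files are averaged they
are inner-joined on identical intervals — the tracks are assumed to
share one grid; tracks on different grids should be resampled upstream.

The caller consumes pre-summarized allele-count tables rather than
alignments. Producer-side read filtering (a base-quality cutoff of 30
is the recorded expectation) is deliberately out of scope and carried in
`CallerConfig.producer_base_quality` for provenance only.

## Unique-mutation calling

Candidate filter (all three must hold): mutated-sample alt-allele
frequency ≥ `min_alt_vaf` (0.2), mutated-sample coverage ≥ `min_cov`
(5), and reference-allele frequency ≥ `min_other_ref_af` (0.93) in
*every* other sample. A sample missing at a position counts as coverage
0 and fails the third test: absence of evidence never supports a unique
call. Multi-allelic sites emit only the most frequent alt allele, ties
broken alphabetically (A<C<G<T) for determinism.

Quality score: with the candidate's counts (a, c) and the counts
(a', c') of the other sample with the lowest reference-allele
frequency, the score is `−log10 p` with `p` the hypergeometric
upper-tail probability `P(X ≥ a)` for the 2×2 table `[alt, ref] ×
[candidate, other]`. The tail is directional: when `a/c ≤ a'/c'` the
data carry no evidence of excess and `p = 1`, so identical count pairs
score exactly 0 and the score is monotone non-decreasing in the alt
count. Zero coverage on either side returns score 0 with a degenerate
flag. The implementation uses `scipy.stats.hypergeom.sf`; the test
suite checks it against integer-combinatorics enumeration over the
complete coverage ≤ 20 grid (agreement ≈ 2e−15).

Threshold calibration: candidate thresholds are 0 plus the observed
scores (any value between two observed scores filters identically). The
accepted threshold is the smallest at which every ancestral clone keeps
at most `ancestral_fp_fraction` (1%) of each of its descendants'
surviving SBS calls, or at most `ancestral_indel_cap` (5) indel calls.
If no threshold satisfies the constraint, +inf is returned with a
warning rather than silently keeping unbounded false positives. Note
that at the fixed default SBS threshold of 3.5 (≈ p 3×10⁻⁴), a
heterozygous site whose binomial alt draw is low (e.g. 9 of 30 reads)
scores below threshold, which caps recall near 0.92 at 30× Poisson
depth; the calibrated pipeline does not have this ceiling and is the
recommended (and tested) configuration.

## Spectrum classification

SBS96: substitutions are expressed on the pyrimidine strand (purine
references reverse-complemented with their flanks); channel order is
C>A, C>G, C>T, T>A, T>C, T>G blocks of 16, 5' then 3' flank
alphabetical. The mapping from the 192 oriented inputs onto 96 channels
is exactly 2-to-1 (enumerated in the tests).

ID83: 1 bp events are typed by the deleted/inserted pyrimidine (C/T
after complementing) and the homopolymer run length at the
(left-aligned) site — deletions subscripted by run length 1…6+,
insertions by reference run length 0…5+. Events of ≥ 2 bp are typed by
length (2/3/4/5+) and tandem copies of the indel unit counted rightward
from the left-aligned position (the deleted copy itself is included for
deletions). Deletions with no tandem copy are classified by
microhomology: the longest prefix of the deleted sequence matching the
sequence after it, or suffix matching the sequence before, capped at
length−1. Events whose chromosome is absent from the genome are
excluded and counted, never silently dropped.

Context logos: the background is 10 random positions per mutation drawn
uniformly within ±1 kb (controls for local composition); draws whose
±flank window leaves the chromosome are redrawn so observed and
background context lengths match. Scores are
`log2((f_obs + ε)/(f_bg + ε))` per position and base with a pseudo-count
of ε = 0.5 observations (avoids log 0 on small sets; configurable),
median-centred over the four bases per position (an
enrichment/depletion logo). Background positions are *not* filtered for
reference-base identity with the mutated base; with such filtering the
logo would measure context conditional on the central base instead of
total composition, and the unconditional form is what the ±1 kb
background is meant to control.

## Signature refitting and extraction

Refitting is non-negative least squares (`scipy.optimize.nnls`), exact
for this convex problem; exposures carry mutation-count units when the
spectrum holds counts. Strict refitting iterates: fit, evaluate the
reconstruction cosine of every leave-one-out subset, and remove the
signature whose removal costs the least cosine, while that per-step
cost is < `max_delta` (default 0.004); ties go to signature order; the
final fit runs on the survivors and removed names are reported. With
`max_delta = 0` no removal is accepted and the result equals the plain
fit. Strict pruning deliberately sacrifices small true contributors
(≈ ≤ 10% broad components can be dropped) for parsimony — this is the
intended behaviour of strictness, not an artefact.

De novo extraction uses multiplicative-update NMF under Frobenius loss:
best of `n_starts` (default 200) seeded restarts, stopping when the
relative error improvement falls below 1e−6 or at 2000 iterations.
Signature columns are normalized to sum 1 with exposures rescaled, so
exposures stay in catalog units; results are bit-reproducible for a
fixed `random_state`. The rank k is a user decision; `SignatureNMF.scree`
reports reconstruction error over candidate ranks but performs no
automatic selection. NMF runs on counts, not frequencies, so
higher-burden samples legitimately weigh more. A caveat on recovery:
NMF can only recover a planted signature whose vertex the data cone
approaches; if every sample is a well-mixed combination (no near-pure
sample), the Frobenius optimum lies strictly inside the cone and
per-signature cosines saturate below 1 regardless of restarts.

Difference spectra are computed on per-population-doubling normalized
counts (`high/doublings_high − low/doublings_low`), floored at zero and
renormalized to sum 1; the number of floored channels is reported so the
flooring is auditable. Per-doubling normalization is used because the
culture rates themselves are expressed per doubling. The two-component
decomposition refits stratum spectra (e.g. replication-timing deciles)
against the normalized baseline and difference components, with a
collinearity warning when the components are numerically parallel. No
free intercept is fitted.

## Genome context

Replication timing at a position is the linear interpolation between
the nearest track points, clamped at chromosome ends. Decile cuts are
the empirical 0.1…0.9 quantiles of the reference score set — computed
over track points, not over genomic base pairs — with left-closed bins;
deciles of fewer than 10 distinct scores are refused. The source-track
convention (higher score = earlier replication) is preserved, and
annotated deciles are reported with decile 1 = earliest; the
orientation is written into CLI output headers to prevent silent flips.

RFD per 1 kb window is `(R − L)/(R + L)` (the normalized difference of
rightward- and leftward-fork evidence — normalization makes windows
comparable across coverage and gives the ±0.5 stratification bounds
meaning); empty windows are missing values, not zeros. Strand calls are
made in pyrimidine representation: positive RFD means a rightward fork,
under which the plus strand is the lagging-strand template; a
pyrimidine on the minus strand flips the call, RFD 0 or missing is
unassigned. Transcriptional strand: under a single-strand gene
footprint, a pyrimidine on the template strand is "transcribed", on the
non-template strand "untranscribed"; positions under genes of both
orientations are "ambiguous" and excluded from bias tests (no strand is
defined), positions under no gene are "intergenic".

Strand-bias tests are one-degree-of-freedom χ² against a 50:50
expectation with two-sided tail; the RFD-stratified analysis partitions
mutations into `RFD ≤ −0.5`, `−0.5 < RFD < 0.5` (open interval;
boundary values go to the flanking strata) and `RFD ≥ 0.5` and tests
per substitution class within each stratum. The synthetic confounding
drill in the tests plants a purely replication-linked asymmetry with
genes co-directional to forks and verifies the expected signature:
apparent transcriptional bias in the strong-RFD strata, none in the
middle stratum. Genic/intergenic densities use the strandless union of
transcript footprints; overlapping transcripts count territory and
mutations once.

## Clonality and group statistics

The clonal/subclonal split is two-centre k-means on raw VAFs (not
histogram bin centres). In one dimension the optimal assignment is a
split of the sorted values, so the estimator scans all n−1 split points
with prefix sums and takes the global optimum directly — deterministic,
O(n log n), and by construction a fixed point of Lloyd iteration
(iterative Lloyd from quantile initialization can stall in local optima
on skewed mixtures). The border is the midpoint of the two cluster
means, the upper cluster is "clonal", and samples with fewer than 300
clonal or subclonal mutations are flagged excluded. At centre
separation 0.15 and read depth 60 the labeled clonal fraction carries a
small systematic bias (the variance-minimizing border is pulled toward
the tighter cluster), ≈ 1.5 percentage points on average over seeded
replicates; at separation 0.25 recovery is within 1%.

Mutation rates: `doublings = days × 24 / doubling_time_hours`,
`rate = n / doublings`, optionally per megabase with a user-supplied
genome size (required; no default is assumed). Group comparisons use
two-sided t-tests: unpaired pooled-variance by default (Welch behind
`equal_var=False`, the choice reported in the output), paired for
within-sample clonal-vs-subclonal signature contributions, which are
normalized to relative contributions per compartment before testing.

## Synthetic data: what it emulates and what it does not

The generators mirror the emulated study design: one ancestral clone
plus descendants (default 4), 60 days of culture, ~30× Poisson
sequencing depth, heterozygous unique mutations at VAF 0.5 with
binomial read sampling, per-base error rate 0.001, shared ancestral
variants present in all samples, signature-mixture catalogs drawn
multinomially and realized at genome positions whose triplet context
matches the channel, alternating fork fields with known orientation,
cosine timing waves, and bimodal VAF mixtures. The shipped signature
fixture (`data/synthetic_sbs96_signatures.tsv`) is synthetic: a broad
background, an MMRd-like C>T/T>C-heavy component, and an oxygen-like
component concentrating 72% of its mass on the A[T>C]A, G[T>C]A,
G[T>C]T and T[T>C]A channels — the contexts that respond most to
oxygen in MMRd cells. In the two-condition cohort drill the oxygen-like
component is entirely absent from low-oxygen samples, matching the
experimental contrast.

Not modelled: mapping bias and alignment artefacts, error-rate context
dependence, copy-number variation, read-level data. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated sampling models, not robustness to alignment- or
library-level artefacts of real sequencing data.

Problem sizes in the shipped tests and acceptance script are desk-scale
by design: toy genomes of 20–500 kb, catalogs of 2,000–10,000
mutations, cohorts of 8 samples, 10⁴ null replicates for test
calibration, 100 seeded strict-refit trials, and the complete
coverage ≤ 20 score grid (53,361 count configurations).

## Known limitations

- Indel candidate records from count tables carry class and VAF but not
  the indel sequence (the count format aggregates ins/del evidence), so
  ID83 classification applies to fully specified indel records (e.g.
  from VCF), not raw caller output.
- Strict refitting is greedy; it does not guarantee the globally
  minimal surviving subset, only one whose per-step cosine cost stayed
  below `max_delta` (the exhaustive-subset comparison in the tests
  covers small reference sets).
- The cohort path for real cancer data (reference-set substitution,
  MMRd sample selection at > 1000 attributed mutations, clonal/subclonal
  signature comparison) is implemented and unit-tested on synthetic
  exposures, but has not been exercised against the external cohort
  downloads it would consume in production.
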
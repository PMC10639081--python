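# isomutsig

Mutational-signature analysis of isogenic clone-sequencing experiments,
built around the question of how culture oxygen shapes mutagenesis in
mismatch-repair-deficient (MMRd) human cells. The package is aimed at
groups running long-term clone-expansion mutation-accumulation
experiments (one ancestral clone, several sequenced descendants) and at
anyone refitting or extracting single-base-substitution (SBS) and indel
(ID) mutational signatures, relating mutations to replication timing and
fork direction, or decomposing mutation sets into clonal and subclonal
compartments.

## What it does

**Unique-mutation calling in isogenic sets.** At every genomic position,
per-sample allele counts are compared across the whole set; sample *s*
gets a candidate call iff

1. its most frequent non-reference allele has frequency ≥ 0.2,
2. its coverage is ≥ 5, and
3. every other sample's reference-allele frequency is ≥ 0.93.

Each candidate is scored `S = −log10 p`, where `p` is the one-tailed
Fisher exact (hypergeometric upper-tail) probability of the candidate's
alt count against the other sample with the lowest reference-allele
frequency; when the candidate's alt frequency does not exceed that
sample's, `p = 1`. Class-specific score thresholds (defaults 3.5 SBS,
2.1 insertions, 3.1 deletions) can be recalibrated on the data so that
no ancestral clone retains more than 1% of any descendant's SBS calls
(absolute cap of 5 for indels) — ancestral clones carry no true unique
mutations, so their surviving calls estimate the false-positive load.

**Spectra.** SBS calls are classified into the standard 96 triplet
channels (pyrimidine-strand representation, blocks C>A…T>G, flanks
alphabetical); indels into the 83 COSMIC v3 channels (length,
homopolymer run, tandem-repeat copies, microhomology), with left
alignment before repeat counting. Extended-context enrichment logos use
a background of 10 random positions per mutation drawn within ±1 kb,
log2 observed/background frequency ratios, median-centred per position.

**Signature refitting and extraction.** `refit` solves
`argmin ‖m − S·e‖₂, e ≥ 0` (non-negative least squares) for a spectrum
`m` and signature matrix `S`; `refit_strict` additionally prunes, one
per iteration, the signature whose removal costs the least
reconstruction cosine while that cost stays below `max_delta`
(default 0.004). `SignatureNMF` extracts de novo signatures by
multiplicative-update NMF (Frobenius loss, 200 seeded restarts by
default, bit-reproducible). `difference_spectrum` subtracts
per-population-doubling rates between conditions, floors at zero and
renormalizes — the oxygen-effect spectrum; `two_component_fit`
decomposes stratified spectra into a baseline and a difference
component.

**Genome context.** Replication-timing lookup by linear interpolation
with decile binning (decile 1 = earliest); replication fork
directionality `RFD = (R − L)/(R + L)` per 1 kb window from OK-seq
counts; leading/lagging and transcribed/untranscribed strand assignment
in pyrimidine representation; χ² strand-bias tests, RFD-stratified to
separate replicative from transcriptional asymmetry; genic/intergenic
mutation densities.

**Clonality and rates.** 1-D two-centre k-means on variant allele
frequencies, solved exactly by a split-point scan (the border is the
midpoint of the two cluster means; samples with < 300 clonal or
subclonal mutations are flagged excluded); mutation rates per population
doubling (`doublings = days·24 / doubling time`); unpaired/paired
t-tests and per-signature clonal-vs-subclonal comparisons.

**Synthetic data.** Every input above can be generated with planted
truth: isogenic count tables at ~30× Poisson depth with 0.001 per-base
errors, signature-mixture catalogs realized at context-matched genome
positions, smooth timing waves, alternating fork fields, bimodal VAF
mixtures. All generators are pure functions of their seed.

## Worked example

```python
from isomutsig import *

# 1) call unique mutations in a simulated isogenic set (1 ancestor + 4 clones)
genome = gen_genome(60_000, gc_fraction=0.4, seed=1)
cfg = SimulationConfig(rng_seed=1, genome_length=60_000, planted_per_sample=100)
counts, truth = gen_isogenic_counts(genome, cfg)
ancestry = AncestryMap({"anc": {"d1", "d2", "d3", "d4"}})
calls = [r for r in call_unique_mutations(counts, ancestry=ancestry, calibrate=True)
         if r.mut_class == "SBS"]
print(f"planted: {len(truth)}  called: {len(calls)}")

# 2) build a spectrum from a signature-mixture catalog and refit it
sigs = load_synthetic_signatures()
catalog = gen_catalog(sigs, exposures=[0.1, 0.6, 0.3], n=5000, genome=genome, seed=1)
spec, _ = build_spectrum(catalog, {"chr1": genome}, "SBS96")
fit = refit(spec.to_series(), SignatureMatrix(sigs))
print(f"reconstruction cosine: {fit.reconstruction_cosine:.4f}")

# 3) split a bimodal VAF distribution into clonal/subclonal
vafs, _ = gen_vaf_mixture(2000, clonal_fraction=0.5, centers=(0.25, 0.5),
                          depth=60, seed=1)
split = split_clonal_subclonal(vafs)
print(f"border VAF: {split.border_vaf:.3f}  clonal: {split.clonal_count}")
```

prints

```
planted: 400  called: 400
reconstruction cosine: 0.9981
border VAF: 0.376  clonal: 988
```

All 400 planted heterozygous mutations are recovered with no false
positives; the refit recovers the planted 10/60/30 exposure mixture
(8.5/61.9/29.6 here, multinomial sampling noise at n = 5000); the VAF
border lands between the subclonal (0.25) and clonal (0.5) centres and
the 50:50 split is recovered within 1%. Note that `refit_strict` on the
same spectrum drops the broad 10% background component — strict pruning
deliberately trades small contributors for parsimony.

A `isomutsig` command-line tool wraps the same functions
(`simulate`, `call`, `spectrum`, `fit`, `nmf`, `context`, `clonality`,
`rates`); every subcommand is a thin shell over the library.

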
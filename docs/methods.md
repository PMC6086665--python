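# Methods

## The kinetic model

At steady state a transcript's abundance obeys

    d[mRNA]/dt = alpha - beta [mRNA] ~ 0   =>   beta ~ alpha / [mRNA]

where alpha is the production (transcription) rate and beta the first-order
degradation rate. Metabolic labeling (a short 4sU pulse followed by pulldown
and sequencing) measures nascent transcription, a proxy for alpha; standard
total RNA-seq measures [mRNA]. The package's **relative stability score** is
therefore

    stability = log2( (total CPM + c) / (nascent CPM + c) )

which equals -log2(beta) up to a per-sample additive constant. Only ranks
and differences of this score are meaningful; no absolute half-lives in time
units are produced. **Translation level** is the analogous ratio of
high-polysome to monosome CPM from sucrose-gradient fractionation, and
**translational efficiency (TE)** the ratio of ribosome-protected footprints
to total mRNA. Replicates are paired by replicate index; with unequal
replicate numbers the mean over all cross pairs is used.

The pseudocount c = 0.5 CPM bounds the ratio for genes with zero counts in
one assay without materially perturbing genes that pass the expression
filter (CPM >= 3 in >= 3 samples, counted over the samples entering the
given analysis). In the exact noise-free limit the pseudocount itself
perturbs ranks at very low CPM, so the noiseless oracle tests use c = 0.

## Differential testing

Genotype differences in any log-ratio are tested per gene with the
interaction term of the two-factor linear model on y = log2(CPM + c):

    y = b0 + b1 * assay + b2 * genotype + b3 * (assay x genotype)

b3 is the log2 fold-change of the ratio (stability, translation level, or
TE) in the test genotype relative to the reference. The fit is ordinary
least squares with the exact t-test (df = n - 4); this replaces the
empirical-Bayes moderated t of limma-style pipelines because it is fully
specified, oracle-testable against an explicit normal-equations solve, and
calibrated (the null simulation puts the 5% rejection rate at 0.050 and the
KS distance of the p-values from U(0,1) below 0.01 at 5,000 genes). An
optional `shrink_var=True` pools residual variances toward a moment-matched
scaled-inverse-chi-square prior (moderated t with df + d0); it is off by
default. Replicates are treated as unpaired — the simplest model consistent
with the two-factor design. P-values are Benjamini-Hochberg adjusted across
the genes of one contrast. Genes with (numerically) zero residual variance
cannot be tested and are flagged with p = NaN.

Because CPM renormalisation makes each sample sum to 10^6, a genotype
effect confined to a sizeable gene subset shifts every gene's interaction
coefficient by a common composition constant. All group-level readouts
therefore use the **target-minus-background median shift**, which cancels
that constant; absolute per-gene coefficients should be read with this in
mind.

## Sequence features

Ten per-gene covariates: log10 lengths of 5'UTR/CDS/3'UTR, GC fraction of
each region, ARE count (occurrences of TATTTAT in the 3'UTR), upstream-ORF
count (occurrences of ATG in the 5'UTR), miRNA seed-match count, and log10
exon count. Motif occurrences are counted with overlap (the simplest
deterministic convention). A seed match is an occurrence in the 3'UTR of
the reverse complement of the miRNA seed given 5'->3' (the AAGUGC seed of
the ESCC family yields the site GCACTT). Features are z-scored before the
multiple regression so coefficients are comparable across features (R^2 is
unaffected); per-feature Spearman correlations (average-rank ties) rank
single-feature impact. Designs with condition number above 1e8 are rejected
with the offending columns named. Seed-match counting is a deliberate
simplification of conservation-aware target prediction: a user-supplied
target list can replace it wherever a target set is consumed.

## Codon optimality

Codon usage frequency is each sense codon's fraction of a gene's CDS
codons; the three stop codons are excluded from numerator and denominator
and ATG is included (the standard tAI convention). The stable/unstable
comparison takes the top and bottom 20% of genes by stability score (ties
broken by gene id; constant scores are rejected rather than arbitrarily
split), runs a two-sided Mann-Whitney test per codon, and applies
Bonferroni correction over exactly the 61 sense codons. The cross-genotype
concordance statistic is the Spearman correlation of per-codon median
differences (stable minus unstable) between two genotypes.

tRNA adaptiveness follows the dos Reis tAI construction: for each codon,
W = sum over pairing anticodons of (1 - s) * tGCN, where tGCN is the tRNA
gene copy number and s the wobble constraint of the pair. Watson-Crick
pairs have s = 0; the wobble pairs use the classic constraint values
G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68 (anticodon wobble-position A is
modeled as inosine). These values are configuration, not estimates: the
species-specific hill-climbing optimisation performed by dedicated sTAI
tools is out of scope, so sTAI values here support correlation-direction
analyses rather than absolute comparisons with published mouse values.
w = W / max(W); codons no tRNA can read receive the geometric mean of the
nonzero w and a flag. A gene's sTAI is the geometric mean of w over its
sense codons.

## Target-set statistics

Group shifts of per-gene change scores (targets vs background) use the
two-sided Mann-Whitney test: exact by exhaustive enumeration when both
groups have at most 8 members (ties counted half), otherwise the normal
approximation with continuity and tie correction. The background defaults
to the non-target complement (using all genes would count targets twice);
`background="all"` is available. Percentile fold ranges are
2^(Q(hi) - Q(lo)) with linear-interpolation quantiles on the log2 scores.
The decoupling summary assembles, per (knockout contrast x metric), the
target shift of the interaction coefficients plus cross-knockout Spearman
correlations of the per-gene changes: a factor that mediates only the
translational arm of miRNA repression shows a translation shift without a
stability shift, while a factor upstream of both arms shifts both.

## The synthetic-data generator

The generator realises exactly the model the analysis assumes, so
parameter recovery is a meaningful end-to-end test:

- Per gene: log2(alpha), log2(beta), log2(t) independent normal with SDs
  1.0, 1.5, 1.0 (log2 units). A correlation knob tilts log2(t) toward
  -log2(beta) (default 0; the two-knockout study uses 0.3 to emulate the
  positive stability-translation coupling of real transcriptomes).
- Expected relative abundances: nascent ∝ alpha; total ∝ (alpha/beta) s;
  monosome ∝ mRNA/(1+t'); high polysome ∝ mRNA t'/(1+t'); low polysome a
  configurable mixture of the two (default weight 0.5, simulated but unused
  by the default analysis); RPF ∝ mRNA t'. Here s is the genotype's
  stability effect (fold-change of 1/beta), t' = t times the genotype's
  translation effect, and effects differ from 1 only for target genes in
  knockout genotypes. Note nascent RNA carries no stability effect — a
  stability change alters steady-state abundance, not production.
- Counts: each sample's abundances are scaled to 2e6 reads, multiplied by a
  log-normal library jitter (SD 0.2 log2 units), and drawn negative-binomial
  via a gamma-Poisson mixture with variance mu + phi mu^2 (phi = 0.05 by
  default; phi = 0 degenerates to Poisson). 3 replicates per (assay,
  genotype). `expected_counts` gives the noise-free limit used by the
  steady-state identity tests.
- Sequences: region lengths log-normal (medians 150 nt 5'UTR, 400 codons
  CDS, 800 nt 3'UTR), i.i.d. bases at the target GC (0.45). The CDS starts
  ATG, contains no internal stop and ends with a stop. Target genes get 2
  planted seed sites in the 3'UTR; ARE and upstream-ATG plant counts are
  Poisson with rates multiplied by 2^(coupling * z_beta), and the 3'UTR
  length median can shift with z_beta, giving the feature analyses
  programmable signal. Planting overwrites non-overlapping windows and
  errors if the region cannot host the motifs.
- The codon spike study generates genes of variable length (log-normal
  around 300 codons) with uniform sense-codon usage and adds a fixed
  increment to one codon's frequency in the unstable half (renormalised).
  Variable lengths matter: with a fixed length all frequencies sit on one
  lattice of multiples of 1/L, and the renormalisation then turns the
  huge tie mass into systematic rank wins, inflating false positives in a
  way real, length-heterogeneous transcriptomes do not show.

What the generator does not emulate — and hence what passing tests do not
establish about real data: positional read coverage and codon-resolution
ribosome occupancy; 4sU labeling-efficiency and pulldown biases beyond a
sample-level scale factor; real codon-usage bias and its coupling to
expression; UTR secondary structure; correlated feature distributions
(features here are nearly independent by construction); batch effects.

## Problem sizes and determinism

The validation studies (`mrnastab.validation`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) use 2,000 genes for
the recovery and decoupling studies (300 targets), 5,000 genes for the
null calibration and feature regression, 20 runs of 800 genes for the codon
spike, and 200/100/100/20 random instances for the oracle comparisons —
sizes at which the measured quantities are stable to well within their
acceptance bands across seeds. Every random draw flows from a single
`numpy.random.default_rng` seed; identical configuration and seed give
byte-identical pipeline outputs.
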
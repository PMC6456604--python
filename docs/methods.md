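# Methods

`clipseed` reimplements, on synthetic ground truth, the analysis chain that
turns AGO-CLIP sequencing data into a map of miRNA target sites with a
measured signal-to-noise ratio: UMI-aware read processing, midpoint peak
calling, diagnostic-event (DE) cluster formation, kernel-density crosslink
inference, seed-match assignment anchored on the crosslink, decoy-based
benchmarking, and a knockdown de-repression readout. This note records the
model, the parameters that matter, and the numerical and design choices.

## The generative model

**Transcriptome.** Transcripts are 5'UTR + CDS + 3'UTR in transcript
coordinates (no genomic splicing; spliced-read handling is still exercised
by constructed alignments). 3'UTRs are AU-rich (default AU fraction 0.6,
typical of fly 3'UTRs); UTR/CDS lengths are uniform in (60,150), (300,900)
and (240,600) nt. Per-transcript expression is log-normal and weights
background read placement.

**miRNA pool.** Mature sequences are random 22-mers with pairwise-distinct
seed heptamers (positions 2–8). Expression is a two-component log10-normal
mixture (component means 0.5 and 3.0, sd 0.5, equal weights); the upper
component models the CLIP-engaged subset, and the mixture fit downstream
must resolve it.

**Planted sites.** Canonical sites (8mer-A1 : 7mer-m8 : 7mer-A1 : 6mer =
0.25 : 0.35 : 0.30 : 0.10 by default) are written into 3'UTRs uniformly at
random, at least 25 nt from each other, with flanking bases adjusted so the
seed matcher reports exactly the planted type. Placement is resampled when
the edit would create a canonical match of any *other* pool miRNA within
±25 nt. Each site receives a crosslinkable T at an offset drawn from a
discrete distribution over {−5..0} with mode at −1/−2 (mean ≈ −2); the
mode position mirrors the observed concentration of conversions just 5' of
seed matches, and the exact shape is a modeling choice — no parametric
form is reported for real data.

**Reads.** Signal molecules cover their site's crosslink at a uniform
interior read position (read length uniform in 26–36 nt, minimum accepted
length 16 nt); background molecules (30% of reads by default) land
uniformly on expression-weighted transcripts and crosslink at a random
interior T. Per molecule, a T-to-C conversion is applied with the protocol
probability (PAR 0.80, HITS 0.016) or a T-deletion (PAR 0.005, HITS
0.0083); the PAR and HITS defaults are the published per-read DE rates for
the two protocols. Each molecule gets an 8-nt UMI (4+4 randomized adapter
ends), a geometric PCR copy number (mean 1.7), and each copy receives
independent per-base sequencing errors (rate 0.001). UMIs are i.i.d. over
the 4^8 space: global uniqueness is impossible beyond 65 536 molecules,
and only per-coordinate collisions (~1/65 536) would matter to the
grouping rules.

What the generator does **not** emulate: adapters and quality scores,
genomic multi-exon coordinates, rRNA contamination, alignment ambiguity
(multimapper resolution is exercised on constructed inputs only), 4SU
incorporation biases, and spike-in normalisation. Passing tests therefore
demonstrate the correctness and calibration of the analysis machinery on
data with the stated statistical structure, not performance on real
libraries.

## Read processing

Processing order is fixed and idempotent: (1) collapse reads identical in
sequence+UMI, accumulating copy numbers; (2) within each (reference,
start, end, strand, UMI) group, sort by copy number and remove reads whose
event fingerprint (position, outcome) strictly contains the top-copy
read's fingerprint at lower copy number — the classic PCR+sequencing-error
shadow; equal copy numbers are never removed (ties destroy no evidence)
and the strict-superset reading is deliberately minimal, so an error that
*replaces* an existing event's outcome is outside its reach; (3) drop
reads with any event in read positions {1,2} or {L−1,L} in read
orientation; (4) drop reads shorter than 16 nt. Multimapper resolution
(keep the best alignment only when the runner-up has >1 extra mismatch)
sits upstream of this artifact's simulated data but is implemented and
tested on constructed candidate sets.

## Peak calling

Peaks are called on read midpoints (spliced reads: the read-space midpoint
projected through the block structure), binned at 20 nt per reference and
strand. A zero-truncated negative binomial (ZTNB) background is fit by
maximum likelihood (method-of-moments start, L-BFGS-B on (log r, log μ)
with r bounded in [0.05, 10^4] — the r→0 ridge is a degenerate log-series
fit that a contaminated sample otherwise falls into). The fit uses the
lowest 95% of bin counts; when reference lengths are available the 95%
cutoff is taken over *all* bins of the binned input space (zeros
included), which keeps the background estimate clean even when bound sites
occupy a sizeable share of the non-zero bins, as they do at desk scale.
Per-bin upper-tail probabilities P(X ≥ x | X ≥ 1) are Benjamini–Hochberg
adjusted and thresholded at 0.01; adjacent significant bins merge into
peaks ranked by read count. BH adjustment (rather than raw p < 0.01) is
what makes "a single spiked bin is the only call among 500 background
bins" a reliable property and keeps the false-call rate at or below the
nominal level.

Replicate reproducibility uses a rank-consistency proxy for IDR: peaks
pairing across replicates with intersection ≥ 0.1 × the smaller peak are
scored by the geometric mean of their within-replicate read-count ranks,
and the top n pooled union intervals are kept (named presets store the
study-scale cut-offs, HITS n = 8971 and PAR n = 11 667). The proxy keeps
IDR's only role here — choosing a top-n cut — without the copula
machinery.

## Clusters and crosslink inference

A peak with ≥ 2 DEs of the configured class (T-to-C by default; T-to-V
and T-to-V+T-del available) is a cluster; edges are trimmed inward while
coverage < 5 reads. T-to-C conversion specificity (T-to-C over all
T-reference mismatches) supports the ≥ 0.6 filter. DE counts are smoothed
with a Gaussian kernel (bandwidth 3 nt, the PARalyzer-style convention;
the method is named in the source analyses but not the bandwidth),
evaluated at integer positions and normalised to unit mass; the crosslink
is the profile argmax (leftmost on exact ties) and the coverage summit the
raw-coverage argmax. Note that two equal DE spikes closer than roughly
2.6σ produce a *midpoint* maximum — that is the correct KDE argmax, not a
tie.

## Positional-preference statistics

Peaks (extended ±5 nt) with exactly one 7mer/8mer match of the query
miRNA set anchor a ±25 nt window at the match start (the 5'-most target
nucleotide). Per DE type and window, the position of maximal DE occurrence
(leftmost tie rule) is recorded; the statistics are the mean absolute
distance of these maxima to the anchor and the Gini coefficient of the
maxima histogram (concentrated maxima ⇒ high Gini; the Gini-sided
empirical p therefore counts shuffles with Gini ≥ the true value — the
source text's "higher 1/Gini" phrasing is inverted for a concentration
statistic, and the concentration direction is implemented). The null
rebuilds the identical pipeline 1000 times with dinucleotide-shuffled
decoy miRNAs; empirical p = (1 + #{shuffles ≤/≥ true})/(N+1), effect size
= median shuffled mean distance / true mean distance.

## Seed assignment

Canonical matching is exact Watson–Crick complementarity of the target to
miRNA positions 2–7/2–8 with the optional A1 adenosine anchor; every core
occurrence is reported once with the most specific supported type.
Nucleation-bulge sites pair positions 2–8 with one extra target
nucleotide between the bases pairing positions 5 and 6; by default the
bulged nucleotide must itself pair the pivot (position 6), and the
constraint is toggleable.

The crosslink-to-seed offset model is learned from clusters with exactly
one 7mer/8mer match of the enriched miRNAs (mean and variance of crosslink
− match start; variance floored at 0.25 so a concentrated training set
cannot collapse the kernel; fallback mean −1/variance 4 with a warning
below 30 training clusters). A candidate site s in a cluster (±5 nt) is
scored by the Gaussian-kernel concordance

    score(s) = Σ_p smoothed(p) · exp(−(p − start(s) − μ)² / (2v)),

the fraction of smoothed DE mass inside a width-√v window at the expected
offset. The hidden-Markov machinery of the original assignment tool is
replaced by this explicit positional-likelihood scorer: it reproduces the
decision shape (one best candidate per cluster, variance-controlled
stringency) while being fully specified here; its variance axis is
order-preserving but not numerically identical to an HMM emission
variance. In viterbi-style mode the best-scoring accepted candidate wins
(ties: leftmost start, then lexicographic miRNA id).

**Acceptance threshold.** A candidate is accepted when score ≥ c with
fixed c = 0.05. A threshold that instead moves with the variance (e.g.
"the score of a site 6 nt off") is not monotone for mixture-valued
profiles: as v → 0 any sliver of profile mass near the expected offset
dominates such a threshold and stringency inverts. Because score(s) is
pointwise non-decreasing in v, a *fixed* c makes the accepted sets nested
across variance levels, so decreasing the variance provably never
increases the number of predictions — the monotone-stringency law the
benchmark sweep relies on. c = 0.05 sits between the concordance of a
well-anchored cluster (~0.23 at v = 0.5 under bandwidth-3 smoothing) and
that of a uniform profile (~0.04); it is configurable.

Predictions collapse across isoforms and seed families (family = shared
positions 2–8; representative = lexicographically smallest id), and
reproducible predictions are the intersection of collapsed (coordinates,
family) keys across replicate runs.

## Decoy benchmarking

Decoys are dinucleotide shuffles of the true miRNAs via the Euler-path
construction (exact mono- and dinucleotide multiset, first and last
nucleotide preserved), rejected and resampled while positions 3–7 equal
any true miRNA's positions 3–7 (the strictest reading: it prevents
6mer-level collisions; default one decoy per miRNA for SNR sweeps, 1000×
for positional nulls). Each of (by default) 100 repetitions regenerates
decoys from a derived sub-seed and reruns assignment on the combined
true+decoy pool; SNR = #true/#decoy predictions (reported +∞ when no
decoy predicts), sensitivity = clusters with a true prediction / clusters,
specificity = true/(true+decoy) ≡ SNR/(SNR+1). The
matches-anywhere-in-cluster baseline drops all positional information.
Rank-binned evaluation (bins of 1000 by default; trailing partial bin
retained) tracks how prediction certainty decays down the cluster ranking.

**Signal-free calibration.** Without planted signal the ZTNB caller
correctly calls (close to) nothing, so null runs form clusters on
fixed-width tiling windows (`tile_windows`), trimmed and smoothed exactly
as real clusters. The null SNR is averaged over several independent query
pools (4 pools × 25 repetitions), not just shuffle repetitions of one
pool: a single 30-miRNA pool's chance-match count is one random draw
whose ±15% fluctuation would otherwise dominate the type-I anchor.

## Knockdown readout

Expected RNA log2 fold change (depleted vs control) of a gene is the sum
of its planted sites' per-type effects (defaults 8mer-A1 0.35, 7mer-m8
0.25, 7mer-A1 0.20, 6mer 0.10 — ordered 8mer ≥ 7mer ≥ 6mer); ribosome
footprints inherit the RNA effect plus a translational component (+0.25)
for a random 10% of genes. Counts are negative binomial (dispersion 0.1,
≥ 2 replicates). Analysis uses median-of-ratios size factors and
pseudocount-1 log2 fold changes of replicate-mean normalised counts —
deliberately simple, because the readout is fold-change CDFs per stratum
(by site count {1,2,3,4,>4}, by seed class among single-site genes, by
miRNA) against the zero-prediction background, compared with the
two-sided two-sample Kolmogorov–Smirnov test (asymptotic by default,
exact for small groups; at n per group ≈ 6 the asymptotic p can differ
from the exact permutation p by ~0.15 in the mid-range, so small strata
should use the exact mode).

## Diagnostic-event rate round trip

The round trip (protocol probabilities in, measured read fractions out,
binomial 99% CI at 10^5 reads) is run with the sequencing-error channel
off: errors are an orthogonal channel whose handling is verified by the
error-removal fidelity tests, and the ~0.2% of surviving single-copy
error reads they contribute would otherwise be conflated with the
protocol's 1.6%/0.83% HITS rates.

## Problem sizes and determinism

Standard analyses run at 300 transcripts / 30 miRNAs / 500 planted sites
(~36 000 raw reads), the rate round trips at 10^5 molecules, the
positional null at 50 × (25 transcripts, 12 000 molecules, 200 shuffles),
chosen so the full suite and the acceptance script each complete in a few
minutes on one CPU while every statistical check retains comfortable
power. All randomness derives from one integer seed; each stage derives a
dedicated sub-stream (`SeedSequence([seed, stage])`), so stages are
independently reproducible, and fixed-seed runs are byte-identical,
including emitted SAM (header restricted to @HD/@SQ for that reason).

## Known limitations

Transcript-space only; plus-strand simulation (minus-strand ingestion and
orientation rules are covered by constructed alignments); the offset
distribution and per-site read depth are modeling choices calibrated only
qualitatively; the assignment scorer's variance axis is not numerically
comparable to an HMM emission variance; very small assignment variances
(≤ 0.01) are maximally strict under bandwidth-3 smoothing and can drive
sensitivity toward zero; the knockdown normalisation is a stand-in for
spike-in calibrated differential expression.
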
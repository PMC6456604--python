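# clipseed

Mapping functional miRNA target sites from AGO-CLIP data — as a fully
testable pipeline on synthetic ground truth.

miRNAs guide Argonaute (AGO) to partially complementary sites, mostly in
3'UTRs, where pairing of the miRNA *seed* (positions 2–7/2–8) defines the
canonical site types 6mer, 7mer-A1, 7mer-m8 and 8mer-A1. Crosslinking and
immunoprecipitation (CLIP) narrows the search from whole 3'UTRs to ~30–40
nt AGO footprints, but a footprint does not name the bound miRNA. The key
single-nucleotide evidence is the *diagnostic event* (DE): reverse
transcription across the UV-crosslinked uridine leaves T-to-C conversions
(dominant in the 4SU/PAR protocol) or T-deletions (HITS protocol) that
concentrate a few nucleotides 5' of the seed match. `clipseed` turns that
evidence into miRNA–site assignments and measures how trustworthy they
are:

1. **Simulate** a transcriptome, a miRNA pool with bimodal log-expression,
   planted seed matches with known crosslink offsets, and CLIP reads with
   UMIs, PCR duplicates and sequencing errors (the answer key is emitted
   alongside).
2. **Process** reads: UMI collapse, removal of PCR/sequencing-error
   shadows within (coordinates, UMI) groups, end-mismatch and length
   filters, multimapper resolution.
3. **Call peaks** on read midpoints with a zero-truncated
   negative-binomial background and Benjamini–Hochberg control; select
   replicate-reproducible peaks by a rank-consistency criterion.
4. **Form clusters** (peaks with ≥ 2 DEs, coverage-trimmed), smooth the
   DE profile with a Gaussian kernel and take its argmax as the inferred
   crosslinked nucleotide.
5. **Assign** the most plausible miRNA per cluster by scoring each
   candidate seed match s against the smoothed profile,
   `score(s) = Σ_p smoothed(p)·exp(−(p−start(s)−μ)²/2v)`, with the offset
   model μ learned from unambiguous clusters and v the stringency knob.
6. **Benchmark** against dinucleotide-shuffled decoy miRNAs:
   SNR = #true/#decoy predictions, sensitivity, specificity
   (= SNR/(SNR+1)), swept over variance levels and 100 shuffle
   repetitions, plus DE positional-preference statistics (mean distance
   of DE maxima to seed starts, Gini concentration, 1000-shuffle
   empirical p).
7. **Evaluate function**: negative-binomial AGO-knockdown count tables in
   which de-repression adds per planted site; log2 fold changes for RNA,
   ribosome footprints and translational efficiency (TE = RiboFP − RNA),
   stratified by site count, seed type and miRNA with two-sided KS tests.

See `docs/methods.md` for the model, parameter defaults and design
decisions.

## Worked example

A small end-to-end run from the shell (every subcommand is
byte-reproducible for a fixed `--seed`):

```bash
clipseed simulate --protocol PAR --seed 7 --out-dir run \
    --n-transcripts 60 --n-mirnas 10 --n-sites 100
# wrote 7014 reads for 100 planted sites to run

clipseed process --sam run/reads.sam --out run/processed.sam
# 7014 raw -> 4221 filtered unique reads

clipseed callpeaks --sam run/processed.sam --out-prefix run/peaks \
    --regions run/regions.bed
# 99 peaks

clipseed assign --sam run/processed.sam --peaks run/peaks.tsv \
    --reference run/reference.fasta --mirnas run/mirnas.tsv \
    --out run/preds.tsv --variance 0.5
# 97 predictions on 98 clusters (offset model mean -2.03, var 1.08)

clipseed evaluate --sam run/processed.sam --peaks run/peaks.tsv \
    --reference run/reference.fasta --mirnas run/mirnas.tsv \
    --out run/eval.tsv --variances 0.5 --reps 10 --seed 7
#  variance     mode  snr_mean  ...  sensitivity_mean  specificity_mean
#       0.5  viterbi 84.125000  ...          0.985714          0.994856
#       NaN baseline 12.064707  ...          0.989796          0.918513
```

Reading: of 100 planted sites, 98 cluster-supported footprints were
recovered and 97 received a miRNA call; the learned crosslink offset
(−2.03 nt, i.e. just 5' of the seed start) matches the planted offset
distribution. Against shuffled decoys, positional scoring at variance 0.5
predicts true miRNAs 84× more often than decoys while explaining 98.6% of
clusters — versus 12× for plain anywhere-in-cluster seed matching: the
crosslink anchor, not the sequence match alone, carries the specificity.

The same steps are available in-memory via `clipseed.workflows`:

```python
from clipseed import workflows
study = workflows.run_planted_study(seed=1)         # 300 tx, 30 miRNAs, 500 sites
covered, recovered = workflows.planted_recovery(study)
print(recovered / covered)                          # ~0.93
```

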
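# Methods

## Quantitation model

Each phosphopeptide carries one reporter intensity per TMT channel per
technical replicate. Abundance is expressed as
`log2(I[sample, rep] / I[control, rep])` — the ratio is taken **within** a
replicate because technical replicates are separate labeling/injection
batches, then replicate-averaged only for the dysregulation calls. No
normalization is applied by default; an optional flag median-centers every
ratio column to 0, for loading imbalance, but is off because the analysis
the pipeline models applies none.

Filters, in order (order is provably irrelevant, and tested):

* **Localization**: a peptide is kept only if *every* one of its site
  localization probabilities is strictly greater than 0.75. "Greater than
  75%" is read literally, so a probability of exactly 0.75 is excluded; for
  multi-site peptides all sites must pass — the conservative choice for a
  convention the upstream tools leave open.
* **Completeness**: a peptide must be quantified (> 0) in every design
  channel of every replicate. An intensity of 0 encodes "not measured",
  never a measured zero, since detected reporter ions always have positive
  signal.
* **Dysregulation**: a sample call is *hyper* when the replicate-mean log2
  ratio is ≥ +1 (2-fold), *hypo* when ≤ −1, else *unchanged*. Whether the
  2-fold rule should apply to replicate means or to either replicate is an
  open convention; the replicate mean is used here as the lower-variance
  choice.

Site tallies count unique (accession, position, residue) keys across
peptides, split by S/T/Y, optionally cross-checked against the proteome
sequence. Coordinates are 1-based throughout, matching site nomenclature
such as TLN1 S425.

## Differential signature

Per peptide, a two-sided two-sample Student's *t*-test with pooled variance
compares the non-type columns (sample × replicate, 6 vs 6 under the default
design) with the luminal/basal columns. Pooled-variance *t* (not Welch) is
the convention of the desktop proteomics tools this models; a
`replicate_mean` flag tests on per-sample means instead. The signature is
defined by **raw** p ≤ 0.05 — deliberately uncorrected, matching common
practice for exploratory phosphoproteome signatures — while BH q-values are
reported in the same table so the multiplicity cost is visible. Zero
pooled-variance rows (never seen in real ratio data, but reachable in
constructed input) get a deterministic outcome: p = 1 when the group means
are equal, p = 0 with a warning otherwise.

Clustering z-scores each row (mean 0, SD 1; zero-variance rows are excluded
with a warning), uses 1 − Pearson correlation as the distance and average
linkage for rows and columns, via `scipy.cluster.hierarchy`. Supervised
mode is simply row restriction to the signature. Dendrograms export as
Newick with branch lengths equal to merge-height differences. The
hypergeometric over-representation test included here is generic plumbing
(one-sided tail, BH across sets) and makes no claim to reproduce any
proprietary pathway knowledge base.

## EMT score

For one sample, let `ECDF_Epi` and `ECDF_Mes` be the empirical CDFs of the
epithelial- and mesenchymal-set expression values (right-continuous,
evaluated at the pooled observed values, which handles ties
deterministically). With the two one-sided Kolmogorov–Smirnov statistics

```
D_epi_over_mes = max_x [ECDF_Epi(x) − ECDF_Mes(x)]
D_mes_over_epi = max_x [ECDF_Mes(x) − ECDF_Epi(x)]
```

the score is `D_epi_over_mes − D_mes_over_epi`, in [−1, +1], positive when
the mesenchymal genes sit high in the sample's expression ranking
(mesenchymal-like). The difference-of-one-sided-statistics form is chosen
because it reproduces the printed range and sign convention of ECDF-based
EMT scoring; variants that gate the score on the 2-sample-KS p-value exist,
so the p-value is reported alongside but never zeroes the score. The score
depends only on within-sample ranks: it is invariant under any strictly
increasing per-sample transform (tested by property), so expression may be
supplied on any monotone scale.

## Kinase-substrate enrichment (KSEA)

Site log2 fold-changes for a contrast (default non-type vs luminal/basal;
the contrast is an explicit parameter because conventions differ) are built
by propagating each peptide's fold-change to every site it covers and
averaging sites covered by several peptides. For a kinase with m matched
annotated substrate sites,

```
z = (m̄_s − m̄_p) · √m / δ
```

with m̄_s the substrate-site mean, m̄_p the mean and δ the population SD
(ddof = 0) of **all** site fold-changes in the input — the SD of the whole
dataset, not of the substrate subset. Two-sided normal p, BH across
kinases; the reportable flag uses the conventional plotting cutoffs
p < 0.05 and m ≥ 5. Matching is exact on (accession, position, residue);
δ = 0 (all fold-changes identical) is a degenerate-input error rather than
a silent infinity.

## Motif discovery

Windows are 15-mers (±7 residues, `_`-padded at protein termini, center
lowercased). The search is greedy and iterative: at each step, for every
unfixed offset and every standard residue (the pad character is never a
candidate), the exact binomial upper tail P(X ≥ k) of the k foreground
matches out of n foreground windows is computed against the residue's
current background frequency; the smallest p wins if p < 10⁻³ and
k ≥ the minimum occurrence (20 for serine runs, 10 for threonine).
Both sets are then reduced to matching windows. When no pair qualifies the
motif is emitted; its matches are removed from the original foreground and
the search restarts, with the background reset to the full set. The
background is the windows around *every* central-residue occurrence of the
supplied proteome. Support and fold enrichment are recounted over the
original foreground/background, so `FE = (support/|fg|) / (bg matches/|bg|)`
is exactly reproducible from the reported pattern. Determinism: p ties are
broken by larger foreground count, then smaller |offset|, then residue
alphabetical order. An (offset, residue) pair with background frequency 0
or 1 cannot be tested and is skipped.

## Synthetic-data generator

The generator emulates the study design — a 10-plex with 7 used
channels (control TERT-NHUC on 126; luminal SW780/RT112 on 130N/130C; basal
VMCUB-1 on 129C; non-type T24/J82/UMUC3 on 131/128C/128N), two technical
replicates. Control intensities are log-normal (log2 mean 20, SD 1.5, per
replicate); every other channel is `control × 2^(effect + N(0, σ))` with
σ = 0.25 on the log2 scale, so a null peptide's log2 ratio is pure
N(0, 0.25) and a planted peptide's is its effect plus that noise. Defaults:
10% planted differential peptides with |effect| = 1 (random sign) in the
non-type group; 3 planted-active kinases with 10 dedicated substrate
peptides each, all shifted +1, plus 20 null kinases with 10 null substrates
each; a planted motif residue (P at offset +1) written into the simulated
proteome next to 40% of the positively planted sites; 10% of peptides drawn
with localization probability below 0.75 and 2% with one missing channel,
to exercise both filters. Expression is N(0,1) with the epithelial/
mesenchymal sets shifted by ±shift/2 (default shift 1.5) according to each
sample's planted polarity. These defaults are desk-scale (seconds) yet
statistically resolvable — planted kinases reach z ≈ 8–9, planted peptides
are detected with sensitivity ~1 at α = 0.05.

What the generator does **not** emulate: co-isolation interference and
ratio compression, isotopic impurity, peptide-level missingness structure
beyond a single dropped channel, correlated peptides within a protein,
realistic amino-acid composition (the proteome is uniform over the 20
residues, so background motif frequencies are ≈ 0.05 everywhere), or real
transcriptome covariance. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not performance on
real mass-spectrometry output.

Records are emitted with a single phosphosite each; multi-site records are
fully supported by the formats and filters (and exercised by hand-built
fixtures in the tests) but are not needed to probe the site-level
statistics downstream.

All randomness flows from one explicit integer seed through
`numpy.random.default_rng`; no global state. Identical seeds give
byte-identical serialized outputs.

## Numerical and reproducibility choices

* Binomial, hypergeometric, *t* and normal tails come from scipy's
  log-space implementations; the test suite pins them against brute-force
  summation / closed-form oracles to ≤ 1e−10.
* Output TSV floats are serialized to 6 significant digits, which is what
  makes full reruns byte-identical.
* Problem sizes used by the test suite and the acceptance script (e.g.
  2,500 peptides for calibration, 100 seeds × 200–300 peptides for recovery
  runs, one 10,000-peptide end-to-end run) were chosen as the smallest
  scales at which the binomial error bars of the measured rates are well
  inside the asserted bands.

## Known limitations

* The uniform-composition synthetic proteome makes motif backgrounds
  maximally flat; real proteome backgrounds (e.g. proline-rich contexts)
  are harsher tests of the binomial model.
* KSEA treats substrate sites as exchangeable and independent; shared
  peptides between kinases induce correlation the normal approximation
  ignores.
* The EMT score is a two-set rank statistic; it does not model partial
  (hybrid) EMT states beyond the sign and magnitude of one number.
* The over-representation module is a generic hypergeometric test, not a
  curated pathway analysis.
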
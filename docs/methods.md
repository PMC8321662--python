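# Methods

This note documents the statistical procedure, the synthetic data model,
the numerical choices, and the known limitations of `pkdscreen`.

## Enrichment model

The pipeline quantifies a paired immunoprecipitation design: the same
biological replicate (e.g. hepatocytes from one animal) contributes one
control and one treatment sample, giving a paired control/treatment matrix
of LFQ intensities with 3 replicate pairs by default.

**Peptide filter.** Protein groups identified by fewer than 2 razor+unique
peptides are excluded (`min_razor_unique`, default 2; the retained boundary
is `count >= 2`). The filter runs *before* imputation, so excluded rows
cannot shift the imputation anchor. By default the total razor+unique
count column is used; per-sample counts can be mapped instead via the
column map.

**Imputation.** LFQ missingness is treated as left-censored (MNAR): a
missing cell is far more likely to be a low-abundance protein than a random
dropout. Missing cells are therefore drawn from N(q, σ²) in log10 space,
with q the `quantile` (default 0.05) quantile of **all observed log10
intensities pooled over both conditions and all replicates**, and σ =
`sd` = 0.1. Observed cells are never altered (bitwise). The imputation
consumes a dedicated, named RNG substream of the pipeline seed, so adding
or removing other randomised stages never changes imputed values.

**Ratios.** The matrix stays in log10 end to end; log2 ratios are obtained
by dividing log10 differences by log10 2, avoiding a double transform.
Default mode is the paired per-replicate difference averaged over pairs;
`ratio-of-means` (difference of condition means) is provided for unpaired
interpretations. The per-protein mean of all its log10 values is exported
as the scatter x-coordinate.

**Classification.** Tukey-style fences on the screen-wide ratio vector:
Q1/Q3 by linear interpolation between order statistics (the common
"type 7" rule; configurable through `quantile_method` since conventions
differ across software), IQR = Q3 − Q1. Class 2 outside the 3× fences,
class 1 outside the 1.5× fences, class 0 otherwise; the extreme fence is
tested first and classes are mutually exclusive. Inequalities are strict,
so when IQR = 0 (all ratios equal) the fences collapse onto the quartiles
and fence ties remain class 0. Fences are two-sided and a `direction` sign
(+1 upper, −1 lower) is reported; substrate nomination normally uses the
+1 side, but both are kept in the table. The classification is location-
and positive-scale-equivariant, which the test suite asserts as a property.

"Enriched" throughout the comparison stage means class 1 **or** 2.

## Motif scanning

The full PKD consensus `[L/V/I]xRxx[S/T]` is a positional constraint table
over a 6-residue window ending at the phospho-acceptor: {L,V,I} at −5, R at
−3, {S,T} at 0, wildcards elsewhere; the partial motif `Rxx[S/T]` drops the
−5 constraint (window 4). Acceptor positions are 1-based, matching the
"Ser16"-style site notation used in the literature. All overlapping
occurrences are reported; every full-motif acceptor is by construction also
a partial-motif acceptor.

Ambiguity residues (X, B, Z, U) match wildcard offsets but never a
constrained offset — an unknown residue cannot be asserted to be L/V/I, R,
S or T. The scanner operates on plain sequence; it has no notion of
phosphorylation state (the antibodies recognise the phosphorylated motif,
but sequence-level scanning mirrors what pattern-search tools do).

Implementation is a compiled lookahead regex derived from the constraint
table; the test suite checks it against exhaustive per-position enumeration
on random sequences, so the regex is convenience, not trusted ground truth.

## Known-site cross-reference

The lookup against a phosphosite repository is replaced by a local TSV
(accession, 1-based position, residue, annotation); the package performs no
network calls. The join is the exact (accession, position) pair; a
position match with a different residue is reported as a conflict, not a
match. A ±k positional tolerance exists but defaults to 0 — published
repositories and scans can disagree on isoform numbering, and silently
absorbing that with a tolerance would overstate "previously reported"
counts.

## Synthetic data model

`generate_lfq_experiment` draws, per protein, a latent log10 abundance
aᵢ ~ N(7.0, 0.7²) — the typical LFQ intensity scale — then per replicate
control log10 Cᵢᵣ = aᵢ + ε and treatment log10 Tᵢᵣ = aᵢ + fcᵢ·log10 2 + ε
with ε ~ N(0, 0.1²). A minority of proteins (`spike_fraction`, default 5%)
receive fcᵢ = +5 log2 units, emulating genuine substrates strongly enriched
by the pulldown; all others have fc = 0. Each cell is then independently
missing with probability 1/(1 + exp(slope·(log10 value − midpoint)))
(midpoint 6.0, slope 2.0): ~88% missing at log10 = 5, ~12% at 7 —
left-censoring of the kind the low-quantile imputation presumes. Peptide
counts are ≥ 1 with a configurable fraction (default 10%) below the
standard filter threshold, so the filter stage is exercised.

What the generator does **not** model: between-sample normalisation error
(LFQ is assumed pre-normalised upstream), correlated missingness within a
protein, peptide-to-protein roll-up noise, contaminant/decoy rows, or
compositional effects of the immunoprecipitation itself. Passing recovery
tests therefore demonstrates the statistics chain is correct under the
stated model, not that the model captures every failure mode of real IP-MS
data.

`generate_proteome` draws background residues uniformly from the 20-letter
alphabet **excluding R, S and T**, then splices motif windows at requested
positions. Because both motif forms require an arginine at −3 and an S/T
acceptor, no accidental site can form, and the planted truth table is
provably the exact hit set. For a partial plant, the residue at −5 is kept
out of {L,V,I} so it cannot accidentally satisfy the full pattern. An
obvious consequence: these sequences have unrealistic composition; they
validate the scanner and bookkeeping, not biological sequence statistics
(the scanner itself is separately validated on full-alphabet random
sequences against exhaustive enumeration).

`generate_two_screen_study` assembles the full benchmark: two screens over
a 1,500-protein namespace with 84 and 226 spiked proteins overlapping in
24, of which 12 carry planted full motifs totalling 30 sites, 11 of them
in the generated known-site table. Only those 12 proteins carry motifs at
all, so false-positive enrichments elsewhere can inflate the enriched sets
and their intersection but never the motif-bearing chain — the
(12, 30, 11) triple is pinned to the designed truth. Two fixture-specific
choices keep the designed substrates observable: their peptide counts stay
above the filter threshold (`low_peptide_fraction = 0`), and their latent
abundance is floored at log10 = 6.5 (`spike_latent_floor`), inside the
reliably quantified range — a benchmark cannot score recovery of proteins
the instrument model never sees. Both knobs are off by default in
`LfqSimSpec`.

## Validation battery and problem sizes

The acceptance script and test suite recompute, at sizes chosen to run in
seconds on one CPU:

* quartiles and fence classes vs. an independent order-statistic oracle on
  1,000 random vectors of length 4–50 (agreement to 1e−12, zero class
  mismatches);
* imputation over ≥ 10,000 imputed cells (mean within ±0.01 of the pooled
  5% quantile, SD within 0.1 ± 0.01);
* scanner vs. exhaustive enumeration on 1,000 random full-alphabet
  sequences (length ≤ 200) and exact planted-site recovery;
* spike recovery over 20 seeded 500-protein screens with 5% spiked at
  log2 FC +5 and MNAR missingness on: sensitivity ≥ 0.95 and FPR ≤ 0.05
  for class-2 recovery. Rates are computed over proteins passing the
  peptide filter, since a protein excluded at identification never reaches
  the classifier;
* the end-to-end (12, 30, 11) chain above.

## Numerical and degenerate-input choices

* Intensity 0 and a blank cell both mean "missing" (MaxQuant writes 0 for
  unquantified LFQ); negative intensities are a parse error.
* A matrix with zero observed values cannot be imputed (the anchor
  quantile is undefined) and raises an error.
* Fence classification requires ≥ 4 finite ratios (quartiles are
  meaningless below that) and rejects non-finite ratios outright rather
  than silently dropping them.
* Sequences shorter than the motif window yield no hits, not an error.
* Duplicate leading accessions and duplicate FASTA accessions are errors
  by default with an explicit `keep_first` opt-in.
* All output floats are written with 6 significant digits; re-running an
  unchanged config and seed is byte-identical.

## Limitations

* The IQR-fence criterion has no error-rate calibration; the false-positive
  behaviour under heavy-tailed, imputation-inflated ratio distributions is
  whatever the fences give (measured at ~1% for class 2 and ~10% for
  class ≥ 1 under the default simulation conditions). It is a ranking
  heuristic, not a test.
* The known-site cross-reference is only as current as the supplied local
  table; counts of "previously reported" sites are snapshot-dependent.
* Motif percentages depend on which proteome FASTA (canonical vs. all
  isoforms) is scanned; the run summary records the FASTA used.
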
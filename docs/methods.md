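# Methods

## Model and assumptions

The predictor treats a miRNA–mRNA interaction as driven entirely by the
miRNA seed: a contiguous window near the 5′ end of the miRNA (default
positions 2–8, i.e. a 7-mer; 6- and 8-mer windows are configurable).  The
match motif is the exact DNA reverse complement of the seed, scanned on the
mRNA sense strand with overlaps counted and no G:U wobble.  The method does
not model flanking pairing, site spacing or 3′-supplementary pairing; it
asks only whether the *number* of seed matches in a transcript is larger
than a null model predicts, and it reports the transcript as a whole — when
several positions match, no claim is made about which is functional.

### 3′ UTR null: order-k Markov background

The background is an order-*k* Markov chain over {A,C,G,T} (default
*k* = 1, configurable 0–3), fitted by pooling transition counts over all
supplied transcripts of the run's region type, with no wrap-around across
records; a per-transcript background is available by flag.  Estimation is
add-one by default (pseudocount 1.0), applied to both the transition rows
and the initial k-mer distribution — the latter is a deliberate extension of
plain frequency normalization so that no motif prefix ever receives
probability zero on a degenerate corpus; with pseudocount 0 plain
normalization is recovered and never-seen contexts fall back to uniform
(logged).  Motif probability is the chain product accumulated in log space.

The count statistic is the exact binomial upper tail P(X ≥ n) with
N = L − m + 1 trials.  This ignores the dependence between overlapping
positions.  For non-self-overlapping motifs the error of the tail is small:
an exhaustive enumeration of all 4⁸ sequences of length 8 under a skewed
order-0 model (the independent oracle in the test suite) bounds it below
0.02 absolute, and the acceptance script reports the measured maximum
(~0.005 at that size).  Exact overlapping-word distributions and compound
Poisson corrections are out of scope; a Poisson tail is available behind a
flag for comparison but the binomial is the reference.

When conservation/accessibility filters are active, the observed count is
the number of *passing* sites while the per-position probability p is left
unchanged.  Filtering can only shrink the count, so the resulting P-value
is conservative.  Folding a pair-specific conservation probability into the
null is a known refinement left open.

### CDS null: synonymous-codon permutation

Coding sequence carries the protein signal, so the CDS null permutes codons
uniformly at random within each synonymous group (positions coding the same
amino acid exchange codons).  This is the unique simple scheme that
preserves *both* the amino-acid sequence and the exact codon multiset —
resampling from a codon-usage table would preserve usage only in
expectation.  Stop codons form their own group; internal stops are
permitted but logged.  The P-value is the add-one estimator
(1 + #{null ≥ observed}) / (1 + n_shuffles), bounded in
[1/(1+n_shuffles), 1] and never zero; default n_shuffles = 999.  Each
transcript gets an independent RNG stream derived from the master seed and
a hash of its id, so results are invariant to processing order.  When the
conservation filter is on, the observed count is conservation-filtered but
the null counts are raw occurrences (shuffling ortholog rows coherently has
no defined procedure here), again conservative.  Null calibration is
checked by treating a fresh shuffle as the observation: the p-value
distribution must be super-uniform, verified with a one-sided KS statistic
at n_shuffles = 199 over 500 replicates on a 50-codon CDS — sizes chosen to
keep the whole suite desk-scale while leaving the KS test well powered.

### Site filters

*Accessibility* consumes externally produced structure ensembles
(dot-bracket, one structure per line; an ensemble file groups structures
under `>transcript_id` headers).  A window "counts" when all its positions
are unpaired; the site passes when the window's unpaired fraction is
**≥** 0.20 (the threshold is inclusive by design).  Loose mode accepts any
4-mer window inside the site (offsets 0..3 of a 7-mer); strict mode only
the 3′-end window (offsets 3..6).  The 3′ end is interpreted in the mRNA
coordinate frame — the site is a substring of the transcript written
5′→3′, so its 3′ end is its right end.  This frame choice is the main
documented ambiguity of the filter.  Structures are inputs: the package
never folds RNA itself (an external folding tool can be invoked separately
to produce ensembles), which keeps runs deterministic.

*Conservation* maps the site through the reference row of a per-transcript
ortholog alignment (gaps skipped) and requires exact, gap-free identity of
the full site in at least `min_other_species` non-reference rows (default:
all of them — the strictest reading; weaker policies via the parameter;
`0` disables the filter).  Wobble-preserving substitutions are not
accepted.

### Ranking and output

BH adjusted values are computed over all candidate pairs evaluated in the
run (after filters, before the α threshold) — the family a user actually
sees.  The α cut is inclusive.  Ties are broken lexicographically by
(P-value, miRNA accession, transcript id) so re-runs are byte-identical.
"Potential target" lists are derived *before* the α/max-pairs truncation,
so a transcript absent from them truly has no passing seed match rather
than having been cut by output limits.  Floats in output files use
scientific notation at 6 significant digits; CSV carries only the
predictions table, the workbook adds six overview sheets; more than the
inline display limit (default 10 000) of records forces CSV.  Files are
written atomically (temp file + rename).

## Synthetic data generator

The fixtures module emulates the inputs end to end: uniform (or
user-specified composition) random transcripts; planted seed matches
implanted by overwriting at the requested positions (lengths fixed;
overlapping plants rejected; truth recorded by re-scanning, so incidental
background matches are part of the manifest); structure ensembles in which
each controlled 4-mer window is unpaired in exactly the rounded fraction of
structures, every uncontrolled position unpaired, and paired windows closed
by properly nested bracket blocks at the molecule's tail; alignments with
one insertion column (to exercise gap mapping) and a single substitution
inside each deliberately non-conserved site.  It does **not** emulate
realistic UTR composition, phylogeny, folding thermodynamics or isomiRs —
passing plant-and-recover tests demonstrates the machinery is correct, not
that real-data precision matches any benchmark.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| seed window | start 2, length 7 | canonical 2–8 seed, 7-mer match |
| markov_order | 1 | UTR background order (0–3) |
| pseudocount | 1.0 | add-one smoothing of the background |
| n_shuffles | 999 | CDS null size; p ≥ 1/1000 |
| accessibility window / threshold | 4 nt / 0.20 inclusive | unpaired 4-mer in ≥ 20% of structures |
| min_other_species | all rows | strict conservation |
| alpha | 0.05 | BH FDR level |
| inline_display_limit | 10 000 | above it, output forced to CSV |

## Numerical and degenerate-input choices

Log-space motif probability; `scipy.stats.binom.sf` for the tail with a
floor at the smallest positive double so P-values stay in (0, 1];
P(X ≥ 0) = 1 by definition.  Empty requested-id lists select everything
available; duplicate requests deduplicate keeping first occurrence; ids
that look version-suffixed get a log hint.  CDS transcripts whose length is
not a multiple of 3 are collected as per-transcript errors and skipped
without aborting the run; missing ensembles or alignments for an active
filter abort by default.

## Known limitations

Binomial independence across overlapping positions (self-overlapping
motifs, e.g. poly-A seeds, have heavier-tailed counts than modeled);
conservative interaction between filters and both nulls; conservation as
exact identity (no wobble or seed-type rules); no genome coordinates,
strand handling or database retrieval — inputs are plain FASTA/dot-bracket
files supplied by the user.
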
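# paccmit

miRNA target prediction in 3′ UTRs and coding sequences by seed-match
over-representation, for researchers who need a transparent, fully
reproducible desk-scale predictor: given miRNA sequences and mRNA regions
(FASTA), it finds exact seed matches, scores each miRNA–mRNA pair against a
sequence-appropriate null model, optionally sharpens precision with
conservation and structural-accessibility filters, and returns pairs ranked
by P-value with Benjamini–Hochberg adjusted values.

## The statistics

**Seed matching.** A miRNA's seed (default: positions 2–8 from the 5′ end)
defines a 7-mer motif — its exact reverse complement — searched on the mRNA
sense strand.  Overlapping occurrences are counted; only Watson–Crick
complementarity is used (no G:U wobble).

**3′ UTR mode (Markov-binomial).** An order-*k* Markov chain (default
*k* = 1, add-one smoothing) is fitted to the supplied transcripts.  For a
motif of length *m* with per-position probability *p* under that chain, the
observed count *n* in a transcript of length *L* is scored by the exact
binomial upper tail

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ n),  X ~ Binomial(N, p),  N = L − m + 1.

**CDS mode (synonymous shuffle).** Coding sequence is constrained by its
protein, so the null permutes codons uniformly at random within synonymous
groups — preserving the amino-acid sequence and the codon multiset exactly —
and uses the add-one empirical P-value
(1 + #{null ≥ observed}) / (1 + n_shuffles), default 999 shuffles.

**Filters.** A site is *accessible* when a 4-mer within it is unpaired in at
least 20% (inclusive) of the transcript's sampled secondary structures
(dot-bracket input); *loose* allows any 4-mer inside the site, *strict*
requires the one at the site's 3′ end.  A site is *conserved* when the
aligned columns in ortholog rows are gap-free and identical to the
reference site.

**Ranking.** Adjusted P-values follow the BH step-up procedure (the analog
of R's `p.adjust(x, method = "BH")`); pairs with adjusted P ≤ α are sorted
by (P-value, miRNA accession, transcript id) and truncated to the requested
maximum.  More than 10 000 returned pairs forces CSV output.

## Worked example

`python examples/utr_prediction.py` builds a seeded synthetic data set
(3 miRNAs × 4 UTRs of 1000 nt, one conserved and one non-conserved planted
site), runs the UTR pipeline with both filters on and prints:

```
Used miRNAs with at least one potential target (1): MIR0000
Used mRNAs that are potential targets (1): TX0000

Predictions
-----------
rank mirna_accession transcript_id gene_name site_count positions      p_value   p_adjusted
   1         MIR0000        TX0000                    1       101 6.275811e-02 6.275811e-02
```

The conserved, accessible planted site is recovered at its planted position
(101); the non-conserved plant is rejected by the conservation filter, so
TX0001 never appears as a potential target.  The P-value 0.063 is the
binomial chance of seeing ≥ 1 seed match in 1000 nt under the order-1
background fitted to these four transcripts.  Other examples:
`cds_prediction.py` (codon-shuffle null), `background_model.py` (Markov
backgrounds and the "every fifth transcript" 6-mer argument),
`site_filters_demo.py` (filter semantics).

## Command line

```
paccmit fixtures --n-mirnas 3 --n-transcripts 4 --plant 0,0,101 --outdir fx/
paccmit predict --mirna-fasta fx/mirnas.fa --transcript-fasta fx/transcripts.fa \
    --alpha 0.05 --output-format csv --output predictions.csv
paccmit fit-background --transcript-fasta fx/transcripts.fa --order 1 --output model.txt
```

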
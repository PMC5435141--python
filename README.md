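# intronseek

Discovery and characterization of **short introns** (10–70 nt) from
splice-junction tables produced by a splice-aware RNA-seq aligner.

Standard gene models assume a minimum intron length (often 50 nt), yet
well-documented short introns exist below it — the 26-nt intron that IRE1
excises from the *XBP1* mRNA being the classic case. When an aligner is
allowed to call gaps this short, the candidate pool is dominated by two
confounders: irreproducible low-support calls, and *spontaneous genomic
deletions* in cultured cell lines, which align against the reference exactly
like a spliced-out intron. `intronseek` implements a filtering pipeline that
separates genuine short introns from both, then characterizes the survivors:
splice-site class, position within transcripts, predicted frameshift,
splicing efficiency, secondary-structure stability, and enrichment of
IRE1-consensus cleavage sites.

## Method

For each cell line with two biological replicates:

1. **Reproducibility (npIDR).** For a read-support cutoff *n*, the
   non-parametric irreproducible discovery rate is the fraction of junctions
   with ≥ *n* unique reads in one replicate that are present (≥ 1 read) in
   the other, averaged over both directions. The per-sample cutoff is the
   smallest *n* with npIDR > 0.90.
2. **Length filter.** Intron length is end − start + 1 on 1-based inclusive
   junction coordinates; candidates with 10 ≤ L ≤ 70 continue.
3. **Genomic-deletion screens** on the intron plus 10-nt exonic flanks:
   *direct repeat* (junction-proximal flank 6-mer equals the matching
   terminal intron 6-mer), *inverted repeat* (first six intronic bases
   reverse-complement the last six), and *simple repeat* (> 75 % of the
   intron covered by tandem copies of one 1–5 nt unit). Matches are removed
   as likely deletions.
4. **Conservation cutoff.** Pooled across all datasets, the short pool is
   compared with *unannotated long* introns (> 70 nt, ends matching no
   annotated intron): the pooled unique-read cutoff is raised until the
   remaining short introns are detected in more biological samples, on
   average, than the unannotated long pool.
5. **Characterization.** Terminal dinucleotides (GT–AG / GC–AG / AT–AC vs
   non-canonical; 3/256 ≈ 1.2 % of random gaps look canonical by chance);
   annotated / alternative-5′ / alternative-3′ / nested status against the
   annotation; transcript region (5′UTR / ORF / 3′UTR / intronic / lncRNA)
   and frameshift (L mod 3 ≠ 0 for ORF introns); splicing efficiency
   `100 − 100·mid/((flank5+flank3)/2)` (clamped at 0) from 10-nt coverage
   windows; minimum free energy of folding (ΔG, built-in nearest-neighbor
   dynamic program); and a binomial test of IRE1 hexamer counts
   (CTGCAG, CCGCAG, CAGCAG, CTGCCG, CTGCAA) against the uniform-base null
   probability 5/4096 per position.

A seeded synthetic-data generator emits a toy genome, annotation, replicate
junction tables and coverage with planted ground truth for every one of
these signals, so the whole analysis runs and is validated without any
external download. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```bash
intronseek simulate --seed 1 --outdir demo/data
intronseek run --indir demo/data --outdir demo/out
```

prints (abridged):

```json
{
 "funnel": {
  "junction_rows": 7778,
  "pooled_introns": 830,
  "short_candidates": 710,
  "post_artifact_screen": 650,
  "final_pool": 379
 },
 "sample_cutoffs": {"cell01": 4, "cell02": 4, "...": 4},
 "read_cutoff": 6,
 "canonical": 88,
 "non_canonical": 291,
 "support_R": 0.985,
 "deltag_R": -0.851,
 "ire1_observed": 71,
 "ire1_expected": 25.67,
 "ire1_pvalue": 1.4e-13
}
```

Reading: 7,778 junction rows collapse to 830 distinct introns; 710 are
10–70 nt; the deletion screens remove 60; the pooled-read cutoff settles at
6 and leaves a final pool of 379. Every sample's npIDR cutoff lands on 4 —
the read-support level above which the generator plants reproducible
junctions. Splicing efficiency correlates positively with read support
(R = 0.99 across bins of 20) and negatively with folding free energy
(R = −0.85): more stable structure, more efficient splicing. IRE1 consensus
hexamers occur 71 times where 25.7 are expected by chance (binomial
p ≈ 10⁻¹³), with 43 hits at or within 1 nt of an exon/intron boundary.

`intronseek score --indir demo/data` reruns the pipeline and reports
recovery against the planted truth (sensitivity, artifact detection,
efficiency RMSE, correlation signs).

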
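# Methods

This note records the models, conventions and numerical choices behind
`intronseek`, and what the synthetic benchmark does and does not establish.

## Coordinates and inputs

Junction tables are the 9-column tab-separated dialect emitted by
splice-aware aligners: chromosome, 1-based positions of the first and last
intronic base, strand code (0 undefined / 1 plus / 2 minus), motif code,
annotated flag, unique reads, multimapped reads, maximum overhang. Those
1-based inclusive coordinates are kept verbatim on `SpliceJunction`;
everything downstream (BED output, coverage windows, annotation queries)
goes through the record's 0-based half-open `start0`/`end0` properties, so
the inclusive/exclusive conversion lives in one place. Intron length is
`end − start + 1`, the true base count, and the size window is
10 ≤ L ≤ 70: the upper bound is where non-canonical calls stop dominating
the length profile, the lower bound is where spontaneous genomic deletions
become common and known short introns end.

Sequences are reported in transcribed orientation: for minus-strand
junctions the three pieces (5′ flank, intron, 3′ flank) are
reverse-complemented and the flanks swapped, so "5′ flank" always means the
upstream exon in transcript sense. Undefined-strand junctions are processed
in genomic plus orientation and flagged; they pass through every screen but
are excluded from canonical/non-canonical summary curves by default, since
their end assignment is ambiguous. Any `N` disqualifies a repeat or motif
match at that position.

## Reproducibility between replicates (npIDR)

There is no reference set of short introns against which a false discovery
rate could be computed, so reproducibility between the two biological
replicates of a sample substitutes for it. For cutoff *n*, eligibility is
cumulative (unique reads ≥ *n*, matching the idea of a *minimum* support
level), presence in the other replicate means ≥ 1 unique read there, and
junction identity is (chromosome, start, end, strand). The statistic is the
mean of the two directional rates; a direction with an empty eligible set
contributes nothing, and an empty pair is an error. Whether to symmetrize
is genuinely open; the symmetric mean is the package's documented choice
and is what the invariance tests pin down. The per-sample cutoff is the
smallest *n* whose value exceeds the threshold (default 0.90).

## Genomic-deletion screens

Deletions arise preferentially where DNA replication slips (repeats) or
where unwound DNA forms secondary structure (stem-loops); aligned to a
reference, such deletions are indistinguishable from spliced introns, so
candidates in deletion-prone contexts are removed outright:

* **Direct repeat** — "six nucleotides of the flanking exon" is read as the
  junction-proximal exonic 6-mer, because slippage acts at the junction;
  it is compared with the corresponding terminal 6-mer of the intron
  (5′ flank ↔ intron end, 3′ flank ↔ intron start).
* **Inverted repeat** — "complementary" is implemented as antiparallel
  reverse complement, the geometry that actually forms a stem. For 10–11 nt
  introns the two terminal 6-mers overlap and are still compared.
* **Simple repeat** — ">75 % repetitive" is operationalized as tandem
  coverage: for unit size 1 it is plain base frequency (8 A's in a 10-nt
  intron trips it); for unit sizes 2–5 it is the maximal fraction of the
  intron covered by runs of ≥ 2 consecutive whole copies of a single unit,
  pooling all runs of that unit. The threshold is strict (exactly 75 % does
  not trip). Exhaustive search over units and phases is affordable at
  L ≤ 70, and the implementation is checked against an independent
  regex-based brute-force oracle.

All three rules are pure functions of transcribed-orientation sequence and
strand-symmetric under that convention.

## Conservation across samples and the pooled-read cutoff

After per-sample npIDR filtering, junctions are pooled by identity: a
junction is *detected* in a dataset when it reaches that dataset's cutoff
in at least one replicate, while pooled unique reads sum every observation
(sub-cutoff replicates included) so that total evidence is not truncated.
Long introns (> 70 nt) are split by exact end-match against the annotation.
"Favored detection in more biological samples" is operationalized as strict
inequality of the mean `samples_detected` — the simplest monotone summary
of the overlaid distributions; the full per-cutoff table is retained for
inspection. The selected cutoff is the smallest pooled-read value at which
the restricted short pool's mean exceeds the unannotated-long mean.

## Classification

End classes are the terminal dinucleotide pairs GT–AG, GC–AG (major
spliceosome) and AT–AC (minor); the by-chance probability that a uniform
random gap looks canonical is exactly 3/256 = 1.171875 %, kept as an exact
rational until printing. Annotation comparison is exact-coordinate: a
candidate is *annotated* when both ends match an annotated intron (any
transcript); *AS-3′* when the donor matches an annotated donor but the
acceptor is novel (the distance to the nearest annotated acceptor is
recorded rather than doing fuzzy matching), *AS-5′* symmetrically; *nested*
inside a transcript with neither end known; *intergenic* otherwise. Region
assignment uses the host transcript's CDS/UTR structure with tie priority
ORF > 5′UTR > 3′UTR > lncRNA > intronic — exonic placement in any host
outranks a purely intronic one, which matters when an alternative
transcript annotates the candidate itself as an intron. Frameshift is
L mod 3 ≠ 0, defined only for ORF-resident introns.

## Splicing efficiency

Three 10-nt genomic windows per intron (half-open, s0 = start−1, e0 = end):
upstream exon [s0−15, s0−5), middle [m−5, m+5) with m = ⌊(s0+e0)/2⌋, and
downstream exon [e0+5, e0+15). The floor in the mid-window centre resolves
the even-length ambiguity and makes the window coincide with the whole
intron at L = 10. Efficiency is `100 − 100·mid/((flank5+flank3)/2)`,
clamped below at zero; a zero flank average leaves the value undefined and
excluded from per-intron averages (both flanks are always averaged — using
"either" flank alone is not attempted). A read counts toward a window when
any aligned block overlaps it by ≥ 1 base, so junction-spanning reads
support the flanks but not the excised middle. For the support and
structure relationships, records are ranked by the key (descending),
grouped in bins of 20 (the last bin may be smaller when the pool size is
not a multiple of 20), and the Pearson correlation is computed across the
per-bin means — correlating bin means, not raw records, matches how such
data are summarized and plotted.

## Folding

The built-in engine is a simplified Zuker-style minimum-free-energy dynamic
program: helix stability from a packaged nearest-neighbor stacking table
(RNA-like values, kcal/mol, T read as U), fixed per-loop constants
(hairpin +5.4, internal/bulge +3.3, multiloop +4.6), minimum hairpin loop
of 3 unpaired bases, internal loops capped at 30 unpaired bases, no
pseudoknots. An unpaired chain scores 0, so ΔG ≤ 0 always. This is
deliberately not a full thermodynamic model: ΔG is used only as a *ranking*
covariate (more negative = more structured), for which stacking dominance
suffices; the DP is verified against exhaustive structure enumeration on
short sequences, and an adapter can register an external folding executable
(e.g. RNAfold) behind the same contract for users who want published
parameter sets. Folding is applied to the transcribed sequence of the
intron plus both 10-nt flanks, so splice-site-pairing stems formed with
exonic bases are visible to it.

## IRE1 consensus scan

The five cleavage-consensus hexamers (CTGCAG, CCGCAG, CAGCAG, CTGCCG,
CTGCAA) are sought on the transcribed strand only — IRE1 cleaves RNA, the
antisense strand is not a substrate. Every occurrence is reported,
overlapping ones included. The signed distance of a hit's 5′ base to the
nearer exon/intron boundary is positive on the intronic side, negative on
the exonic side, with equidistant ties assigned to the 5′ boundary. The
enrichment null assumes uniform base composition: the five hexamers are
distinct, so the per-position success probability is exactly 5/4096 and the
test is an upper-tail binomial on the total hit count over all scannable
positions (Poisson limit above 10⁵ positions); correlations between
overlapping positions are ignored by the null, a documented approximation.

## The synthetic benchmark

The generator emulates the *shape* of the real inputs — ten cell lines,
two replicates each, a genome, a transcript annotation, junction tables and
window coverage — with every signal planted and labeled. Defaults (the
study conditions): 40 three-exon genes (15 % lncRNA), 150 true short
introns with lengths uniform on 10–70, end classes canonical 0.55 / IRE1
0.25 / plain non-canonical 0.20, 40 % carrying a GC-rich 8-bp stem between
the flanks (splice sites at the stem base, so the intron-end screens are
not tripped); 20 deletion artifacts per screen class, each constructed to
trip exactly its own screen and, like a real somatic deletion, private to
one or two cell lines but reproducible between replicates; every gene's
real introns as annotated long introns present everywhere; 40 unannotated
long introns in 1–4 datasets; 150 replicate-private noise junctions per
replicate below the support boundary; and 500 reproducible single-dataset
short junctions with pooled support ≤ 6, the class the pooled-read cutoff
exists to remove. Per-replicate support for planted elements is the
boundary (4) plus negative-binomial extra reads (mean 12, dispersion 3), a
standard overdispersed model of junction counts; a replicate misses a
planted junction with probability 0.03. Planted efficiency is
`20 + 30·(support quantile) + 25·(stem) + N(0, 8)` clipped to [0, 100], and
coverage counts are Poisson around flank depth 1000 and the matching mid
expectation, so the estimator's expectation equals the planted value
(an exact, noise-free mode exists for calibration checks). True short
introns and single-dataset junctions are rejection-sampled to be repeat-free
against all three screens.

What passing tests on this benchmark show: the statistics recover planted
parameters under the stated noise models, coordinate and strand handling
are consistent end to end, and each screen flags exactly the contexts it
was defined on. What they do not show: performance on real alignments with
mapping bias, composition bias (the null base composition here is uniform
by construction), overlapping genes, fragmented annotations, or
expression-dependent detection — the generator has no read-level error
model and no expression realism. Repeated-seed tests use a scaled-down
configuration (4 datasets, 15 genes, 60 true introns) so fifty independent
studies run in seconds; the full-size conditions are exercised once per
suite and by the acceptance script.

## Known limitations

* The pooled-read cutoff selection compares means; first-order stochastic
  dominance of the distributions is not required (the per-cutoff table is
  exposed for users who want a stricter criterion).
* The folding energies are rank-faithful, not thermodynamically calibrated;
  absolute ΔG values should not be compared with published tools.
* EST-style transcriptional evidence is not consulted for "annotated"
  status — only the supplied annotation is.
* Alignment-file coverage counting streams the whole file; for large
  indexed BAMs a region-query implementation would be preferable.
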
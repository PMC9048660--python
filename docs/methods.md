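# Methods

## Model

A gene body is an alternation of exons and introns with optional fixed
5′/3′ flanking sequences. Intron removal concatenates the exons into
the CDS and records a *junction* — the 0-based CDS offset of the first
nucleotide downstream of each removed intron. When the first intron is
retained (the default, as it is often required for robust expression),
it is held aside with its insertion offset, spliced back on output in
lowercase, and its exon boundary contributes **no** junction: the
intron is still there, so no ESE vicinity applies at that boundary.

Recoding is a single 5′→3′ pass, one codon at a time. At each mutable
codon the synonymous candidates are enumerated (all six codons at
6-fold sites by default, or only the 2-/4-codon sub-box containing the
current codon under the sub-box policy), scored, converted to a
selection probability by linear normalization of the convex blend

    combined = (1 − λ)·gc + λ·ese        (λ only where ESE scoring applies)

and one candidate is drawn. Selection is deliberately stochastic —
likelihood-proportional, not greedy — so repeated passes populate a
*cloud* of distinct variants. Committed choices are visible to later
sites; there is no backtracking. The best variant minimizes

    objective = mean over 10-codon bins of |GC3_achieved − GC3_target|
              + |ESE density − target density|     (when ESE mode is on)

with ties broken by fewest changes, then generation order. GC3 is
measured over degenerate codons only (Met, Trp and stops excluded).
The ESE density target is 0 when depleting and 1 when enriching; like
the GC3 term it is a direction to push in, not a value real sequences
reach, so best-variant objectives are compared within a cloud rather
than interpreted absolutely.

### GC strategies

* **one_two_exon** (default): the probability of third nucleotide *n*
  at codon index *i* within codon box *b* is
  `floor + (ceiling − floor)·exp(−i/τ)`, renormalized over the box at
  each index. Boxes group synonymous codons sharing their first two
  nucleotides; the 6-fold families Leu/Ser/Arg are always handled as
  their 4-fold plus 2-fold sub-boxes (CTN|TTR, TCN|AGY, CGN|AGR). When
  full-box candidates span both sub-boxes, each candidate is scored in
  its own sub-box and the scores are jointly renormalized through the
  selection-probability step.
* **max_gc**: a candidate scores the fraction of its family's variable
  positions that are G or C — for ordinary families simply 1 if the
  third position is G/C, else 0; for 6-fold families the first/second
  positions that vary across sub-boxes also count.
* **human_usage**: the candidate's usage frequency normalized within
  its amino-acid family; position-independent. A human table
  (frequencies per 1000 from the public codon usage database) is
  bundled; any table in the same `CODON frequency` layout can be
  substituted.
* **ese_only**: no GC preference (a flat 1/n per candidate). Sites
  outside the ESE-eligible region then have no active scoring component
  at all, and the original codon is retained — with nothing to score
  there is no basis to replace.

### Default curves

The published position-dependent favourability curves for native
one/two-exon human genes are not available as data, so the default
`one_two_exon` model is an editable parametric stand-in
(`data/default_curves.yaml`): G/C-ending probabilities start elevated
at the 5′ end (ceiling 0.40 per nucleotide in 4-fold boxes, 0.80 in
2-fold boxes) and decay with τ = 50 codons to a uniform floor, with
A/T-ending curves complementary so each box sums to exactly 1 at every
index. τ = 50 reflects that the expression benefit of high GC3
concentrates in the first ~100–200 codons. Users with training data
(e.g. native one/two-exon CDSs) should rebuild the table with
`fit_position_curves`, which tabulates third-nucleotide frequencies in
10-codon bins, least-squares fits (floor, ceiling, τ) per box and
nucleotide with bins weighted by their counts, and keeps the
3-parameter curve only when it beats the position-independent flat
model on AIC — otherwise sampling noise alone drives the parameters
apart. Boxes absent from the training data fall back to a flat uniform
curve with a warning.

### ESE scoring

ESE resemblance of a candidate is the fraction of hexamer windows
overlapping the candidate's variable position(s) that match the motif
set after substitution (m/w; 1 − m/w when depleting; 0.5 when no
window fits, e.g. a very short CDS). All overlapping windows count —
density is a per-window statistic, with no greedy masking. Windows are
scanned on the intronless CDS only: ESEs are exonic by definition, so
flanks and a retained intron are not part of the ESE context (they are
part of the blacklist context, below). A site is ESE-eligible when any
of its nucleotides lies within `vicinity_nt` (default 70) of a removed
junction — symmetric, measured on the intronless CDS, so the farthest
assessed nucleotide sits exactly 70 nt from the junction on either
side — or everywhere when `ese_in_cores` is set.

### Constraints

Restriction-site protection scans the *original* working sequence
(5′ flank + CDS with retained intron + 3′ flank) with each IUPAC
recognition pattern and its reverse complement; codons overlapping any
match are frozen. New recognition sites may still arise in variants —
protection means "retain what is there", not "forbid new"; add the
pattern to the blacklist to forbid new sites too.

The blacklist is checked at draw time: the drawn codon is substituted
into the current working sequence and a window of length
2·(L_max − 1) + 3 around the codon (L_max = longest avoid motif,
generalized when a retained intron splits the codon) is rescanned; if
any avoid-motif occurrence appears at an offset where none existed
before the substitution, the draw is reverted and the site keeps its
current codon. Because flanks and the retained intron are in the
working sequence, junction-spanning introductions are caught. Avoid
motifs are matched on the given strand only (the motivating cases,
e.g. miRNA binding sites, are strand-specific); list both orientations
to forbid both. Pre-existing occurrences are never counted as
violations and do not block unrelated changes.

## Randomness and reproducibility

Variant *k* of a cloud draws from an RNG sub-stream seeded with
(seed, k), so clouds are reproducible bit-for-bit from (input, config,
seed) and independent of generation order. The CLI writes a JSON
manifest (config echo, input SHA-256, seed, version, timings, output
paths) on every run, success or failure.

## Synthetic fixtures

`make_toy_gene` builds gene-like fixtures: an ATG…TAA CDS over the 18
degenerate sense families (every one offers both a G/C- and an
A/T-ending codon, so the degenerate-third-position GC probability
equals `gc3_bias` exactly and no internal stop can arise), split into
exons of the requested lengths with GT…AG introns. Optionally a
requested number of non-overlapping ESE-set matches is planted within
70 nt of the junctions, re-validating the reading frame after each
placement. `make_training_corpus` draws third-position nucleotides
from a known curve model so curve fitting can be validated by parameter
recovery. These fixtures capture the statistical features the method
acts on (GC3 composition, positional third-nucleotide gradients,
junction-proximal motif matches) and none of the biology it does not:
amino-acid usage is uniform, introns are short and unstructured, and
there are no splice-site strength, secondary-structure or
dinucleotide (CpG) effects — passing tests demonstrate the recoding
machinery, not expression outcomes on real genes.

## Problem sizes in the test and acceptance suites

Toy genes of 100–200 codons and clouds of tens to hundreds of variants
exercise every code path at sub-second cost; the randomized-guarantee
suites check hundreds to a thousand generated variants; curve-fit
recovery uses 500 CDSs of 300 codons. Per-box curve estimates from such
a corpus carry ~5–15% noise on (ceiling, τ) because each box sees only
~1/21 of the codons, so recovery is asserted on the estimates averaged
over the eight 4-fold boxes, which are independent replicates of the
same truth curve. Exhaustive-enumeration optimality is checked on
CDSs of ≤ 6 codons, where every synonymous sequence can be scored; the
check excludes avoid motifs because blacklist reversion is
path-dependent (a globally clean sequence can be unreachable when an
intermediate working state would transiently spell a forbidden motif),
so cloud-optimum equality is only guaranteed without them — the
blacklist guarantee itself is verified separately on randomized runs.

## Known limitations

* No global optimization (no annealing or backtracking): the cloud
  samples the sequential-commitment distribution, and optimality is
  guaranteed only in the small-CDS enumeration regime.
* Designs with a high GC3 target and increased ESE density pull in
  opposite directions (published ESE hexamers are A-rich), and complete
  ESE elimination is generally impossible within synonymous moves.
* The default curves are a parametric stand-in, not fitted human data;
  conclusions about positional GC3 matching on real genes require
  refitting on a real training set.
* GenBank support covers the minimal single-locus, single-CDS dialect
  with `join()`/`complement()`; RNA alphabets, ambiguity codes inside
  the CDS and multi-gene records are rejected.
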
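# intronless

Design intronless (or first-intron-only) mammalian transgenes by
stochastic synonymous recoding.

## The problem

Most human genes are largely intron; for synthesis-scale transgenes the
introns have to go, but intronless constructs classically express
poorly. Two sequence-level levers mitigate this without touching the
encoded protein:

* **GC3** — native intronless retrogenes carry high GC at synonymous
  (third codon) positions, especially toward the 5′ end, and raising
  GC3 rescues expression of intronless transgenes;
* **ESE density** — exonic splice enhancers (hexamers bound by SR
  proteins) cluster near exon ends in intron-rich genes; once the
  introns are removed they may promote missplicing, so depleting (or,
  if desired, enriching) them near the former junction positions can be
  useful.

`intronless` takes a gene body (GenBank, or FASTA with UPPERCASE exons
and lowercase introns), removes the introns (keeping the first by
default, since it often matters for expression), and slides 5′→3′ over
the CDS recoding one synonymous site at a time. At each site the
candidate codons are scored and one is drawn with probability
proportional to its combined score:

```
P(candidate c at codon i)  ∝  (1 − λ) · gc(c, i)  +  λ · ese(c)
```

* `gc(c, i)` comes from one of four strategies: position-dependent
  third-nucleotide probability curves emulating native one/two-exon
  genes, `p(i) = floor + (ceiling − floor)·e^(−i/τ)` per codon box
  (6-fold boxes split into their 4-fold and 2-fold sub-boxes); maximal
  GC at degenerate positions; human codon usage; or no GC component.
* `ese(c)` is the fraction of hexamer windows overlapping the site that
  match the chosen ESE motif set after substitution (or its complement
  when depleting), applied within 70 nt of each removed junction
  (configurable, optionally everywhere). The five published set names —
  RESCUE-ESE, ESR, Ke-ESE400, PESE, INT3 — are recognized; their motif
  lists are supplements of the defining papers and are supplied as
  one-hexamer-per-line files.

Codons overlapping a protected restriction-enzyme match (either strand)
are never touched, and a draw that would newly introduce a blacklisted
motif — including across flank and retained-intron boundaries — is
reverted. Repeating the pass populates a variant cloud; the variant
with the smallest deviation from the GC3/ESE targets (mean per-10-codon
bin |achieved − target| GC3, plus the ESE density gap) wins. Identical
input, configuration and seed always reproduce the identical cloud.

## A worked example

```python
from intronless import DesignConfig, ToyGeneSpec, design, make_toy_gene

gene = make_toy_gene(ToyGeneSpec(exon_lengths=[150, 150], intron_lengths=[40], seed=1))
config = DesignConfig(gc_strategy="max_gc", keep_first_intron=False,
                      n_variants=100, seed=1)
cloud, plan, processed = design(gene, config)
print(f"GC3 {cloud.input_gc3:.3f} -> {cloud.best.achieved_gc3:.3f}, "
      f"{len(cloud.best.changes)} changes, objective {cloud.best.objective:.4f}")
```

prints

```
GC3 0.500 -> 0.990, 60 changes, objective 0.0100
```

— the 100-codon toy gene went from balanced GC3 to 0.99 through 60
synonymous substitutions (objective 0.01 = mean per-bin distance from
the max-GC target of 1.0); the protein is unchanged by construction.
The `examples/` directory holds one short script per capability
(max-GC design, ESE depletion, curve fitting, motif protection), each
printing the numbers it computes.

The same run from the shell:

```
intronless design --input gene.fasta --gc-strategy max-gc \
    --remove-first-intron --n-variants 100 --seed 1 --out-prefix out/run
```

writes the best-variant FASTA (retained intron, if any, in lowercase),
a multi-FASTA of the whole cloud, a per-site change table (TSV) and a
JSON summary, plus a run manifest sufficient to reproduce the run.
`intronless list-ese-sets` shows the five predefined ESE set names.

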
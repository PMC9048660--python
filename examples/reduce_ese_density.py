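"""Deplete exonic splice enhancers near a removed intron.

ESEs left near the former positions of removed introns can promote
missplicing of an intronless transcript.  This example seeds a toy gene
with ESE motif matches around its splice junction, then recodes only
within 70 nt of the removed junction (ese_only strategy: no GC
pressure) to strip them.
"""

from intronless import DesignConfig, EseSet, ToyGeneSpec, design, make_toy_gene

ese = EseSet("toy", frozenset({"GAAGAA", "AAGAAG", "GAAGAT"}))
gene = make_toy_gene(
    ToyGeneSpec([150, 150], [40], seed=3, motif_seeding=(ese, 4))
)
config = DesignConfig(
    gc_strategy="ese_only",   # leave GC3 alone
    ese_mode="decrease",
    ese_set=ese,
    ese_weight=1.0,
    vicinity_nt=70,
    keep_first_intron=False,
    n_variants=100,
    seed=2,
)
cloud, _, processed = design(gene, config)
best = cloud.best

after = best.ese_density_vicinity
print(f"junction at CDS offset {processed.junctions[0]}; "
      f"{after.window_count} hexamer windows within 70 nt")
print(f"vicinity ESE density: {cloud.input_ese_density:.4f} -> {after.density:.4f} "
      f"({after.match_count} matches left)")
print(f"{len(best.changes)} codon(s) changed, all within the vicinity")
# Density is matching hexamer windows per window.  Reduction is usually
# possible but complete elimination is not guaranteed for real motif
# sets: only synonymous codons are allowed, so some matches are locked
# in by the protein sequence.
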
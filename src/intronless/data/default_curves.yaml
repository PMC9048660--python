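# Default position-dependent third-nucleotide probability curves.
#
# For each codon box (6-fold families split into 4-fold and 2-fold
# sub-boxes), the probability of third nucleotide n at codon index i is
#     p = floor + (ceiling - floor) * exp(-i / tau)
# renormalized over the box at each index.  tau is in codons.
#
# These defaults emulate the GC3 gradient of native human one/two-exon
# genes: elevated G/C probability at the 5' end decaying to a
# genomic-average floor.  Floors and ceilings are complementary within
# each box (both sum to 1) so probabilities sum to 1 at every index.
# Edit freely, or rebuild from training CDSs with fit_position_curves.

CTN: &fourfold
  A: {floor: 0.25, ceiling: 0.10, tau: 50}
  C: {floor: 0.25, ceiling: 0.40, tau: 50}
  G: {floor: 0.25, ceiling: 0.40, tau: 50}
  T: {floor: 0.25, ceiling: 0.10, tau: 50}
GTN: *fourfold
TCN: *fourfold
CCN: *fourfold
ACN: *fourfold
GCN: *fourfold
CGN: *fourfold
GGN: *fourfold

TTY: &twofold_y
  C: {floor: 0.50, ceiling: 0.80, tau: 50}
  T: {floor: 0.50, ceiling: 0.20, tau: 50}
TAY: *twofold_y
CAY: *twofold_y
AAY: *twofold_y
GAY: *twofold_y
TGY: *twofold_y
AGY: *twofold_y

TTR: &twofold_r
  A: {floor: 0.50, ceiling: 0.20, tau: 50}
  G: {floor: 0.50, ceiling: 0.80, tau: 50}
CAR: *twofold_r
AAR: *twofold_r
GAR: *twofold_r
AGR: *twofold_r

ATH:
  A: {floor: 0.33, ceiling: 0.20, tau: 50}
  C: {floor: 0.34, ceiling: 0.60, tau: 50}
  T: {floor: 0.33, ceiling: 0.20, tau: 50}
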
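"""Synthetic gene fixtures with controlled statistical structure.

Everything here is generated data for exercising the design pipeline —
toy genes with a tunable GC3 bias and optionally pre-seeded ESE matches
near their splice junctions, and training corpora whose third-position
nucleotides follow a known position-dependent curve model (so curve
fitting can be validated by parameter recovery).  Fixtures are
gene-like (ATG start, single stop, GT...AG introns) but make no attempt
to mimic real intron length or composition distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ese_motifs import EseSet, ese_match_count
from .gene_io import GeneRecord
from .optimizer import _vicinity_intervals
from .scoring import (
    BOX_CODONS,
    BOX_OF_CODON,
    FAMILIES,
    GENETIC_CODE,
    GcTargetModel,
    translate,
)

# degenerate sense families only: every one offers both a G/C- and an
# A/T-ending codon, so gc3_bias is directly controllable
_DEGENERATE_AA = sorted(
    aa for aa, fam in FAMILIES.items() if aa != "*" and len(fam.codons) > 1
)


@dataclass
class ToyGeneSpec:
    """Recipe for one toy gene."""

    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int] = ()
    gc3_bias: float = 0.5
    motif_seeding: Optional[tuple[EseSet, int]] = None  # (set, matches near junctions)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exon_lengths or any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"need {len(self.exon_lengths) - 1} introns for "
                f"{len(self.exon_lengths)} exons"
            )
        if any(l < 4 for l in self.intron_lengths):
            raise ValueError("introns need >= 4 nt for GT...AG ends")
        if sum(self.exon_lengths) % 3 or sum(self.exon_lengths) < 9:
            raise ValueError("total exon length must be a multiple of 3 and >= 9")
        if not 0.0 <= self.gc3_bias <= 1.0:
            raise ValueError("gc3_bias must be in [0, 1]")


def _random_codon(rng: np.random.Generator, gc3_bias: float) -> str:
    aa = _DEGENERATE_AA[int(rng.integers(len(_DEGENERATE_AA)))]
    codons = FAMILIES[aa].codons
    gc_ending = [c for c in codons if c[2] in "GC"]
    at_ending = [c for c in codons if c[2] in "AT"]
    pool = gc_ending if rng.random() < gc3_bias else at_ending
    return pool[int(rng.integers(len(pool)))]


def make_cds(n_codons: int, gc3_bias: float, rng: np.random.Generator) -> str:
    """ATG + (n-2) random degenerate-family codons + TAA; no internal
    stops by construction; degenerate third positions are G/C with
    probability ``gc3_bias``."""
    if n_codons < 3:
        raise ValueError("a CDS needs at least start, one codon and stop")
    body = [_random_codon(rng, gc3_bias) for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _random_intron(length: int, rng: np.random.Generator) -> str:
    inner = "".join(
        "ACGT"[int(rng.integers(4))] for _ in range(length - 4)
    )
    return "GT" + inner + "AG"


def make_toy_gene(spec: ToyGeneSpec) -> GeneRecord:
    """Generate a GeneRecord per the spec; fully determined by its seed."""
    rng = np.random.default_rng(spec.seed)
    total = sum(spec.exon_lengths)
    cds = make_cds(total // 3, spec.gc3_bias, rng)
    if spec.motif_seeding is not None:
        cds = _seed_motifs(cds, spec, rng)
    exons = []
    pos = 0
    for l in spec.exon_lengths:
        exons.append(cds[pos : pos + l])
        pos += l
    introns = [_random_intron(l, rng) for l in spec.intron_lengths]
    gene = GeneRecord(
        identifier=f"toy_{spec.seed}",
        description="synthetic toy gene",
        exons=exons,
        introns=introns,
    )
    gene.validate()
    return gene


def _seed_motifs(cds: str, spec: ToyGeneSpec, rng: np.random.Generator) -> str:
    """Plant the requested number of non-overlapping motif matches within
    70 nt of the exon junctions, preserving a valid CDS frame
    (ATG start, single terminal stop)."""
    ese_set, n_wanted = spec.motif_seeding  # type: ignore[misc]
    junctions = list(np.cumsum([l for l in spec.exon_lengths[:-1]]))
    intervals = _vicinity_intervals(junctions, 70, len(cds))
    candidates = [
        s
        for lo, hi in intervals
        for s in range(max(lo, 3), min(hi, len(cds) - 3) - 5)
    ]
    rng.shuffle(candidates)
    motifs = sorted(ese_set.motifs)
    chars = list(cds)
    placed: list[int] = []
    for start in candidates:
        if len(placed) == n_wanted:
            break
        if any(abs(start - p) < 6 for p in placed):
            continue
        motif = motifs[int(rng.integers(len(motifs)))]
        trial = chars[:]
        trial[start : start + 6] = motif
        trial_cds = "".join(trial)
        protein = translate(trial_cds)
        if "*" in protein[:-1] or not protein.endswith("*"):
            continue
        chars = trial
        placed.append(start)
    if len(placed) < n_wanted:
        raise ValueError(
            f"could only place {len(placed)} of {n_wanted} requested motif "
            f"matches near the junctions"
        )
    return "".join(chars)


def write_gene_genbank(gene: GeneRecord, minus_strand: bool = False) -> str:
    """Render a GeneRecord as a minimal GenBank flat file (round-trippable
    through parse_genbank).  With ``minus_strand`` the whole locus is
    reverse-complemented and the CDS becomes a complement() feature."""
    import io

    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    body = []
    intervals = []
    pos = 0
    for i, exon in enumerate(gene.exons):
        intervals.append((pos, pos + len(exon)))
        body.append(exon)
        pos += len(exon)
        if i < len(gene.introns):
            body.append(gene.introns[i])
            pos += len(gene.introns[i])
    seq = Seq("".join(body))
    strand = 1
    if minus_strand:
        total = len(seq)
        seq = seq.reverse_complement()
        intervals = [(total - e, total - s) for s, e in reversed(intervals)]
        strand = -1
    locs = [SimpleLocation(s, e, strand=strand) for s, e in intervals]
    if strand == -1:
        locs = list(reversed(locs))
    location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    record = SeqRecord(
        seq,
        id=gene.identifier,
        name=gene.identifier[:16],
        description=gene.description,
        annotations={"molecule_type": "DNA"},
        features=[SeqFeature(location, type="CDS")],
    )
    buf = io.StringIO()
    from Bio import SeqIO

    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def make_training_corpus(
    n: int,
    model: GcTargetModel,
    n_codons: int = 300,
    seed: int = 0,
) -> list[str]:
    """CDSs whose third-position nucleotide at codon index i is drawn
    from the curve model's box probabilities at i (feeds curve fitting)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.strategy != "one_two_exon":
        raise ValueError("training corpora are drawn from a one_two_exon model")
    rng = np.random.default_rng(seed)
    # pre-index: one representative box per degenerate family sub-box
    boxes = [b for b, codons in BOX_CODONS.items() if len(codons) > 1]
    corpus = []
    for _ in range(n):
        codons = ["ATG"]
        for i in range(1, n_codons - 1):
            box = boxes[int(rng.integers(len(boxes)))]
            probs = model.box_probabilities(box, i)
            nts = sorted(probs)
            p = np.array([probs[nt] for nt in nts])
            nt = nts[int(rng.choice(len(nts), p=p / p.sum()))]
            codons.append(box[:2] + nt)
        codons.append("TAA")
        corpus.append("".join(codons))
    return corpus
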
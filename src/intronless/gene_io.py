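"""Reading, validating and splicing gene bodies.

A gene body is an ordered alternation of exons and introns.  Two input
routes are supported:

* GenBank flat files — exon/intron structure is taken from the CDS
  feature (``join()`` of exon intervals; ``complement()`` is honoured).
* FASTA — structure is encoded by case, soft-masking style: UPPERCASE
  runs are exons, lowercase runs are introns.  The record must start and
  end in an exon.

Internally all sequence is upper-case DNA over {A,C,G,T}.  Coordinates
are 0-based half-open; user-facing reports are 1-based.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

from Bio import SeqIO
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .optimizer import Variant, VariantCloud, SitePlan

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_DNA = frozenset("ACGT")


class GeneError(ValueError):
    """Raised when a gene body fails parsing or validation."""


class PartialCdsWarning(UserWarning):
    """CDS does not start with ATG or end with a stop codon."""


@dataclass
class GeneRecord:
    """A parsed gene body: ordered exons/introns plus optional flanks."""

    identifier: str
    description: str
    exons: list[str]
    introns: list[str]
    five_prime_flank: str = ""
    three_prime_flank: str = ""

    @property
    def cds(self) -> str:
        return "".join(self.exons)

    def validate(self, allow_partial: bool = False) -> None:
        """Check structural invariants; raise :class:`GeneError` on failure.

        Start/stop codon violations raise by default and downgrade to
        :class:`PartialCdsWarning` when ``allow_partial`` is set.
        """
        if len(self.introns) != len(self.exons) - 1:
            raise GeneError(
                f"expected {len(self.exons) - 1} introns for "
                f"{len(self.exons)} exons, found {len(self.introns)}"
            )
        for kind, segs in (("exon", self.exons), ("intron", self.introns)):
            for i, seg in enumerate(segs, 1):
                if not seg:
                    raise GeneError(f"{kind} {i} is empty")
                bad = set(seg) - _DNA
                if bad:
                    raise GeneError(
                        f"{kind} {i} contains non-ACGT character(s): "
                        f"{', '.join(sorted(bad))}"
                    )
        for kind, seg in (
            ("5' flank", self.five_prime_flank),
            ("3' flank", self.three_prime_flank),
        ):
            bad = set(seg) - _DNA
            if bad:
                raise GeneError(
                    f"{kind} contains non-ACGT character(s): {', '.join(sorted(bad))}"
                )
        cds = self.cds
        if not cds or len(cds) % 3 != 0:
            raise GeneError(f"CDS length {len(cds)} is not a positive multiple of 3")
        problems = []
        if not cds.startswith("ATG"):
            problems.append(f"CDS does not start with ATG (found {cds[:3]})")
        if cds[-3:] not in STOP_CODONS:
            problems.append(f"CDS does not end with a stop codon (found {cds[-3:]})")
        for msg in problems:
            if allow_partial:
                warnings.warn(msg, PartialCdsWarning, stacklevel=2)
            else:
                raise GeneError(msg + " (use allow_partial to accept a partial CDS)")


@dataclass
class ProcessedGene:
    """CDS after intron removal.

    ``junctions`` holds, for every *removed* intron, the 0-based CDS
    offset of the first nucleotide downstream of its former position —
    these anchor the ESE vicinity windows.  A retained first intron is
    kept aside with its insertion offset and is spliced back on output;
    its exon boundary is deliberately absent from ``junctions``.
    """

    cds: str
    junctions: list[int]
    retained_intron: Optional[tuple[str, int]] = None
    five_prime_flank: str = ""
    three_prime_flank: str = ""

    def working_sequence(self) -> tuple[str, list[int]]:
        """Full editable context and the CDS→context index map.

        Returns ``(sequence, cds_to_working)`` where the sequence is
        5' flank + CDS with any retained intron re-inserted + 3' flank,
        and ``cds_to_working[i]`` locates CDS position ``i`` in it.
        """
        off5 = len(self.five_prime_flank)
        if self.retained_intron is None:
            seq = self.five_prime_flank + self.cds + self.three_prime_flank
            return seq, [off5 + i for i in range(len(self.cds))]
        intron, at = self.retained_intron
        seq = (
            self.five_prime_flank
            + self.cds[:at]
            + intron
            + self.cds[at:]
            + self.three_prime_flank
        )
        idx = [off5 + i if i < at else off5 + len(intron) + i for i in range(len(self.cds))]
        return seq, idx

    def spliced_output(self, cds: Optional[str] = None) -> str:
        """Gene body for output: given (or own) CDS with a retained
        intron re-inserted in lowercase, flanks attached."""
        cds = self.cds if cds is None else cds
        if self.retained_intron is None:
            body = cds
        else:
            intron, at = self.retained_intron
            body = cds[:at] + intron.lower() + cds[at:]
        return self.five_prime_flank + body + self.three_prime_flank


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def parse_genbank(text: str, allow_partial: bool = False) -> GeneRecord:
    """Build a :class:`GeneRecord` from GenBank flat-file content.

    Exactly one locus with one CDS feature is required.  Exons are the
    CDS intervals in transcript order, introns the gaps between them;
    minus-strand CDSs are reverse-complemented into sense orientation.
    """
    try:
        records = list(SeqIO.parse(io.StringIO(text), "genbank"))
    except Exception as exc:  # malformed flat file
        raise GeneError(f"could not parse GenBank input: {exc}") from exc
    if len(records) != 1:
        raise GeneError(f"expected exactly 1 locus, found {len(records)}")
    rec = records[0]
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if not cds_feats:
        raise GeneError("no CDS feature in GenBank record")
    if len(cds_feats) > 1:
        raise GeneError(f"expected exactly 1 CDS feature, found {len(cds_feats)}")
    feat = cds_feats[0]
    seq = _normalize(str(rec.seq))
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    exons, introns = [], []
    prev_end = None
    for part in parts:
        start, end = int(part.start), int(part.end)
        if start < 0 or end > len(seq) or start >= end:
            raise GeneError(
                f"CDS interval {start + 1}..{end} outside sequence bounds 1..{len(seq)}"
            )
        if prev_end is not None:
            if start < prev_end:
                raise GeneError("CDS intervals overlap")
            introns.append(seq[prev_end:start])
        exons.append(seq[start:end])
        prev_end = end
    if feat.location.strand == -1:
        exons = [str(Seq(e).reverse_complement()) for e in reversed(exons)]
        introns = [str(Seq(i).reverse_complement()) for i in reversed(introns)]
    record = GeneRecord(
        identifier=rec.id or rec.name or "gene",
        description=rec.description or "",
        exons=exons,
        introns=introns,
    )
    record.validate(allow_partial=allow_partial)
    return record


def parse_fasta(text: str, allow_partial: bool = False) -> GeneRecord:
    """Build a :class:`GeneRecord` from FASTA with case-encoded structure
    (UPPERCASE = exon, lowercase = intron)."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) != 1:
        raise GeneError(f"expected exactly 1 FASTA record, found {len(records)}")
    rec = records[0]
    raw = str(rec.seq).replace("U", "T").replace("u", "t")
    if not raw:
        raise GeneError("FASTA record has an empty sequence")
    if raw[0].islower() or raw[-1].islower():
        raise GeneError("gene body must start and end in an exon (uppercase)")
    exons, introns = [], []
    i = 0
    while i < len(raw):
        j = i
        is_exon = raw[i].isupper()
        while j < len(raw) and raw[j].isupper() == is_exon:
            j += 1
        (exons if is_exon else introns).append(raw[i:j].upper())
        i = j
    desc = rec.description or ""
    if rec.id and desc.startswith(rec.id):
        desc = desc[len(rec.id) :].strip()
    record = GeneRecord(
        identifier=rec.id or "gene",
        description=desc,
        exons=exons,
        introns=introns,
    )
    record.validate(allow_partial=allow_partial)
    return record


def write_gene_fasta(gene: GeneRecord) -> str:
    """Render a GeneRecord as case-convention FASTA (round-trippable
    through :func:`parse_fasta`)."""
    parts = []
    for i, exon in enumerate(gene.exons):
        parts.append(exon.upper())
        if i < len(gene.introns):
            parts.append(gene.introns[i].lower())
    header = f">{gene.identifier}"
    if gene.description and gene.description != gene.identifier:
        header += f" {gene.description}"
    return header + "\n" + _wrap("".join(parts)) + "\n"


def remove_introns(gene: GeneRecord, keep_first: bool = True) -> ProcessedGene:
    """Splice the gene body: drop all introns, optionally retaining the
    first in place.

    Junction offsets mark removed introns only; when the first intron is
    retained, the exon1/exon2 boundary gets no junction (the intron is
    still there, so no ESE vicinity applies).
    """
    cds = gene.cds
    boundaries = []
    pos = 0
    for exon in gene.exons[:-1]:
        pos += len(exon)
        boundaries.append(pos)
    retained = None
    junctions = list(boundaries)
    if keep_first and gene.introns:
        retained = (gene.introns[0], boundaries[0])
        junctions = boundaries[1:]
    return ProcessedGene(
        cds=cds,
        junctions=junctions,
        retained_intron=retained,
        five_prime_flank=gene.five_prime_flank,
        three_prime_flank=gene.three_prime_flank,
    )


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_outputs(
    best: "Variant",
    cloud: "VariantCloud",
    processed: ProcessedGene,
    prefix: str | Path,
    plan: Optional["SitePlan"] = None,
) -> dict[str, Path]:
    """Write the four result files and return their paths.

    ``<prefix>_best.fasta``      best variant, flanks + retained intron (lowercase)
    ``<prefix>_variants.fasta``  every cloud variant, header carries objective/changes
    ``<prefix>_changes.tsv``     per-site change table (1-based CDS coordinates)
    ``<prefix>_summary.json``    achieved GC3, ESE density before/after, objective
    """
    prefix = Path(prefix)
    if prefix.parent != Path("."):
        prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "best": prefix.parent / (prefix.name + "_best.fasta"),
        "variants": prefix.parent / (prefix.name + "_variants.fasta"),
        "changes": prefix.parent / (prefix.name + "_changes.tsv"),
        "summary": prefix.parent / (prefix.name + "_summary.json"),
    }
    try:
        paths["best"].write_text(
            f">best objective={best.objective:.6f} changes={len(best.changes)} "
            f"gc3={best.achieved_gc3:.4f}\n" + _wrap(processed.spliced_output(best.cds)) + "\n"
        )
        with paths["variants"].open("w") as fh:
            for k, var in enumerate(cloud.variants):
                fh.write(
                    f">variant_{k} objective={var.objective:.6f} "
                    f"changes={len(var.changes)} gc3={var.achieved_gc3:.4f}\n"
                )
                fh.write(_wrap(processed.spliced_output(var.cds)) + "\n")
        with paths["changes"].open("w") as fh:
            fh.write("codon\tcds_position\toriginal_codon\tnew_codon\treason\n")
            for codon_index, old, new in best.changes:
                if plan is not None and plan.entries[codon_index].ese_eligible:
                    reason = "gc+ese"
                else:
                    reason = "gc"
                fh.write(f"{codon_index + 1}\t{3 * codon_index + 1}\t{old}\t{new}\t{reason}\n")
        summary = {
            "objective": best.objective,
            "n_changes": len(best.changes),
            "n_variants": len(cloud.variants),
            "achieved_gc3": best.achieved_gc3,
            "input_gc3": cloud.input_gc3,
            "ese_density_vicinity_before": cloud.input_ese_density,
            "ese_density_vicinity_after": (
                best.ese_density_vicinity.density
                if best.ese_density_vicinity is not None
                else None
            ),
        }
        paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing outputs under {prefix}: {exc}") from exc
    return paths
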
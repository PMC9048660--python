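"""Scoring synonymous codon candidates.

Two pressures drive codon choice:

* a GC target, under one of four strategies —
  ``one_two_exon``   position-dependent third-nucleotide probability
                     curves per codon box, emulating the 5'-high GC3 of
                     native one/two-exon human genes;
  ``max_gc``         favour G/C at every degenerate position;
  ``human_usage``    position-independent human codon usage;
  ``ese_only``       no GC component;
* ESE resemblance — the fraction of hexamer windows around a site that
  match the chosen ESE set after substituting a candidate.

Per-site scores are blended and linearly normalized into a selection
likelihood, so codon choice is stochastic rather than deterministic.

A codon *box* is a group of synonymous codons sharing their first two
nucleotides; 6-fold families (Leu, Ser, Arg) split into a 4-fold and a
2-fold sub-box and are always curve-scored within their sub-box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .ese_motifs import MOTIF_LENGTH, EseSet

# --------------------------------------------------------------------------
# Genetic code (standard table 1)

GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

_SIX_FOLD_SUB_BOXES: dict[str, list[list[str]]] = {
    "L": [["CTT", "CTC", "CTA", "CTG"], ["TTA", "TTG"]],
    "S": [["TCT", "TCC", "TCA", "TCG"], ["AGT", "AGC"]],
    "R": [["CGT", "CGC", "CGA", "CGG"], ["AGA", "AGG"]],
}

_DEGENERACY_CODE = {
    frozenset("ACGT"): "N",
    frozenset("CT"): "Y",
    frozenset("AG"): "R",
    frozenset("ACT"): "H",
}


@dataclass(frozen=True)
class CodonFamily:
    """All synonymous codons of one amino acid, with its sub-box partition."""

    amino_acid: str
    codons: tuple[str, ...]
    sub_boxes: tuple[tuple[str, ...], ...]
    degenerate_positions: tuple[int, ...]  # codon positions that vary in the family


def _build_families() -> dict[str, CodonFamily]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    families = {}
    for aa, codons in by_aa.items():
        codons = sorted(codons)
        if aa in _SIX_FOLD_SUB_BOXES:
            sub_boxes = tuple(tuple(b) for b in _SIX_FOLD_SUB_BOXES[aa])
        else:
            sub_boxes = (tuple(codons),)
        degenerate = tuple(
            p for p in range(3) if len({c[p] for c in codons}) > 1
        )
        families[aa] = CodonFamily(aa, tuple(codons), sub_boxes, degenerate)
    return families


FAMILIES: dict[str, CodonFamily] = _build_families()
FAMILY_OF_CODON: dict[str, CodonFamily] = {
    codon: FAMILIES[aa] for codon, aa in GENETIC_CODE.items()
}


def _box_name(codons: Sequence[str]) -> str:
    thirds = frozenset(c[2] for c in codons)
    code = _DEGENERACY_CODE.get(thirds, next(iter(thirds)) if len(thirds) == 1 else None)
    if code is None:  # pragma: no cover - standard code never hits this
        raise ValueError(f"unrecognized third-position set {sorted(thirds)}")
    return codons[0][:2] + code


#: codon -> name of its (sub-)box, e.g. CTG -> "CTN", TTA -> "TTR"
BOX_OF_CODON: dict[str, str] = {}
#: box name -> tuple of member codons
BOX_CODONS: dict[str, tuple[str, ...]] = {}
for _fam in FAMILIES.values():
    if _fam.amino_acid == "*":
        continue
    for _sub in _fam.sub_boxes:
        _name = _box_name(_sub)
        BOX_CODONS[_name] = tuple(_sub)
        for _c in _sub:
            BOX_OF_CODON[_c] = _name


def translate(cds: str) -> str:
    """Translate a CDS (length a multiple of 3) with the standard code."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    try:
        return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))
    except KeyError as exc:
        raise ValueError(f"invalid codon {exc.args[0]!r} in CDS") from exc


def synonymous_candidates(
    codon: str, policy: Literal["full_box", "sub_box"] = "full_box"
) -> list[str]:
    """Synonymous alternatives for a codon (the codon itself included).

    ``full_box`` considers every synonym of the amino acid (all six at
    6-fold sites); ``sub_box`` restricts 6-fold sites to the 4- or
    2-codon sub-box containing the input codon.
    """
    if codon in STOP_CODONS:
        raise ValueError("stop codons are immutable")
    family = FAMILY_OF_CODON.get(codon)
    if family is None:
        raise ValueError(f"not a valid codon: {codon!r}")
    if policy == "full_box":
        return list(family.codons)
    if policy == "sub_box":
        for sub in family.sub_boxes:
            if codon in sub:
                return list(sub)
        raise AssertionError  # pragma: no cover
    raise ValueError(f"unknown policy {policy!r}")


def is_degenerate(codon: str) -> bool:
    """True for sense codons with at least one synonymous alternative."""
    fam = FAMILY_OF_CODON.get(codon)
    return fam is not None and fam.amino_acid != "*" and len(fam.codons) > 1


# --------------------------------------------------------------------------
# GC target models

Strategy = Literal["ese_only", "one_two_exon", "max_gc", "human_usage"]

#: curve parameters: box name -> third nucleotide -> (floor, ceiling, tau)
CurveTable = dict[str, dict[str, tuple[float, float, float]]]


class ModelConfigError(ValueError):
    """A GC target model is missing an entry it needs."""


@dataclass
class GcTargetModel:
    """One of the four GC-targeting strategies.

    For ``one_two_exon`` the probability of third nucleotide ``n`` in
    box ``b`` at codon index ``i`` is

        p(n | b, i)  ∝  floor + (ceiling - floor) * exp(-i / tau)

    renormalized over the box's third nucleotides at each index.  For
    ``human_usage`` the score is the codon's usage frequency normalized
    within its amino-acid family.
    """

    strategy: Strategy
    curves: Optional[CurveTable] = None
    usage_table: Optional[dict[str, float]] = None  # codon -> within-family share

    def __post_init__(self) -> None:
        if self.strategy == "one_two_exon":
            if not self.curves:
                raise ModelConfigError("one_two_exon strategy requires curves")
            for box, codons in BOX_CODONS.items():
                if len(codons) < 2:
                    continue
                if box not in self.curves:
                    raise ModelConfigError(f"no curve entry for codon box {box}")
                for c in codons:
                    if c[2] not in self.curves[box]:
                        raise ModelConfigError(
                            f"no curve for nucleotide {c[2]} in codon box {box}"
                        )
        if self.strategy == "human_usage":
            if not self.usage_table:
                raise ModelConfigError("human_usage strategy requires a usage table")
            # normalize within each family once, up front
            norm: dict[str, float] = {}
            for fam in FAMILIES.values():
                if fam.amino_acid == "*":
                    continue
                missing = [c for c in fam.codons if c not in self.usage_table]
                if missing:
                    raise ModelConfigError(
                        f"usage table lacks codon(s) {', '.join(missing)}"
                    )
                total = sum(self.usage_table[c] for c in fam.codons)
                for c in fam.codons:
                    norm[c] = self.usage_table[c] / total if total > 0 else 1 / len(fam.codons)
            self.usage_table = norm

    # -- curve evaluation ---------------------------------------------------

    def box_probabilities(self, box: str, codon_index: int) -> dict[str, float]:
        """Renormalized third-nucleotide probabilities for a box at an index."""
        assert self.strategy == "one_two_exon" and self.curves is not None
        params = self.curves.get(box)
        if params is None:
            raise ModelConfigError(f"no curve entry for codon box {box}")
        raw = {}
        for nt, (floor, ceiling, tau) in params.items():
            raw[nt] = floor + (ceiling - floor) * float(np.exp(-codon_index / tau))
        total = sum(raw.values())
        if total <= 0:
            return {nt: 1 / len(raw) for nt in raw}
        return {nt: v / total for nt, v in raw.items()}

    @classmethod
    def default_one_two_exon(cls) -> "GcTargetModel":
        """The packaged default curve model (5'-high GC3 decaying with
        position)."""
        text = resources.files("intronless").joinpath("data/default_curves.yaml").read_text()
        return cls.from_curve_config(text)

    @classmethod
    def from_curve_config(cls, text: str) -> "GcTargetModel":
        """Parse a YAML curve config: box -> nucleotide -> {floor, ceiling, tau}."""
        data = yaml.safe_load(text)
        curves: CurveTable = {}
        for box, by_nt in data.items():
            curves[box] = {
                nt: (float(p["floor"]), float(p["ceiling"]), float(p["tau"]))
                for nt, p in by_nt.items()
            }
        return cls(strategy="one_two_exon", curves=curves)

    @classmethod
    def default_human_usage(cls) -> "GcTargetModel":
        """Human codon usage (Codon Usage Database frequencies per 1000)."""
        text = resources.files("intronless").joinpath("data/human_codon_usage.txt").read_text()
        return cls.from_usage_table(text)

    @classmethod
    def from_usage_table(cls, text: str) -> "GcTargetModel":
        """Parse a codon-usage text file: ``CODON  frequency`` per line,
        '#' comments; U accepted for T."""
        table: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ModelConfigError(f"usage table line {lineno}: expected 'CODON freq'")
            codon = fields[0].upper().replace("U", "T")
            if codon not in GENETIC_CODE:
                raise ModelConfigError(f"usage table line {lineno}: invalid codon {fields[0]!r}")
            table[codon] = float(fields[1])
        return cls(strategy="human_usage", usage_table=table)

    @classmethod
    def max_gc(cls) -> "GcTargetModel":
        return cls(strategy="max_gc")

    @classmethod
    def ese_only(cls) -> "GcTargetModel":
        return cls(strategy="ese_only")


def gc_score(
    candidate: str,
    codon_index: int,
    model: GcTargetModel,
    n_candidates: int = 1,
) -> float:
    """GC-target score of one candidate codon in [0, 1].

    ``n_candidates`` matters only for ``ese_only``, whose flat score is
    1/n so the GC component carries no preference.
    """
    if candidate in STOP_CODONS or candidate not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {candidate!r}")
    if model.strategy == "max_gc":
        fam = FAMILY_OF_CODON[candidate]
        if not fam.degenerate_positions:
            return 1.0
        gc = sum(1 for p in fam.degenerate_positions if candidate[p] in "GC")
        return gc / len(fam.degenerate_positions)
    if model.strategy == "human_usage":
        assert model.usage_table is not None
        return model.usage_table[candidate]
    if model.strategy == "one_two_exon":
        box = BOX_OF_CODON[candidate]
        if len(BOX_CODONS[box]) == 1:
            return 1.0
        return model.box_probabilities(box, codon_index)[candidate[2]]
    if model.strategy == "ese_only":
        return 1.0 / max(1, n_candidates)
    raise ValueError(f"unknown strategy {model.strategy!r}")


def expected_gc3(codon: str, codon_index: int, model: GcTargetModel) -> float:
    """Target probability that the third position of this site is G or C.

    Used to build the per-bin GC3 target profile the objective compares
    against; defined for degenerate sense codons.
    """
    fam = FAMILY_OF_CODON[codon]
    if model.strategy == "max_gc":
        return 1.0
    if model.strategy == "ese_only":
        return 0.0  # no GC component; callers skip the GC3 term entirely
    if model.strategy == "human_usage":
        assert model.usage_table is not None
        return sum(model.usage_table[c] for c in fam.codons if c[2] in "GC")
    # one_two_exon: probability mass on G/C thirds within the codon's box
    box = BOX_OF_CODON[codon]
    probs = model.box_probabilities(box, codon_index)
    return sum(p for nt, p in probs.items() if nt in "GC")


# --------------------------------------------------------------------------
# ESE resemblance

def variable_positions(candidates: Sequence[str]) -> list[int]:
    """Codon positions (0..2) at which the candidate set differs."""
    return [p for p in range(3) if len({c[p] for c in candidates}) > 1]


def ese_score(
    context: str,
    covered_positions: Iterable[int],
    ese_set: EseSet,
    mode: Literal["increase", "decrease"],
) -> float:
    """ESE resemblance of a candidate already substituted into ``context``.

    ``covered_positions`` are the context offsets the candidate can
    change.  Over the hexamer windows overlapping any of them, the score
    is the matching fraction m/w (``increase``) or 1 - m/w
    (``decrease``); with no windows (w = 0) it is neutral at 0.5.
    """
    starts: set[int] = set()
    for pos in covered_positions:
        lo = max(0, pos - (MOTIF_LENGTH - 1))
        hi = min(pos, len(context) - MOTIF_LENGTH)
        starts.update(range(lo, hi + 1))
    if not starts:
        return 0.5
    m = sum(1 for s in starts if context[s : s + MOTIF_LENGTH] in ese_set.motifs)
    frac = m / len(starts)
    return frac if mode == "increase" else 1.0 - frac


def selection_probabilities(
    gc_scores: Sequence[float],
    ese_scores: Optional[Sequence[float]],
    weight: float = 0.5,
    ese_active: bool = False,
) -> np.ndarray:
    """Convert per-candidate scores into a selection likelihood.

    combined_i = (1 - λ)·gc_i + λ·ese_i when the ESE component is
    active, else gc_i; probabilities are the linear normalization of the
    combined scores (uniform if they sum to zero).
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"ESE weight λ must be in [0, 1], got {weight}")
    gc = np.asarray(gc_scores, dtype=float)
    if gc.size == 0:
        raise ValueError("at least one candidate is required")
    if ese_active:
        if ese_scores is None or len(ese_scores) != gc.size:
            raise ValueError("ese_scores must match gc_scores in length")
        combined = (1.0 - weight) * gc + weight * np.asarray(ese_scores, dtype=float)
    else:
        combined = gc
    total = combined.sum()
    if total <= 0:
        return np.full(gc.size, 1.0 / gc.size)
    return combined / total


# --------------------------------------------------------------------------
# Fitting position-dependent curves from training CDSs

def _decay(i, floor, ceiling, tau):
    return floor + (ceiling - floor) * np.exp(-i / tau)


def fit_position_curves(
    training: Sequence[str], bin_codons: int = 10, max_codons: int | None = None
) -> GcTargetModel:
    """Rebuild the one_two_exon curve table from training CDSs.

    Third-nucleotide frequencies per codon box are tabulated in bins of
    ``bin_codons`` codon positions, then least-squares fitted to
    floor + (ceiling - floor)·exp(-i/τ) per (box, nucleotide), weighting
    bins by their observation counts.  Boxes absent from the training
    data fall back to a flat uniform curve with a warning.
    """
    if len(training) < 10:
        raise ValueError(f"need at least 10 training CDSs, got {len(training)}")
    # counts[box][nt][bin]
    counts: dict[str, dict[str, dict[int, int]]] = {
        box: {c[2]: {} for c in codons}
        for box, codons in BOX_CODONS.items()
        if len(codons) > 1
    }
    for cds in training:
        if len(cds) % 3:
            raise ValueError("every training CDS must have length a multiple of 3")
        n = len(cds) // 3
        if max_codons is not None:
            n = min(n, max_codons)
        for i in range(n):
            codon = cds[3 * i : 3 * i + 3]
            box = BOX_OF_CODON.get(codon)
            if box is None or box not in counts:
                continue
            b = i // bin_codons
            counts[box][codon[2]][b] = counts[box][codon[2]].get(b, 0) + 1
    curves: CurveTable = {}
    for box, by_nt in counts.items():
        bins = sorted({b for d in by_nt.values() for b in d})
        totals = {b: sum(d.get(b, 0) for d in by_nt.values()) for b in bins}
        usable = [b for b in bins if totals[b] > 0]
        if not usable:
            warnings.warn(
                f"codon box {box} absent from training data; using a flat uniform curve"
            )
            curves[box] = {nt: (1 / len(by_nt), 1 / len(by_nt), 1.0) for nt in by_nt}
            continue
        x = np.array([(b + 0.5) * bin_codons for b in usable])
        w = np.array([totals[b] for b in usable], dtype=float)
        curves[box] = {}
        for nt, d in by_nt.items():
            y = np.array([d.get(b, 0) / totals[b] for b in usable])
            curves[box][nt] = _fit_one_curve(x, y, w)
    return GcTargetModel(strategy="one_two_exon", curves=curves)


def _fit_one_curve(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> tuple[float, float, float]:
    mean = float(np.average(y, weights=weights))
    flat = (mean, mean, 1.0)
    if len(x) < 4 or float(np.ptp(y)) < 1e-9:
        return flat
    sigma = 1.0 / np.sqrt(weights)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _decay,
                x,
                y,
                p0=[float(y[-1]), float(y[0]), float(max(x.mean(), 1.0))],
                sigma=sigma,
                bounds=([0.0, 0.0, 1e-3], [1.0, 1.0, 1e5]),
                maxfev=20000,
            )
    except RuntimeError:
        return flat
    # keep the 3-parameter curve only if it beats the 1-parameter flat
    # model on AIC; otherwise noise alone drives floor/ceiling/tau apart
    n = len(x)
    w = weights / weights.mean()
    sse_curve = float(np.sum(w * (y - _decay(x, *popt)) ** 2))
    sse_flat = float(np.sum(w * (y - mean) ** 2))
    eps = 1e-12
    aic_curve = n * np.log(max(sse_curve, eps) / n) + 2 * 3
    aic_flat = n * np.log(max(sse_flat, eps) / n) + 2 * 1
    if aic_curve >= aic_flat:
        return flat
    return float(popt[0]), float(popt[1]), float(popt[2])
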
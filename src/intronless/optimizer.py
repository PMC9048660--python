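"""Stochastic recoding: site planning, variant generation and selection.

The generator moves 5'→3' over the CDS, one synonymous site at a time.
At each mutable codon it scores the synonymous candidates (GC target,
plus ESE resemblance when the site lies within the vicinity of a
removed intron), converts scores into a selection likelihood and draws
one candidate.  A draw that would newly introduce a blacklisted motif —
anywhere in the working context, flanks and a retained intron included
— is reverted and the site left as is.  Committed choices are visible
to later sites.  Repeating this populates the variant cloud, from which
the variant with the lowest target deviation is selected.

Codons overlapping a protected restriction-enzyme match (either strand
of the original sequence) are never touched.  Protection is computed on
the original sequence only: recoding may create *new* recognition
sites unless they are also blacklisted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .ese_motifs import EseDensity, EseSet, ese_match_count
from .gene_io import ProcessedGene
from .scoring import (
    STOP_CODONS,
    GcTargetModel,
    ese_score,
    gc_score,
    is_degenerate,
    selection_probabilities,
    synonymous_candidates,
    translate,
    variable_positions,
)

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

BIN_CODONS = 10  # codons per bin for GC3 profiles and the objective


def iupac_reverse_complement(pattern: str) -> str:
    bad = set(pattern) - set(_IUPAC_COMPLEMENT)
    if bad:
        raise ValueError(
            f"invalid IUPAC character {', '.join(repr(c) for c in sorted(bad))} "
            f"in pattern {pattern!r}"
        )
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern:
        letters = IUPAC_CODES.get(c)
        if letters is None:
            raise ValueError(f"invalid IUPAC character {c!r} in pattern {pattern!r}")
        parts.append(letters if len(letters) == 1 else f"[{letters}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def _find_all(seq: str, regex: re.Pattern, length: int) -> list[tuple[int, int]]:
    return [(m.start(), m.start() + length) for m in regex.finditer(seq)]


def find_restriction_matches(
    seq: str, patterns: Sequence[str]
) -> list[tuple[int, int]]:
    """All 0-based half-open match intervals of each IUPAC pattern on the
    given strand and of its reverse complement (minus-strand recognition).
    Overlaps allowed; intervals are deduplicated and sorted."""
    hits: set[tuple[int, int]] = set()
    for pattern in patterns:
        pattern = pattern.upper()
        for pat in {pattern, iupac_reverse_complement(pattern)}:
            hits.update(_find_all(seq, _iupac_regex(pat), len(pat)))
    return sorted(hits)


@dataclass
class DesignConfig:
    """Everything that shapes one design run."""

    gc_strategy: Literal["ese_only", "one_two_exon", "max_gc", "human_usage"] = "one_two_exon"
    ese_mode: Literal["off", "increase", "decrease"] = "off"
    ese_set: Optional[EseSet] = None
    ese_weight: float = 0.5
    vicinity_nt: int = 70
    ese_in_cores: bool = False
    sixfold_policy: Literal["full_box", "sub_box"] = "full_box"
    keep_first_intron: bool = True
    protect_enzymes: tuple[str, ...] = ()
    avoid_motifs: tuple[str, ...] = ()
    n_variants: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vicinity_nt < 0:
            raise ValueError("vicinity_nt must be >= 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.ese_weight <= 1.0:
            raise ValueError("ese_weight must be in [0, 1]")
        if self.ese_mode != "off" and self.ese_set is None:
            raise ValueError("ese set required when ese_mode is not 'off'")
        self.protect_enzymes = tuple(p.upper() for p in self.protect_enzymes)
        self.avoid_motifs = tuple(m.upper() for m in self.avoid_motifs)


@dataclass(frozen=True)
class SiteEntry:
    codon_index: int
    codon: str
    mutable: bool
    ese_eligible: bool
    protection_reason: Optional[str]  # restriction | no_synonyms | stop | start


@dataclass
class SitePlan:
    """Per-codon mutability/eligibility decisions for one design."""

    entries: list[SiteEntry]
    protected_intervals: list[tuple[int, int]]  # working-sequence coordinates

    def mutable_indices(self) -> list[int]:
        return [e.codon_index for e in self.entries if e.mutable]


def _vicinity_intervals(
    junctions: Sequence[int], vicinity_nt: int, cds_length: int
) -> list[tuple[int, int]]:
    """Merged [j - v, j + v) windows, clipped to the CDS."""
    raw = sorted(
        (max(0, j - vicinity_nt), min(cds_length, j + vicinity_nt)) for j in junctions
    )
    merged: list[tuple[int, int]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return [iv for iv in merged if iv[1] > iv[0]]


def build_site_plan(processed: ProcessedGene, config: DesignConfig) -> SitePlan:
    """Decide, per codon, whether it may be recoded and whether its
    candidates are scored for ESE resemblance."""
    working, cds2w = processed.working_sequence()
    protected = find_restriction_matches(working, config.protect_enzymes)
    blocked: set[int] = set()
    for lo, hi in protected:
        blocked.update(range(lo, hi))
    cds = processed.cds
    n_codons = len(cds) // 3
    vicinity = _vicinity_intervals(processed.junctions, config.vicinity_nt, len(cds))
    entries = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        reason: Optional[str] = None
        if codon in STOP_CODONS:
            reason = "stop"
        elif i == 0:
            reason = "start"
        elif len(synonymous_candidates(codon, config.sixfold_policy)) < 2:
            reason = "no_synonyms"
        elif any(cds2w[p] in blocked for p in range(3 * i, 3 * i + 3)):
            reason = "restriction"
        if config.ese_mode == "off":
            eligible = False
        elif config.ese_in_cores:
            eligible = True
        else:
            eligible = any(
                lo <= p < hi
                for lo, hi in vicinity
                for p in range(3 * i, 3 * i + 3)
            )
        entries.append(
            SiteEntry(
                codon_index=i,
                codon=codon,
                mutable=reason is None,
                ese_eligible=eligible,
                protection_reason=reason,
            )
        )
    return SitePlan(entries=entries, protected_intervals=protected)


# --------------------------------------------------------------------------
# Variant statistics and objective

@dataclass
class Variant:
    """One recoded CDS with its achieved statistics."""

    cds: str
    changes: list[tuple[int, str, str]]  # (codon_index, from, to)
    achieved_gc3: float
    achieved_gc3_profile: list[Optional[float]]  # per 10-codon bin; None if no degenerate codon
    ese_density_vicinity: Optional[EseDensity]
    objective: float


@dataclass
class VariantCloud:
    """The population of generated variants and the index of the best."""

    variants: list[Variant]
    best_index: int
    input_gc3: float
    input_ese_density: Optional[float]

    @property
    def best(self) -> Variant:
        return self.variants[self.best_index]

    def unique_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.cds, None)
        return list(seen)


def gc3_profile(cds: str) -> tuple[float, list[Optional[float]]]:
    """Overall and per-bin fraction of G/C third positions over
    degenerate codons (codons with synonymous alternatives)."""
    n_codons = len(cds) // 3
    n_bins = (n_codons + BIN_CODONS - 1) // BIN_CODONS
    gc = [0] * n_bins
    tot = [0] * n_bins
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if not is_degenerate(codon):
            continue
        b = i // BIN_CODONS
        tot[b] += 1
        gc[b] += codon[2] in "GC"
    profile = [g / t if t else None for g, t in zip(gc, tot)]
    overall = sum(gc) / sum(tot) if sum(tot) else 0.0
    return overall, profile


def _target_gc3_profile(
    cds: str, model: GcTargetModel
) -> list[Optional[float]]:
    from .scoring import expected_gc3

    n_codons = len(cds) // 3
    n_bins = (n_codons + BIN_CODONS - 1) // BIN_CODONS
    acc = [0.0] * n_bins
    tot = [0] * n_bins
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if not is_degenerate(codon):
            continue
        b = i // BIN_CODONS
        acc[b] += expected_gc3(codon, i, model)
        tot[b] += 1
    return [a / t if t else None for a, t in zip(acc, tot)]


def vicinity_density(
    cds: str, junctions: Sequence[int], vicinity_nt: int, ese_set: EseSet
) -> EseDensity:
    """Aggregate hexamer-window ESE density over all vicinity regions."""
    windows = matches = 0
    for lo, hi in _vicinity_intervals(junctions, vicinity_nt, len(cds)):
        d = ese_match_count(cds, lo, hi, ese_set)
        windows += d.window_count
        matches += d.match_count
    return EseDensity(window_count=windows, match_count=matches)


def score_variant(
    cds: str,
    changes: list[tuple[int, str, str]],
    processed: ProcessedGene,
    model: GcTargetModel,
    config: DesignConfig,
) -> Variant:
    """Assemble a Variant with its deviation-from-target objective.

    objective = mean over 10-codon bins of |achieved GC3 - target GC3|
    (omitted under ese_only) + |vicinity ESE density - target density|
    when the ESE component is on (target 1 for increase, 0 for
    decrease).  Lower is better; 0 means on-target everywhere.
    """
    achieved, profile = gc3_profile(cds)
    objective = 0.0
    if model.strategy != "ese_only":
        target = _target_gc3_profile(cds, model)
        devs = [
            abs(a - t) for a, t in zip(profile, target) if a is not None and t is not None
        ]
        if devs:
            objective += sum(devs) / len(devs)
    density: Optional[EseDensity] = None
    if config.ese_mode != "off":
        assert config.ese_set is not None
        density = vicinity_density(
            cds, processed.junctions, config.vicinity_nt, config.ese_set
        )
        target_density = 1.0 if config.ese_mode == "increase" else 0.0
        if density.window_count:
            objective += abs(density.density - target_density)
    return Variant(
        cds=cds,
        changes=changes,
        achieved_gc3=achieved,
        achieved_gc3_profile=profile,
        ese_density_vicinity=density,
        objective=objective,
    )


# --------------------------------------------------------------------------
# Generation

def _new_motif_introduced(
    working: list[str],
    mapped: Sequence[int],
    new_chars: Sequence[str],
    avoid_regexes: Sequence[tuple[re.Pattern, int]],
    lmax: int,
) -> bool:
    """Would writing ``new_chars`` at ``mapped`` working positions create
    an avoid-motif occurrence absent at the same offsets beforehand?"""
    lo = max(0, min(mapped) - (lmax - 1))
    hi = min(len(working), max(mapped) + 1 + (lmax - 1))
    before = "".join(working[lo:hi])
    after = list(before)
    for p, c in zip(mapped, new_chars):
        after[p - lo] = c
    after = "".join(after)
    for regex, length in avoid_regexes:
        hits_before = {m.start() for m in regex.finditer(before)}
        for m in regex.finditer(after):
            if m.start() not in hits_before:
                return True
    return False


def generate_variant(
    processed: ProcessedGene,
    plan: SitePlan,
    model: GcTargetModel,
    config: DesignConfig,
    rng: np.random.Generator,
) -> Variant:
    """Draw one recoded variant by the 5'→3' stochastic sliding pass."""
    cds_chars = list(processed.cds)
    working, cds2w = processed.working_sequence()
    working_chars = list(working)
    avoid_regexes = [
        (_iupac_regex(m), len(m)) for m in config.avoid_motifs
    ]
    lmax = max((len(m) for m in config.avoid_motifs), default=0)
    ese_on = config.ese_mode != "off"
    changes: list[tuple[int, str, str]] = []
    for entry in plan.entries:
        if not entry.mutable:
            continue
        i = entry.codon_index
        original = entry.codon
        candidates = synonymous_candidates(original, config.sixfold_policy)
        site_ese = ese_on and entry.ese_eligible
        if model.strategy == "ese_only" and not site_ese:
            continue  # no active scoring component; retain the codon
        gc_scores = [gc_score(c, i, model, len(candidates)) for c in candidates]
        ese_scores = None
        if site_ese:
            assert config.ese_set is not None
            varpos = variable_positions(candidates)
            covered = [3 * i + p for p in varpos]
            lo = max(0, min(covered) - 5)
            hi = min(len(cds_chars), max(covered) + 6)
            local = cds_chars[lo:hi]
            ese_scores = []
            for cand in candidates:
                trial = list(local)
                for p in varpos:
                    trial[3 * i + p - lo] = cand[p]
                ese_scores.append(
                    ese_score(
                        "".join(trial),
                        [c - lo for c in covered],
                        config.ese_set,
                        config.ese_mode,
                    )
                )
        probs = selection_probabilities(
            gc_scores, ese_scores, config.ese_weight, ese_active=site_ese
        )
        choice = candidates[int(rng.choice(len(candidates), p=probs))]
        if choice == original:
            continue
        mapped = [cds2w[p] for p in range(3 * i, 3 * i + 3)]
        if avoid_regexes and _new_motif_introduced(
            working_chars, mapped, choice, avoid_regexes, lmax
        ):
            continue  # would introduce a blacklisted motif: leave site as is
        for off, (p, w) in enumerate(zip(range(3 * i, 3 * i + 3), mapped)):
            cds_chars[p] = choice[off]
            working_chars[w] = choice[off]
        changes.append((i, original, choice))
    cds = "".join(cds_chars)
    assert translate(cds) == translate(processed.cds)
    return score_variant(cds, changes, processed, model, config)


def generate_cloud(
    processed: ProcessedGene,
    plan: SitePlan,
    model: GcTargetModel,
    config: DesignConfig,
) -> VariantCloud:
    """Generate ``n_variants`` independent variants and pick the best.

    Each variant draws from its own RNG sub-stream derived from
    (seed, variant index), so identical (input, config, seed) always
    yields an identical cloud.  Best = lowest objective, ties broken by
    fewest changes, then generation order.
    """
    variants = []
    best_key = None
    best_index = 0
    for k in range(config.n_variants):
        rng = np.random.default_rng([config.seed, k])
        var = generate_variant(processed, plan, model, config, rng)
        key = (var.objective, len(var.changes), k)
        if best_key is None or key < best_key:
            best_key, best_index = key, k
        variants.append(var)
    input_density = None
    if config.ese_mode != "off" and config.ese_set is not None:
        input_density = vicinity_density(
            processed.cds, processed.junctions, config.vicinity_nt, config.ese_set
        ).density
    input_gc3, _ = gc3_profile(processed.cds)
    return VariantCloud(
        variants=variants,
        best_index=best_index,
        input_gc3=input_gc3,
        input_ese_density=input_density,
    )
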
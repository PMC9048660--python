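"""Hexamer exonic-splice-enhancer (ESE) motif sets and window statistics.

ESEs are hexameric exonic motifs bound by SR proteins.  Five published
sets are recognized by name — RESCUE-ESE, ESR, Ke-ESE400, PESE and their
>=3-of-4 intersection INT3.  Their contents are supplements of the
papers that defined them and are not bundled here; the loader accepts a
one-motif-per-line file for any of them (or any user-defined set).

Match counting is window-based: every hexamer window counts, overlaps
included, and density is matches per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

PREDEFINED_SET_NAMES = ("RESCUE-ESE", "ESR", "Ke-ESE400", "PESE", "INT3")

MOTIF_LENGTH = 6
_DNA = frozenset("ACGT")


class EseSetError(ValueError):
    """Raised for malformed or unavailable motif sets."""


@dataclass(frozen=True)
class EseSet:
    """A named set of distinct ESE hexamers."""

    name: str
    motifs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise EseSetError(f"ESE set '{self.name}' is empty")
        for m in self.motifs:
            if len(m) != MOTIF_LENGTH:
                raise EseSetError(
                    f"ESE set '{self.name}': motif '{m}' has length {len(m)} != 6"
                )
            if set(m) - _DNA:
                raise EseSetError(
                    f"ESE set '{self.name}': motif '{m}' has characters outside ACGT"
                )

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in self.motifs


@dataclass(frozen=True)
class EseDensity:
    """Hexamer-window match statistics over a region.

    ``window_count`` is the number of hexamer windows evaluated
    (``max(0, region_length - 5)``), ``density`` = matches per window.
    """

    window_count: int
    match_count: int

    @property
    def density(self) -> float:
        return self.match_count / self.window_count if self.window_count else 0.0


def _parse_lines(lines: Iterable[str], name: str) -> EseSet:
    motifs = set()
    for lineno, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        motif = line.upper().replace("U", "T")
        if len(motif) != MOTIF_LENGTH:
            raise EseSetError(
                f"line {lineno}: motif '{line}' has length {len(motif)}, expected 6"
            )
        bad = set(motif) - _DNA
        if bad:
            raise EseSetError(
                f"line {lineno}: motif '{line}' has invalid character(s) "
                f"{', '.join(sorted(bad))}"
            )
        motifs.add(motif)
    if not motifs:
        raise EseSetError(f"no motifs found for ESE set '{name}'")
    return EseSet(name=name, motifs=frozenset(motifs))


def _bundled_path(name: str):
    return resources.files("intronless").joinpath(f"data/ese/{name}.txt")


def list_ese_sets() -> dict[str, bool]:
    """The five recognized predefined set names, each flagged bundled or not."""
    return {name: _bundled_path(name).is_file() for name in PREDEFINED_SET_NAMES}


def load_ese_set(
    source: Union[str, Path, Iterable[str]], name: str | None = None
) -> EseSet:
    """Load an ESE set from a predefined name, a file path, or lines.

    Lines hold one hexamer each; ``#`` comments and blank lines are
    ignored; U is normalized to T.  A predefined name whose motif list is
    not bundled raises an instructive error.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source not in PREDEFINED_SET_NAMES
    ):
        path = Path(source)
        if not path.is_file():
            raise EseSetError(
                f"'{source}' is neither a predefined ESE set "
                f"({', '.join(PREDEFINED_SET_NAMES)}) nor an existing motif file"
            )
        return _parse_lines(path.read_text().splitlines(), name or path.stem)
    if isinstance(source, str):  # predefined name
        bundled = _bundled_path(source)
        if not bundled.is_file():
            raise EseSetError(
                f"ESE set '{source}' is recognized but its motif list is not "
                f"bundled (it is published as a supplement of the defining "
                f"paper); supply it as a one-motif-per-line file"
            )
        return _parse_lines(bundled.read_text().splitlines(), source)
    return _parse_lines(source, name or "user")


def overlapping_windows(position: int, seq_length: int) -> list[int]:
    """Start offsets of every hexamer window covering ``position``."""
    if not 0 <= position < seq_length:
        raise ValueError(f"position {position} outside sequence of length {seq_length}")
    lo = max(0, position - (MOTIF_LENGTH - 1))
    hi = min(position, seq_length - MOTIF_LENGTH)
    return list(range(lo, hi + 1))


def ese_match_count(seq: str, start: int, end: int, ese_set: EseSet) -> EseDensity:
    """Count matching hexamer windows fully contained in ``seq[start:end]``."""
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"region [{start}, {end}) outside sequence of length {len(seq)}")
    window_count = max(0, (end - start) - (MOTIF_LENGTH - 1))
    matches = sum(
        1
        for s in range(start, start + window_count)
        if seq[s : s + MOTIF_LENGTH] in ese_set.motifs
    )
    return EseDensity(window_count=window_count, match_count=matches)
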
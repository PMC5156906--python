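"""Position-class motif definitions and scanning.

The calcineurin docking motifs handled here are exact position-class
(PROSITE-style) patterns: each motif position admits a fixed set of
amino acids, or any residue at a wildcard position.  The LxVP family is
expressed as three nested six-residue definitions around the L-x-V-P
core,

* ``canonical_pilxvp``   [NQDESRTH]-[YTDFILV]-L-x-V-P
* ``expanded_pilxvp``    [NQDESRTH]-[YTDFILV]-L-x-[VPL]-[PK]
* ``structural_pilxvp``  [NQDESRTH]-[YTDFILV]-L-x-[VPLIH]-x

where position -2 (the "pi" position) accepts polar hydrogen-bond
donor/acceptor side chains and position -1 (the "phi" position) accepts
the residues seen in experimentally confirmed sites.  The two PxIxIT
dialects, ``pxixit_short`` [P]-x-x-x-[IV]-[TDH] and ``pxixit_long``
[P]-x-x-x-x-[IV]-[TDH], model the second docking surface with 3- and
4-residue spacers.

Matching is exact set membership — no scoring, no PWM softening.  All
coordinates are 1-based inclusive, matching the superscript convention
used for protein sites (e.g. QYLAVP at 384..390 of NFATc1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CANONICAL_AA",
    "AMBIGUITY_AA",
    "ResidueClass",
    "MotifDefinition",
    "MotifMatch",
    "build_motif_library",
    "scan",
    "scan_pxixit",
    "classify_hexamer",
    "parse_prosite",
    "PXIXIT_DIALECTS",
]

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes that may appear in real proteomes.
#: They fail every constrained position and satisfy wildcards only.
AMBIGUITY_AA = frozenset("XBZUO")


@dataclass(frozen=True)
class ResidueClass:
    """One motif position: an allowed-residue set or a wildcard.

    ``residues`` keeps the residues in their written order so that a
    pattern round-trips through its PROSITE string bit-exactly;
    membership tests use the derived frozen set.
    """

    residues: str = ""
    wildcard: bool = False
    allowed: frozenset = field(init=False, repr=False)

    def __post_init__(self):
        if self.wildcard:
            if self.residues:
                raise ValueError("wildcard position must not list residues")
            object.__setattr__(self, "allowed", CANONICAL_AA)
            return
        if not self.residues:
            raise ValueError("constrained position needs >= 1 residue")
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise ValueError(f"non-canonical residues in class: {sorted(bad)}")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError(f"duplicate residues in class: {self.residues}")
        object.__setattr__(self, "allowed", frozenset(self.residues))

    def matches(self, residue: str) -> bool:
        """True if ``residue`` satisfies this position.

        Wildcards accept anything, including ambiguity codes; a
        constrained position accepts only its listed canonical residues.
        """
        if self.wildcard:
            return True
        return residue in self.allowed

    def to_prosite(self) -> str:
        if self.wildcard:
            return "x"
        if len(self.residues) == 1:
            return self.residues
        return f"[{self.residues}]"

    def regex(self) -> str:
        # wildcard must also accept ambiguity codes
        return "[A-Z]" if self.wildcard else f"[{self.residues}]"


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered list of residue classes with a name."""

    name: str
    positions: tuple

    def __post_init__(self):
        if not isinstance(self.positions, tuple):
            object.__setattr__(self, "positions", tuple(self.positions))
        if len(self.positions) < 4:
            raise ValueError(f"motif {self.name!r}: length must be >= 4")
        for p in self.positions:
            if not isinstance(p, ResidueClass):
                raise TypeError("positions must be ResidueClass instances")

    @property
    def length(self) -> int:
        return len(self.positions)

    def to_prosite(self) -> str:
        """Serialize to a PROSITE-style pattern string."""
        return "-".join(p.to_prosite() for p in self.positions)

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all reported
        return re.compile("(?=(" + "".join(p.regex() for p in self.positions) + "))")

    def accepts(self, window: str) -> bool:
        """Exact position-class check of a window of the motif's length."""
        if len(window) != self.length:
            return False
        return all(p.matches(r) for p, r in zip(self.positions, window))


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: 1-based inclusive coordinates in a protein."""

    protein_id: str
    start: int
    end: int
    sequence: str
    motif: str
    dialect: str | None = None

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with matched sequence")


def parse_prosite(name: str, pattern: str) -> MotifDefinition:
    """Parse a PROSITE-style pattern like ``[NQDESRTH]-[YTDFILV]-L-x-V-P``."""
    positions = []
    for tok in pattern.split("-"):
        if tok == "x":
            positions.append(ResidueClass(wildcard=True))
        elif tok.startswith("[") and tok.endswith("]"):
            positions.append(ResidueClass(tok[1:-1]))
        elif len(tok) == 1:
            positions.append(ResidueClass(tok))
        else:
            raise ValueError(f"cannot parse pattern element {tok!r}")
    return MotifDefinition(name, tuple(positions))


_LIBRARY_PATTERNS = {
    "core_lxvp": "L-x-V-P",
    "canonical_pilxvp": "[NQDESRTH]-[YTDFILV]-L-x-V-P",
    "expanded_pilxvp": "[NQDESRTH]-[YTDFILV]-L-x-[VPL]-[PK]",
    "structural_pilxvp": "[NQDESRTH]-[YTDFILV]-L-x-[VPLIH]-x",
    "pxixit_short": "P-x-x-x-[IV]-[TDH]",
    "pxixit_long": "P-x-x-x-x-[IV]-[TDH]",
}

PXIXIT_DIALECTS = {"short": "pxixit_short", "long": "pxixit_long"}


_CACHED_LIBRARY: dict | None = None


def _library() -> dict:
    global _CACHED_LIBRARY
    if _CACHED_LIBRARY is None:
        _CACHED_LIBRARY = build_motif_library()
    return _CACHED_LIBRARY


def build_motif_library() -> dict:
    """Return the named motif definitions used throughout the pipeline.

    Keys: ``core_lxvp``, ``canonical_pilxvp``, ``expanded_pilxvp``,
    ``structural_pilxvp``, ``pxixit_short``, ``pxixit_long``.  The three
    six-residue LxVP definitions form a containment chain: every
    canonical match is an expanded match, every expanded match is a
    structural match ({V} < {V,P,L} < {V,P,L,I,H} and {P} < {P,K} < any).
    """
    return {name: parse_prosite(name, pat) for name, pat in _LIBRARY_PATTERNS.items()}


def scan(sequence: str, motif: MotifDefinition) -> list:
    """Find every occurrence of ``motif`` in ``sequence``.

    Overlapping matches are all reported (PROSITE-style; no consumed
    text), in ascending start order, with 1-based inclusive coordinates.
    The sequence is uppercased before matching.  Ambiguity codes
    (X, B, Z, U, O) fail constrained positions and pass wildcards.
    """
    if not isinstance(sequence, str):
        raise TypeError("sequence must be a string")
    if not isinstance(motif, MotifDefinition) or motif.length == 0:
        raise ValueError("motif must be a non-empty MotifDefinition")
    seq = sequence.upper()
    out = []
    for m in motif.regex().finditer(seq):
        window = m.group(1)
        start = m.start() + 1
        out.append(
            MotifMatch(
                protein_id="",
                start=start,
                end=start + motif.length - 1,
                sequence=window,
                motif=motif.name,
            )
        )
    return out


def scan_pxixit(sequence: str, dialects=("short", "long")) -> list:
    """Scan for PxIxIT occurrences with the selected dialect(s).

    ``dialects`` is a subset of {"short", "long"}; matches from the
    selected dialects are pooled (deduplicated by start and dialect,
    which scanning each dialect once already guarantees), each labeled
    with its dialect, sorted by (start, dialect).
    """
    dialects = set(dialects)
    if not dialects:
        raise ValueError("dialect set must be non-empty")
    unknown = dialects - set(PXIXIT_DIALECTS)
    if unknown:
        raise ValueError(f"unknown PxIxIT dialect(s): {sorted(unknown)}")
    lib = _library()
    out = []
    for dialect in sorted(dialects):
        for m in scan(sequence, lib[PXIXIT_DIALECTS[dialect]]):
            out.append(
                MotifMatch(
                    protein_id=m.protein_id,
                    start=m.start,
                    end=m.end,
                    sequence=m.sequence,
                    motif=m.motif,
                    dialect=dialect,
                )
            )
    out.sort(key=lambda m: (m.start, m.dialect))
    return out


def classify_hexamer(hexamer: str) -> str:
    """Assign a six-residue window to its LxVP motif class.

    Returns ``canonical`` if the hexamer satisfies the canonical
    definition; otherwise ``expanded_only`` if it satisfies the expanded
    definition; otherwise ``structural_only`` if it satisfies the
    structural definition; otherwise ``no_match``.  Precedence follows
    the containment chain, so the labels are mutually exclusive and
    exhaustive.
    """
    if not isinstance(hexamer, str) or len(hexamer) != 6:
        raise ValueError("hexamer must be a 6-residue string")
    hexamer = hexamer.upper()
    lib = _library()
    if lib["canonical_pilxvp"].accepts(hexamer):
        return "canonical"
    if lib["expanded_pilxvp"].accepts(hexamer):
        return "expanded_only"
    if lib["structural_pilxvp"].accepts(hexamer):
        return "structural_only"
    return "no_match"
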
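"""Post-funnel descriptive analytics.

Three summaries of the surviving candidates:

* phosphosite geometry — for each motif occurrence, the distance and
  orientation (N- vs C-terminal) of the nearest qualifying pSer/pThr.
  The defaults require a site to sit at least 9 residues C-terminal or
  20 residues N-terminal of the motif edge, the separations needed for
  a docked, disordered segment to reach across the ~30 A gap to the
  phosphatase active site;
* position probability matrices — per-column residue frequencies of the
  aligned motif instances (the numeric core of a sequence logo), with
  per-column information content in bits;
* localization breakdowns — category counts/fractions over a protein
  set, unknowns binned as ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .motifs import CANONICAL_AA
from .proteome_io import LOCALIZATION_VOCABULARY

__all__ = [
    "DistanceConfig",
    "MatchDistanceRecord",
    "DistanceSummary",
    "phospho_distances",
    "aggregate_distances",
    "PositionProbabilityMatrix",
    "build_ppm",
    "ppm_to_meme",
    "LocalizationBreakdown",
    "localization_breakdown",
]

_AA_ORDER = sorted(CANONICAL_AA)


@dataclass(frozen=True)
class DistanceConfig:
    """Distance conventions for phosphosite/motif geometry.

    min_cterm_offset / min_nterm_offset : a phosphosite qualifies only
        at or beyond this separation from the motif edge (defaults 9
        C-terminal, 20 N-terminal).  With ``cutoff_is_minimum=False``
        the same numbers are read as maximum allowed distances instead.
    near_window : radius for the "near" fraction (default 50 residues).
    """

    min_cterm_offset: int = 9
    min_nterm_offset: int = 20
    near_window: int = 50
    cutoff_is_minimum: bool = True

    def __post_init__(self):
        if min(self.min_cterm_offset, self.min_nterm_offset, self.near_window) < 0:
            raise ValueError("distance parameters must be >= 0")

    def qualifies(self, distance: int, orientation: str) -> bool:
        cutoff = self.min_cterm_offset if orientation == "C" else self.min_nterm_offset
        return distance >= cutoff if self.cutoff_is_minimum else distance <= cutoff


@dataclass(frozen=True)
class MatchDistanceRecord:
    """Nearest qualifying phosphosite per orientation for one motif match.

    Distances are anchored at the motif's nearest edge: C-terminal
    distance = site - end, N-terminal distance = start - site.  Sites
    inside the motif are ignored.  ``orientation`` is the side of the
    overall nearest qualifying site (ties resolve C-terminal, the
    majority orientation); None when no site qualifies.
    """

    protein_id: str
    start: int
    end: int
    nearest_cterm: int | None
    nearest_nterm: int | None

    @property
    def orientation(self) -> str | None:
        if self.nearest_cterm is None and self.nearest_nterm is None:
            return None
        if self.nearest_nterm is None:
            return "C"
        if self.nearest_cterm is None:
            return "N"
        return "C" if self.nearest_cterm <= self.nearest_nterm else "N"

    @property
    def nearest_distance(self) -> int | None:
        o = self.orientation
        if o is None:
            return None
        return self.nearest_cterm if o == "C" else self.nearest_nterm


@dataclass(frozen=True)
class DistanceSummary:
    fraction_cterm: float
    fraction_nterm: float
    fraction_within_near_window: float
    mean_first_distance: float
    n_assigned: int


def phospho_distances(match, phospho_positions, config: DistanceConfig | None = None):
    """Locate the nearest qualifying phosphosite on each side of a match."""
    config = config or DistanceConfig()
    cterm, nterm = [], []
    for pos in phospho_positions:
        pos = int(pos)
        if match.start <= pos <= match.end:
            continue  # inside the motif: not reachable geometry, skip
        if pos > match.end:
            d = pos - match.end
            if config.qualifies(d, "C"):
                cterm.append(d)
        else:
            d = match.start - pos
            if config.qualifies(d, "N"):
                nterm.append(d)
    return MatchDistanceRecord(
        protein_id=match.protein_id,
        start=match.start,
        end=match.end,
        nearest_cterm=min(cterm) if cterm else None,
        nearest_nterm=min(nterm) if nterm else None,
    )


def aggregate_distances(records, config: DistanceConfig | None = None) -> DistanceSummary:
    """Pool per-match records into orientation fractions and distances.

    Each match with at least one qualifying site is assigned the
    orientation of its nearest qualifying site; fractions are over
    assigned matches.  Raises if no match has a qualifying site.
    """
    config = config or DistanceConfig()
    assigned = [r for r in records if r.orientation is not None]
    if not assigned:
        raise ValueError("no match has a qualifying phosphosite")
    n = len(assigned)
    n_c = sum(1 for r in assigned if r.orientation == "C")
    dists = np.array([r.nearest_distance for r in assigned], dtype=float)
    return DistanceSummary(
        fraction_cterm=n_c / n,
        fraction_nterm=(n - n_c) / n,
        fraction_within_near_window=float(np.mean(dists <= config.near_window)),
        mean_first_distance=float(dists.mean()),
        n_assigned=n,
    )


# ---------------------------------------------------------------------------
# position probability matrices


@dataclass(frozen=True)
class PositionProbabilityMatrix:
    """Residue probabilities (20 rows x motif length columns) plus IC.

    ``probs`` is a DataFrame indexed by the 20 canonical residues;
    ``information_content`` is log2(20) minus the per-column Shannon
    entropy, in bits.  Raw frequencies, no pseudocounts.
    """

    probs: pd.DataFrame
    instance_count: int

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def information_content(self) -> np.ndarray:
        return np.log2(20.0) - entropy(self.probs.to_numpy(), base=2, axis=0)


def build_ppm(instances) -> PositionProbabilityMatrix:
    """Column-wise residue frequencies of equal-length motif instances."""
    instances = [s.upper() for s in instances]
    if not instances:
        raise ValueError("need at least one motif instance")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("motif instances must all have the same length")
    bad = set("".join(instances)) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues in instances: {sorted(bad)}")
    counts = np.zeros((20, length))
    idx = {aa: i for i, aa in enumerate(_AA_ORDER)}
    for s in instances:
        for j, aa in enumerate(s):
            counts[idx[aa], j] += 1
    probs = pd.DataFrame(counts / len(instances), index=_AA_ORDER, columns=range(1, length + 1))
    return PositionProbabilityMatrix(probs=probs, instance_count=len(instances))


def ppm_to_meme(ppm: PositionProbabilityMatrix, name: str = "motif") -> str:
    """Render a PPM as a MEME minimal-motif format text block."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= " + "".join(_AA_ORDER),
        "",
        "Background letter frequencies",
        " ".join(f"{aa} 0.05000" for aa in _AA_ORDER),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 20 w= {ppm.length} "
        f"nsites= {ppm.instance_count} E= 0",
    ]
    for j in ppm.probs.columns:
        lines.append(" " + " ".join(f"{ppm.probs.at[aa, j]:.6f}" for aa in _AA_ORDER))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# localization


@dataclass(frozen=True)
class LocalizationBreakdown:
    counts: dict
    fractions: dict
    total: int


def localization_breakdown(protein_ids, localization_table) -> LocalizationBreakdown:
    """Category counts and fractions over a protein set; unknowns -> other."""
    ids = sorted(set(protein_ids))
    if not ids:
        raise ValueError("empty protein set")
    counts = {cat: 0 for cat in LOCALIZATION_VOCABULARY}
    for pid in ids:
        counts[localization_table.category_of(pid)] += 1
    total = len(ids)
    fractions = {cat: c / total for cat, c in counts.items()}
    return LocalizationBreakdown(counts=counts, fractions=fractions, total=total)
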
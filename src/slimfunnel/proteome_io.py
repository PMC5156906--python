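"""Readers/writers for the pipeline's file formats and the in-memory proteome.

Sequences travel as FASTA (via Biopython), per-residue disorder scores,
phosphosite annotations, localization labels and match tables as
header-rowed TSV (via pandas), and funnel reports as JSON.  Disorder
scores are consumed, never computed: any predictor that emits one score
in [0, 1] per residue satisfies the contract (the downstream filters
only ever threshold them).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import AMBIGUITY_AA, CANONICAL_AA, MotifMatch

__all__ = [
    "LOCALIZATION_VOCABULARY",
    "ProteinRecord",
    "Proteome",
    "DisorderProfile",
    "PhosphoTable",
    "LocalizationTable",
    "read_fasta",
    "write_fasta",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "read_phospho_tsv",
    "write_phospho_tsv",
    "read_localization_tsv",
    "write_localization_tsv",
    "read_id_list",
    "read_matches_tsv",
    "write_matches_tsv",
]

#: Fixed subcellular localization vocabulary; unlisted labels collapse
#: to ``other`` (optionally through a user-supplied mapping).
LOCALIZATION_VOCABULARY = (
    "nucleus",
    "membrane",
    "intracellular_transport",
    "cytoplasm",
    "mitochondrion",
    "secreted",
    "cytoskeleton",
    "other",
)

_VALID_SEQ = CANONICAL_AA | AMBIGUITY_AA


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_SEQ
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid characters {sorted(bad)} "
                "(gaps and non-amino-acid codes are rejected)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class Proteome:
    """An id-keyed, order-independent collection of protein records."""

    def __init__(self, records):
        self._records = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate protein id {rec.id!r}")
            self._records[rec.id] = rec

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, protein_id):
        return protein_id in self._records

    def __getitem__(self, protein_id) -> ProteinRecord:
        return self._records[protein_id]

    @property
    def ids(self) -> set:
        return set(self._records)

    def subset(self, ids) -> "Proteome":
        return Proteome(self._records[i] for i in ids)


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores for one protein, index-aligned to sequence."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError(f"{self.protein_id!r}: scores must be a non-empty vector")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError(f"{self.protein_id!r}: disorder scores must be in [0, 1]")

    def window(self, start: int, end: int) -> np.ndarray:
        """Scores over 1-based inclusive residue coordinates."""
        if start < 1 or end > self.scores.size or end < start:
            raise ValueError(
                f"{self.protein_id!r}: window [{start}, {end}] outside profile "
                f"of length {self.scores.size}"
            )
        return self.scores[start - 1 : end]


@dataclass
class PhosphoTable:
    """Experimentally observed pSer/pThr sites: (protein_id, 1-based position, S/T)."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["protein_id", "position", "residue"])
    )

    def __post_init__(self):
        df = self.entries
        missing = {"protein_id", "position", "residue"} - set(df.columns)
        if missing:
            raise ValueError(f"phospho table missing columns: {sorted(missing)}")
        bad = df.loc[~df["residue"].isin(["S", "T"])]
        if len(bad):
            raise ValueError(f"phospho residues must be S or T; offenders:\n{bad}")

    def annotated_ids(self) -> set:
        return set(self.entries["protein_id"])

    def positions_for(self, protein_id: str) -> list:
        sel = self.entries.loc[self.entries["protein_id"] == protein_id, "position"]
        return sorted(int(p) for p in sel)

    def validate_against(self, proteome: Proteome) -> None:
        offenders = []
        for row in self.entries.itertuples(index=False):
            if row.protein_id not in proteome:
                offenders.append(f"{row.protein_id}: unknown protein")
                continue
            seq = proteome[row.protein_id].sequence
            pos = int(row.position)
            if not 1 <= pos <= len(seq):
                offenders.append(f"{row.protein_id}:{pos} out of range")
            elif seq[pos - 1] != row.residue:
                offenders.append(
                    f"{row.protein_id}:{pos} states {row.residue}, sequence has {seq[pos - 1]}"
                )
        if offenders:
            raise ValueError("phospho rows disagree with sequences: " + "; ".join(offenders))


@dataclass
class LocalizationTable:
    """One primary subcellular category per protein; unknowns are ``other``."""

    categories: dict = field(default_factory=dict)

    def __post_init__(self):
        for pid, cat in self.categories.items():
            if cat not in LOCALIZATION_VOCABULARY:
                raise ValueError(f"{pid!r}: unknown localization category {cat!r}")

    def category_of(self, protein_id: str) -> str:
        return self.categories.get(protein_id, "other")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Proteome:
    """Load a FASTA file into a Proteome.

    Ids are the first whitespace-delimited header token; bodies are
    uppercased; gap characters raise.  Duplicate ids and empty files
    raise.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "-" in seq or "." in seq:
            raise ValueError(f"protein {rec.id!r}: gap characters are not allowed")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(records)


def write_fasta(proteome: Proteome, path) -> None:
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# disorder


def read_disorder_tsv(path, proteome: Proteome | None = None) -> dict:
    """Load per-residue disorder scores keyed by protein id.

    Expects columns protein_id, position, score with positions contiguous
    from 1 within each protein.  Scores outside [0, 1] and position gaps
    raise; profile lengths are validated against ``proteome`` if given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = {"protein_id", "position", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"disorder table missing columns: {sorted(missing)}")
    profiles = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy(dtype=int)
        expected = np.arange(1, len(positions) + 1)
        if not np.array_equal(positions, expected):
            raise ValueError(f"{pid!r}: positions must be contiguous from 1 (gap detected)")
        profiles[pid] = DisorderProfile(pid, grp["score"].to_numpy(dtype=float))
    if proteome is not None:
        for pid, prof in profiles.items():
            if pid in proteome and prof.scores.size != proteome[pid].length:
                raise ValueError(
                    f"{pid!r}: {prof.scores.size} scores for a "
                    f"{proteome[pid].length}-residue protein"
                )
    return profiles


def write_disorder_tsv(profiles: dict, path) -> None:
    rows = [
        (pid, i + 1, float(s))
        for pid in sorted(profiles)
        for i, s in enumerate(profiles[pid].scores)
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


# ---------------------------------------------------------------------------
# phospho / localization / id lists


def read_phospho_tsv(path, proteome: Proteome | None = None) -> PhosphoTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    table = PhosphoTable(df)
    if proteome is not None:
        table.validate_against(proteome)
    return table


def write_phospho_tsv(table: PhosphoTable, path) -> None:
    table.entries.to_csv(path, sep="\t", index=False)


def read_localization_tsv(path, mapping: dict | None = None) -> LocalizationTable:
    """Load protein -> category labels.

    ``mapping`` optionally rewrites free-text labels into the fixed
    vocabulary before validation; labels that still fall outside it
    raise.  A header-only file yields an empty table (every protein then
    reads back as ``other``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    cats = {}
    for row in df.itertuples(index=False):
        cat = row.category
        if mapping and cat in mapping:
            cat = mapping[cat]
        cats[row.protein_id] = cat
    return LocalizationTable(cats)


def write_localization_tsv(table: LocalizationTable, path) -> None:
    rows = sorted(table.categories.items())
    pd.DataFrame(rows, columns=["protein_id", "category"]).to_csv(path, sep="\t", index=False)


def read_id_list(path) -> list:
    """One protein id per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split()[0])
    return ids


# ---------------------------------------------------------------------------
# match tables


def write_matches_tsv(matches, path) -> None:
    rows = [
        (m.protein_id, m.motif, m.start, m.end, m.sequence, m.dialect or "")
        for m in matches
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "motif", "start", "end", "sequence", "dialect"]
    ).to_csv(path, sep="\t", index=False)


def read_matches_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MotifMatch(
                protein_id=row.protein_id,
                start=int(row.start),
                end=int(row.end),
                sequence=row.sequence,
                motif=row.motif,
                dialect=row.dialect or None,
            )
        )
    return out


def dataclass_to_jsonable(obj):
    """Recursive dataclass/ndarray/set -> plain-JSON conversion helper."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: dataclass_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclass_to_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
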
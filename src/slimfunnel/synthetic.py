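"""Seeded synthetic proteomes with planted motifs and ground truth.

The generator emulates the statistical structure of the real inputs the
funnel consumes — a proteome of sequences, per-residue disorder scores,
curated phosphosites and localization labels — without any of their
biology: background residues are drawn iid (uniform by default, or a
human-proteome-like preset), disorder is a two-level block model, and
phosphosites/localizations follow configured probabilities.  Motif
instances are planted at known coordinates, sampled uniformly from the
requested definition's language, together with the disorder context,
phosphosites and PxIxIT sites that make them pass (or deliberately fail)
each funnel stage.  The emitted truth manifest lets recovery be scored
exactly.

A deliberately defective plant (e.g. ``give_phospho=False``) must be
lost at exactly its designed stage, so plant-hosting proteins receive no
background phosphosites and hosts of ``give_pxixit=False`` plants have
accidental in-IDR PxIxIT occurrences mutated away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .funnel import FunnelReport
from .motifs import MotifDefinition, build_motif_library, scan_pxixit
from .proteome_io import (
    LOCALIZATION_VOCABULARY,
    DisorderProfile,
    LocalizationTable,
    PhosphoTable,
    ProteinRecord,
    Proteome,
    write_disorder_tsv,
    write_fasta,
    write_localization_tsv,
    write_phospho_tsv,
)

__all__ = [
    "GeneratorConfig",
    "PlantRequest",
    "PlantedInstance",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "evaluate_recovery",
    "RecoveryReport",
    "HUMAN_AA_FREQS",
    "sample_from_language",
]

_ALPHABET = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))

#: Approximate human proteome residue composition (fractions renormalized
#: over the 20 canonical residues); used by the realism preset.
HUMAN_AA_FREQS = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}

_CLASS_TO_MOTIF = {
    "canonical": "canonical_pilxvp",
    "expanded": "expanded_pilxvp",
    "structural": "structural_pilxvp",
    "pxixit_short": "pxixit_short",
    "pxixit_long": "pxixit_long",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All the dials of the synthetic proteome.

    Defaults describe a modest curated-proteome-like corpus: 150
    proteins of 300-800 residues, uniform background composition (which
    makes analytic per-window match probabilities exact), about two
    disordered blocks of 30-120 residues per protein scoring in
    [0.5, 1.0] against an ordered baseline in [0.0, 0.3], 90% of
    proteins carrying curated phosphosites, planted phosphosites
    C-terminal of their motif 80% of the time at 9-45 residues (20-45
    N-terminal), and localization drawn with the nucleus as the largest
    class (33%), then membrane (18%) and intracellular transport (13%).
    """

    seed: int
    n_proteins: int = 150
    min_length: int = 300
    max_length: int = 800
    background_frequencies: dict | None = None  # None = uniform over 20
    expected_idr_blocks: float = 2.0
    idr_block_length: tuple = (30, 120)
    idr_score_range: tuple = (0.5, 1.0)
    ordered_score_range: tuple = (0.0, 0.3)
    phospho_presence_prob: float = 0.9
    max_background_phospho: int = 3
    phospho_orientation_cterm_prob: float = 0.8
    cterm_distance_range: tuple = (9, 45)
    nterm_distance_range: tuple = (20, 45)
    localization_probs: dict = field(
        default_factory=lambda: {
            "nucleus": 0.33,
            "membrane": 0.18,
            "intracellular_transport": 0.13,
            "other": 0.36,
        }
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.min_length > self.max_length or self.min_length < 20:
            raise ValueError("invalid length range")
        if not 0 <= self.phospho_presence_prob <= 1:
            raise ValueError("phospho_presence_prob must be in [0, 1]")
        if not 0 <= self.phospho_orientation_cterm_prob <= 1:
            raise ValueError("orientation probability must be in [0, 1]")
        probs = self.localization_probs
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError("localization probabilities must be >= 0 and sum to 1")
        unknown = set(probs) - set(LOCALIZATION_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown localization categories: {sorted(unknown)}")
        if self.background_frequencies is not None:
            f = self.background_frequencies
            if set(f) != set(_ALPHABET.tolist()) or abs(sum(f.values()) - 1) > 1e-6:
                raise ValueError("background frequencies must cover the 20 residues and sum to 1")


@dataclass(frozen=True)
class PlantRequest:
    """How many instances of one motif class to plant, and in what context."""

    motif_class: str
    count: int
    in_idr: bool = True
    give_phospho: bool = True
    give_pxixit: bool = True

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.motif_class not in _CLASS_TO_MOTIF and self.motif_class not in (
            "canonical_pilxvp",
            "expanded_pilxvp",
            "structural_pilxvp",
        ):
            raise ValueError(f"unknown motif class {self.motif_class!r}")

    @property
    def motif_name(self) -> str:
        return _CLASS_TO_MOTIF.get(self.motif_class, self.motif_class)

    @property
    def fully_qualifying(self) -> bool:
        return self.in_idr and self.give_phospho and self.give_pxixit


@dataclass(frozen=True)
class PlantedInstance:
    """Ground truth for one planted motif occurrence.

    ``phospho_offsets`` are signed: +d is a site d residues C-terminal of
    the motif end, -d a site d residues N-terminal of the start.
    """

    protein_id: str
    start: int
    end: int
    hexamer: str
    motif_class: str
    in_idr: bool
    give_phospho: bool
    give_pxixit: bool
    phospho_offsets: tuple = ()
    pxixit_start: int | None = None
    pxixit_sequence: str | None = None

    @property
    def fully_qualifying(self) -> bool:
        return self.in_idr and self.give_phospho and self.give_pxixit


@dataclass
class SyntheticTruth:
    seed: int
    instances: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "instances": [
                {
                    "protein_id": p.protein_id,
                    "start": p.start,
                    "end": p.end,
                    "hexamer": p.hexamer,
                    "motif_class": p.motif_class,
                    "in_idr": p.in_idr,
                    "give_phospho": p.give_phospho,
                    "give_pxixit": p.give_pxixit,
                    "phospho_offsets": list(p.phospho_offsets),
                    "pxixit_start": p.pxixit_start,
                    "pxixit_sequence": p.pxixit_sequence,
                }
                for p in self.instances
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            instances=[
                PlantedInstance(
                    protein_id=p["protein_id"],
                    start=p["start"],
                    end=p["end"],
                    hexamer=p["hexamer"],
                    motif_class=p["motif_class"],
                    in_idr=p["in_idr"],
                    give_phospho=p["give_phospho"],
                    give_pxixit=p["give_pxixit"],
                    phospho_offsets=tuple(p["phospho_offsets"]),
                    pxixit_start=p["pxixit_start"],
                    pxixit_sequence=p["pxixit_sequence"],
                )
                for p in payload["instances"]
            ],
        )


@dataclass
class SyntheticDataset:
    proteome: Proteome
    profiles: dict
    phospho: PhosphoTable
    localization: LocalizationTable
    truth: SyntheticTruth
    config: GeneratorConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, out / "proteome.fasta")
        write_disorder_tsv(self.profiles, out / "disorder.tsv")
        write_phospho_tsv(self.phospho, out / "phospho.tsv")
        write_localization_tsv(self.localization, out / "localization.tsv")
        self.truth.to_json(out / "truth.json")

    def verify_truth(self, disorder_threshold: float = 0.4) -> None:
        """Cross-check every truth entry against the emitted data."""
        lib = build_motif_library()
        phospho_keys = {
            (r.protein_id, int(r.position)) for r in self.phospho.entries.itertuples()
        }
        for inst in self.truth.instances:
            rec = self.proteome[inst.protein_id]
            window = rec.sequence[inst.start - 1 : inst.end]
            assert window == inst.hexamer, inst
            assert lib[_CLASS_TO_MOTIF.get(inst.motif_class, inst.motif_class)].accepts(
                window
            ), inst
            scores = self.profiles[inst.protein_id].window(inst.start, inst.end)
            if inst.in_idr:
                assert np.all(scores >= disorder_threshold), inst
            else:
                assert np.all(scores < disorder_threshold), inst
            for off in inst.phospho_offsets:
                pos = inst.end + off if off > 0 else inst.start + off
                assert (inst.protein_id, pos) in phospho_keys, inst
                assert rec.sequence[pos - 1] in "ST", inst
            if inst.pxixit_start is not None:
                pxi = rec.sequence[inst.pxixit_start - 1 : inst.pxixit_start + 5]
                assert pxi == inst.pxixit_sequence, inst
                assert lib["pxixit_short"].accepts(pxi), inst
                pxi_scores = self.profiles[inst.protein_id].window(
                    inst.pxixit_start, inst.pxixit_start + 5
                )
                assert np.all(pxi_scores >= disorder_threshold), inst


def sample_from_language(motif: MotifDefinition, rng: np.random.Generator) -> str:
    """Draw one string uniformly from a motif's exact match language."""
    out = []
    for pos in motif.positions:
        if pos.wildcard:
            out.append(rng.choice(_ALPHABET))
        else:
            out.append(rng.choice(sorted(pos.allowed)))
    return "".join(out)


class _ProteinDraft:
    """Mutable build state for one protein."""

    def __init__(self, pid, seq_array, scores, rng):
        self.pid = pid
        self.seq = seq_array  # numpy array of single chars
        self.scores = scores
        self.rng = rng
        self.occupied = []  # list of 0-based inclusive (lo, hi)
        self.hosts_plant = False

    def _free(self, lo, hi):
        return all(hi < a or lo > b for a, b in self.occupied)

    def reserve(self, lo, hi):
        self.occupied.append((lo, hi))

    def place_window(self, width, attempts=500):
        L = len(self.seq)
        if L < width:
            raise ValueError(f"{self.pid}: protein too short to host a {width}-mer")
        for _ in range(attempts):
            lo = int(self.rng.integers(0, L - width + 1))
            if self._free(lo, lo + width - 1):
                return lo
        raise ValueError(f"{self.pid}: could not place a {width}-residue plant (too crowded)")


def _uniform_scores(rng, lo_hi, size):
    return rng.uniform(lo_hi[0], lo_hi[1], size=size)


def generate(config: GeneratorConfig, plant_spec=None) -> SyntheticDataset:
    """Build a reproducible synthetic dataset with optional planted motifs.

    Same config (incl. seed) and plant spec => identical output, byte
    for byte once written.  Raises if a plant cannot be hosted.
    """
    rng = np.random.default_rng(config.seed)
    lib = build_motif_library()
    if config.background_frequencies is None:
        bg_p = None
    else:
        bg_p = np.array([config.background_frequencies[a] for a in _ALPHABET])
        bg_p = bg_p / bg_p.sum()

    width = len(str(max(config.n_proteins, 1)))
    drafts = []
    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:0{width}d}"
        L = int(rng.integers(config.min_length, config.max_length + 1))
        seq = rng.choice(_ALPHABET, size=L, p=bg_p)
        scores = _uniform_scores(rng, config.ordered_score_range, L)
        n_blocks = int(rng.poisson(config.expected_idr_blocks))
        placed = []
        for _ in range(n_blocks):
            blen = int(rng.integers(config.idr_block_length[0], config.idr_block_length[1] + 1))
            blen = min(blen, L)
            for _ in range(20):
                s = int(rng.integers(0, L - blen + 1))
                if all(s + blen <= a or s >= a + bl for a, bl in placed):
                    placed.append((s, blen))
                    scores[s : s + blen] = _uniform_scores(rng, config.idr_score_range, blen)
                    break
        drafts.append(_ProteinDraft(pid, seq, scores, rng))

    truth = SyntheticTruth(seed=config.seed)
    phospho_rows = []

    requests = []
    for req in plant_spec or []:
        requests.extend([req] * req.count)
    if len(requests) > config.n_proteins:
        raise ValueError(
            f"{len(requests)} plants requested but only {config.n_proteins} proteins "
            "(one plant host per protein)"
        )
    host_order = rng.permutation(config.n_proteins)[: len(requests)]

    for req, host_idx in zip(requests, host_order):
        draft = drafts[host_idx]
        draft.hosts_plant = True
        motif = lib[req.motif_name]
        w = motif.length
        hexamer = sample_from_language(motif, rng)
        lo = draft.place_window(w)
        draft.seq[lo : lo + w] = list(hexamer)
        band = config.idr_score_range if req.in_idr else config.ordered_score_range
        draft.scores[lo : lo + w] = _uniform_scores(rng, band, w)
        draft.reserve(lo, lo + w - 1)
        start, end = lo + 1, lo + w

        pxixit_start = pxixit_seq = None
        if req.give_pxixit:
            pxi = sample_from_language(lib["pxixit_short"], rng)
            plo = draft.place_window(6)
            draft.seq[plo : plo + 6] = list(pxi)
            draft.scores[plo : plo + 6] = _uniform_scores(rng, config.idr_score_range, 6)
            draft.reserve(plo, plo + 5)
            pxixit_start, pxixit_seq = plo + 1, pxi

        offsets = []
        if req.give_phospho:
            L = len(draft.seq)
            placed_site = False
            towards_c = bool(rng.random() < config.phospho_orientation_cterm_prob)
            for attempt in range(200):
                side_c = towards_c if attempt < 100 else not towards_c
                d_lo, d_hi = (
                    config.cterm_distance_range if side_c else config.nterm_distance_range
                )
                d = int(rng.integers(d_lo, d_hi + 1))
                pos = end + d if side_c else start - d  # 1-based
                if not 1 <= pos <= L:
                    continue
                if not draft._free(pos - 1, pos - 1):
                    continue
                draft.seq[pos - 1] = rng.choice(np.array(["S", "T"]))
                draft.reserve(pos - 1, pos - 1)
                offsets.append(d if side_c else -d)
                phospho_rows.append((draft.pid, pos, str(draft.seq[pos - 1])))
                placed_site = True
                break
            if not placed_site:
                raise ValueError(f"{draft.pid}: could not place a phosphosite for the plant")

        truth.instances.append(
            PlantedInstance(
                protein_id=draft.pid,
                start=start,
                end=end,
                hexamer=hexamer,
                motif_class=req.motif_class,
                in_idr=req.in_idr,
                give_phospho=req.give_phospho,
                give_pxixit=req.give_pxixit,
                phospho_offsets=tuple(offsets),
                pxixit_start=pxixit_start,
                pxixit_sequence=pxixit_seq,
            )
        )

    # hosts of pxixit-free plants must not carry accidental in-IDR PxIxIT
    no_pxixit_pids = {
        inst.protein_id for inst in truth.instances if not inst.give_pxixit
    }
    for draft in drafts:
        if draft.pid not in no_pxixit_pids:
            continue
        _scrub_pxixit(draft, config)

    # background phosphosites on plant-free proteins only
    for draft in drafts:
        if draft.hosts_plant:
            continue
        if rng.random() < config.phospho_presence_prob:
            k = int(rng.integers(1, config.max_background_phospho + 1))
            L = len(draft.seq)
            for _ in range(k):
                for _ in range(50):
                    pos0 = int(rng.integers(0, L))
                    if draft._free(pos0, pos0):
                        draft.seq[pos0] = rng.choice(np.array(["S", "T"]))
                        draft.reserve(pos0, pos0)
                        phospho_rows.append((draft.pid, pos0 + 1, str(draft.seq[pos0])))
                        break

    cats = sorted(config.localization_probs)
    cat_p = np.array([config.localization_probs[c] for c in cats])
    loc = {
        draft.pid: str(rng.choice(np.array(cats), p=cat_p)) for draft in drafts
    }

    proteome = Proteome(
        ProteinRecord(d.pid, "".join(d.seq.tolist())) for d in drafts
    )
    profiles = {
        d.pid: DisorderProfile(d.pid, np.clip(d.scores, 0.0, 1.0)) for d in drafts
    }
    phospho_rows.sort()
    phospho = PhosphoTable(
        pd.DataFrame(phospho_rows, columns=["protein_id", "position", "residue"])
    )
    dataset = SyntheticDataset(
        proteome=proteome,
        profiles=profiles,
        phospho=phospho,
        localization=LocalizationTable(loc),
        truth=truth,
        config=config,
    )
    dataset.verify_truth()
    return dataset


def _scrub_pxixit(draft, config: GeneratorConfig) -> None:
    """Mutate away accidental in-IDR PxIxIT occurrences in one protein.

    A constrained position (the anchor Pro by preference) of each
    offending occurrence is rewritten to Gly, which satisfies no
    constrained position of any motif here, so the rewrite cannot create
    new occurrences; reserved (planted) residues are never touched.
    """
    for _ in range(10):
        seq = "".join(draft.seq.tolist())
        profile = DisorderProfile(draft.pid, np.clip(draft.scores, 0.0, 1.0))
        hits = scan_pxixit(seq, ("short", "long"))
        # any residue >= 0.4 could pass some aggregation; scrub all hits
        offenders = [h for h in hits if np.any(profile.window(h.start, h.end) >= 0.4)]
        if not offenders:
            return
        progress = False
        for h in offenders:
            # constrained positions of the dialect: anchor P, [IV], [TDH]
            constrained = [h.start - 1, h.end - 2, h.end - 1]
            for pos0 in constrained:
                if draft._free(pos0, pos0):
                    draft.seq[pos0] = "G"
                    progress = True
                    break
        if not progress:
            break
    raise RuntimeError(f"{draft.pid}: failed to scrub accidental PxIxIT sites")


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryReport:
    recall: float
    precision: float
    stage_losses: dict  # stage name -> list of lost PlantedInstance
    n_fully_qualifying: int
    n_recovered: int


def evaluate_recovery(report: FunnelReport, truth: SyntheticTruth) -> RecoveryReport:
    """Score a funnel run against the generator's truth manifest.

    Recall is over fully-qualifying plants (in IDR, with phospho and
    PxIxIT); precision counts final-stage matches at non-planted
    coordinates as false positives.  Each lost plant is attributed to
    the first stage that dropped it.
    """
    missing = {p.protein_id for p in truth.instances} - set(report.input_protein_ids)
    if missing:
        raise ValueError(
            f"truth/report dataset mismatch: proteins {sorted(missing)} not in the run"
        )

    def keyset(stage):
        return {(m.protein_id, m.start, m.end) for m in report.stage(stage).matches}

    raw_keys = keyset("raw_scan")
    idr_keys = keyset("idr_filter")
    final_keys = keyset("intersection")
    pho_ids = report.stage("phospho_filter").protein_ids
    pxi_ids = report.stage("pxixit_filter").protein_ids

    losses = {"raw_scan": [], "idr_filter": [], "phospho_filter": [], "pxixit_filter": []}
    fully = [p for p in truth.instances if p.fully_qualifying]
    recovered = 0
    for inst in truth.instances:
        key = (inst.protein_id, inst.start, inst.end)
        if key in final_keys:
            if inst.fully_qualifying:
                recovered += 1
            continue
        if key not in raw_keys:
            losses["raw_scan"].append(inst)
        elif key not in idr_keys:
            losses["idr_filter"].append(inst)
        elif inst.protein_id not in pho_ids:
            losses["phospho_filter"].append(inst)
        else:
            assert inst.protein_id not in pxi_ids
            losses["pxixit_filter"].append(inst)

    if not fully:
        raise ValueError("no fully-qualifying plants in truth; recall undefined")
    truth_keys = {(p.protein_id, p.start, p.end) for p in truth.instances}
    n_final = len(final_keys)
    tp = len(final_keys & truth_keys)
    precision = tp / n_final if n_final else 0.0
    return RecoveryReport(
        recall=recovered / len(fully),
        precision=precision,
        stage_losses=losses,
        n_fully_qualifying=len(fully),
        n_recovered=recovered,
    )
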
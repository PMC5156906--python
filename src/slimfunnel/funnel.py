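"""The staged substrate-discovery filter cascade.

Starting from a raw position-class motif scan over a proteome, three
filters narrow the candidate list:

1. intrinsic disorder — the motif window must lie in a disordered
   region (score >= 0.4 by default; short linear motifs function in
   disordered sequence);
2. phosphosite evidence — the protein must carry at least one
   experimentally observed pSer/pThr anywhere (a phosphatase substrate
   must be phosphorylated);
3. PxIxIT co-occurrence — the protein must also carry the second
   docking motif, itself in a disordered region, because avid
   two-motif engagement is the hallmark of committed substrates.

Filters 2 and 3 branch in parallel from the disorder stage and are then
intersected, so the report can also expose the informative complements
(PxIxIT-only proteins are plausible regulators rather than substrates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .motifs import MotifMatch, build_motif_library, scan, scan_pxixit
from .proteome_io import Proteome, dataclass_to_jsonable

__all__ = [
    "FunnelConfig",
    "FunnelStage",
    "FunnelReport",
    "idr_filter",
    "phospho_filter",
    "pxixit_cooccurrence",
    "run_funnel",
    "validate_conserved",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = 1

_AGGREGATIONS = ("mean", "all", "any")


@dataclass(frozen=True)
class FunnelConfig:
    """Tunable knobs of the cascade.

    disorder_threshold : score at/above which a residue counts as
        disordered (default 0.4).
    disorder_aggregation : how window scores are reduced before
        thresholding — "mean" (default; robust to single-residue dips),
        "all" (every residue disordered) or "any" (at least one).
    pxixit_dialects : which PxIxIT spacer dialects to scan.
    require_pxixit_in_idr : whether the co-occurring PxIxIT must itself
        pass the disorder criterion (default True).
    motif_name : the LxVP-family definition driving the primary scan.
    """

    disorder_threshold: float = 0.4
    disorder_aggregation: str = "mean"
    pxixit_dialects: tuple = ("short", "long")
    require_pxixit_in_idr: bool = True
    motif_name: str = "expanded_pilxvp"

    def __post_init__(self):
        if not 0.0 <= self.disorder_threshold <= 1.0:
            raise ValueError("disorder_threshold must be in [0, 1]")
        if self.disorder_aggregation not in _AGGREGATIONS:
            raise ValueError(f"disorder_aggregation must be one of {_AGGREGATIONS}")
        if not self.pxixit_dialects:
            raise ValueError("pxixit_dialects must be non-empty")
        object.__setattr__(self, "pxixit_dialects", tuple(self.pxixit_dialects))


@dataclass
class FunnelStage:
    name: str
    matches: list
    protein_ids: set

    @property
    def motif_count(self) -> int:
        return len(self.matches)

    @property
    def protein_count(self) -> int:
        return len(self.protein_ids)


@dataclass
class FunnelReport:
    """Stage-by-stage counts, surviving sets, and set-algebra cross-tabs."""

    stages: list
    both_count: int
    pxixit_only_count: int
    phospho_only_count: int
    neither_count: int
    multi_motif_protein_count: int
    input_protein_ids: set = field(default_factory=set)
    config: FunnelConfig | None = None

    def stage(self, name: str) -> FunnelStage:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(name)

    def validate(self) -> None:
        """Assert the report's internal set algebra.

        Nested stage protein sets along the linear spine
        (raw >= idr >= {phospho, pxixit} >= intersection), motif_count >=
        protein_count everywhere, and the complement identities
        both + pxixit_only = pxixit total (and symmetrically for phospho).
        """
        raw, idr = self.stage("raw_scan"), self.stage("idr_filter")
        pho, pxi = self.stage("phospho_filter"), self.stage("pxixit_filter")
        inter = self.stage("intersection")
        assert idr.protein_ids <= raw.protein_ids
        assert pho.protein_ids <= idr.protein_ids
        assert pxi.protein_ids <= idr.protein_ids
        assert inter.protein_ids == pho.protein_ids & pxi.protein_ids
        for st in self.stages:
            assert st.motif_count >= st.protein_count, st.name
            assert {m.protein_id for m in st.matches} == st.protein_ids, st.name
        assert self.both_count + self.pxixit_only_count == pxi.protein_count
        assert self.both_count + self.phospho_only_count == pho.protein_count
        assert (
            self.both_count
            + self.pxixit_only_count
            + self.phospho_only_count
            + self.neither_count
            == idr.protein_count
        )


def _window_passes(scores: np.ndarray, config: FunnelConfig) -> bool:
    t = config.disorder_threshold
    if config.disorder_aggregation == "mean":
        return float(np.mean(scores)) >= t
    if config.disorder_aggregation == "all":
        return bool(np.all(scores >= t))
    return bool(np.any(scores >= t))


def idr_filter(matches, profiles: dict, config: FunnelConfig | None = None) -> list:
    """Keep matches whose window disorder passes the configured criterion.

    The scores over the match's 1-based inclusive window are aggregated
    (mean/all/any) and compared against the threshold.  A match whose
    protein has no profile raises, naming the protein.
    """
    config = config or FunnelConfig()
    out = []
    for m in matches:
        if m.protein_id not in profiles:
            raise ValueError(f"no disorder profile for protein {m.protein_id!r}")
        if _window_passes(profiles[m.protein_id].window(m.start, m.end), config):
            out.append(m)
    return out


def phospho_filter(protein_ids, phospho_table) -> set:
    """Keep proteins with >= 1 observed pSer/pThr anywhere in the sequence."""
    return set(protein_ids) & phospho_table.annotated_ids()


def pxixit_cooccurrence(
    protein_ids, proteome: Proteome, profiles: dict, config: FunnelConfig | None = None
) -> set:
    """Keep proteins that also carry a PxIxIT site (in an IDR if required)."""
    config = config or FunnelConfig()
    out = set()
    for pid in protein_ids:
        hits = scan_pxixit(proteome[pid].sequence, config.pxixit_dialects)
        hits = [
            MotifMatch(pid, h.start, h.end, h.sequence, h.motif, h.dialect) for h in hits
        ]
        if config.require_pxixit_in_idr:
            hits = idr_filter(hits, profiles, config)
        if hits:
            out.add(pid)
    return out


def run_funnel(
    proteome: Proteome,
    profiles: dict,
    phospho_table,
    config: FunnelConfig | None = None,
) -> FunnelReport:
    """Run the full cascade and return the populated report.

    Stage order: raw scan -> disorder filter -> (phospho filter and
    PxIxIT filter, both applied to the disorder-stage protein set in
    parallel) -> intersection.  Matches carried into the protein-level
    stages are the disorder-stage matches of the surviving proteins.
    """
    config = config or FunnelConfig()
    motif = build_motif_library()[config.motif_name]

    raw = []
    for rec in proteome:
        for m in scan(rec.sequence, motif):
            raw.append(MotifMatch(rec.id, m.start, m.end, m.sequence, m.motif))
    raw.sort(key=lambda m: (m.protein_id, m.start))
    stages = [FunnelStage("raw_scan", raw, {m.protein_id for m in raw})]

    idr = idr_filter(raw, profiles, config)
    idr_ids = {m.protein_id for m in idr}
    stages.append(FunnelStage("idr_filter", idr, idr_ids))

    pho_ids = phospho_filter(idr_ids, phospho_table)
    stages.append(
        FunnelStage("phospho_filter", [m for m in idr if m.protein_id in pho_ids], pho_ids)
    )

    pxi_ids = pxixit_cooccurrence(idr_ids, proteome, profiles, config)
    stages.append(
        FunnelStage("pxixit_filter", [m for m in idr if m.protein_id in pxi_ids], pxi_ids)
    )

    both = pho_ids & pxi_ids
    stages.append(
        FunnelStage("intersection", [m for m in idr if m.protein_id in both], both)
    )

    per_protein = {}
    for m in idr:
        per_protein[m.protein_id] = per_protein.get(m.protein_id, 0) + 1

    report = FunnelReport(
        stages=stages,
        both_count=len(both),
        pxixit_only_count=len(pxi_ids - pho_ids),
        phospho_only_count=len(pho_ids - pxi_ids),
        neither_count=len(idr_ids - pho_ids - pxi_ids),
        multi_motif_protein_count=sum(1 for c in per_protein.values() if c >= 2),
        input_protein_ids=proteome.ids,
        config=config,
    )
    report.validate()
    return report


def validate_conserved(interactors: Proteome, motif_name: str) -> tuple:
    """Raw motif search over a confirmed-interactor set.

    Deliberately skips the disorder/phospho/PxIxIT filters: the question
    is simply which experimentally confirmed binding partners contain a
    sequence compatible with the named definition.  Returns
    ``(hit_count, per_protein_matches)`` where hit_count is the number of
    proteins with >= 1 match and the per-protein match lists feed logo
    building.
    """
    if len(interactors) == 0:
        raise ValueError("interactor set is empty")
    motif = build_motif_library()[motif_name]
    per_protein = {}
    for rec in interactors:
        hits = [
            MotifMatch(rec.id, m.start, m.end, m.sequence, m.motif)
            for m in scan(rec.sequence, motif)
        ]
        per_protein[rec.id] = hits
    hit_count = sum(1 for hits in per_protein.values() if hits)
    return hit_count, per_protein


# ---------------------------------------------------------------------------
# report (de)serialization


def write_report(report: FunnelReport, path, provenance: dict | None = None) -> None:
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "stages": [
            {
                "name": st.name,
                "motif_count": st.motif_count,
                "protein_count": st.protein_count,
                "protein_ids": sorted(st.protein_ids),
                "matches": [dataclass_to_jsonable(m) for m in st.matches],
            }
            for st in report.stages
        ],
        "both_count": report.both_count,
        "pxixit_only_count": report.pxixit_only_count,
        "phospho_only_count": report.phospho_only_count,
        "neither_count": report.neither_count,
        "multi_motif_protein_count": report.multi_motif_protein_count,
        "input_protein_ids": sorted(report.input_protein_ids),
        "config": dataclass_to_jsonable(report.config) if report.config else None,
    }
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> FunnelReport:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema: {payload.get('schema_version')}")
    stages = [
        FunnelStage(
            name=st["name"],
            matches=[MotifMatch(**m) for m in st["matches"]],
            protein_ids=set(st["protein_ids"]),
        )
        for st in payload["stages"]
    ]
    cfg = FunnelConfig(**payload["config"]) if payload.get("config") else None
    report = FunnelReport(
        stages=stages,
        both_count=payload["both_count"],
        pxixit_only_count=payload["pxixit_only_count"],
        phospho_only_count=payload["phospho_only_count"],
        neither_count=payload["neither_count"],
        multi_motif_protein_count=payload["multi_motif_protein_count"],
        input_protein_ids=set(payload["input_protein_ids"]),
        config=cfg,
    )
    report.validate()
    return report
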
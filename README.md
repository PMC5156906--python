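# slimfunnel

A structure-informed discovery funnel for short linear motifs (SLiMs)
that dock substrates onto the serine/threonine phosphatase calcineurin.
It is written for computational biologists who want to scan a proteome
for candidate phosphatase substrates and for methods developers who need
a benchmarked, ground-truthed pipeline to evaluate SLiM filtering
strategies on.

## The problem and the method

Calcineurin recognizes its substrates not through a phosphosite
consensus but through two short docking motifs in disordered sequence:
the LxVP motif and the PxIxIT motif. Structural work on the
calcineurin–NFATc1 complex sharpened the LxVP element into a
six-position pattern, and `slimfunnel` implements the resulting family
of exact position-class (PROSITE-style) definitions:

| name | pattern | description |
|---|---|---|
| `core_lxvp` | `L-x-V-P` | the four-residue core |
| `canonical_pilxvp` | `[NQDESRTH]-[YTDFILV]-L-x-V-P` | polar donor/acceptor at −2 (π), confirmed-site residues at −1 (ɸ) |
| `expanded_pilxvp` | `[NQDESRTH]-[YTDFILV]-L-x-[VPL]-[PK]` | Val pocket relaxed to V/P/L, Pro pocket to P/K |
| `structural_pilxvp` | `[NQDESRTH]-[YTDFILV]-L-x-[VPLIH]-x` | everything the rigid binding pockets accommodate |
| `pxixit_short` | `P-x-x-x-[IV]-[TDH]` | PVIVIT-like dialect |
| `pxixit_long` | `P-x-x-x-x-[IV]-[TDH]` | AKAP79-like dialect with an extended spacer |

The three six-residue LxVP definitions form a strict containment chain
(canonical ⊂ expanded ⊂ structural), so every hexamer falls into exactly
one of the classes `canonical`, `expanded_only`, `structural_only`, or
`no_match`.

Raw pattern hits are then pushed through a filter cascade:

1. **disorder** — the motif window must lie in an intrinsically
   disordered region (per-residue disorder score ≥ 0.4; functional SLiMs
   live in disordered sequence);
2. **phosphosite evidence** — the protein must carry ≥ 1 experimentally
   observed pSer/pThr;
3. **PxIxIT co-occurrence** — the protein must also contain the second
   docking motif, itself in a disordered region.

Filters 2 and 3 branch in parallel from the disorder stage and are
intersected; proteins passing only the PxIxIT branch are plausible
regulators rather than substrates, and the report keeps all the
complements. Downstream summaries measure the distance and orientation
of the nearest qualifying phosphosite (≥ 9 residues C-terminal or ≥ 20
N-terminal of the motif edge — the separations that let a docked
disordered segment reach the active site), build the position
probability matrix/logo of the surviving instances, and break the
candidate set down by subcellular localization.

Because real proteome-scale inputs (sequence database, disorder
predictor and phosphosite annotation releases) drift over time, the
package ships a seeded synthetic-proteome generator that emulates their
statistical structure — iid background sequence, block-structured
disorder, phosphosites at controlled distances and orientations,
localization labels — and plants motif instances with a machine-checked
truth manifest, so recovery through the funnel can be scored exactly.

## Worked example

```python
from slimfunnel import FunnelConfig, evaluate_recovery, run_funnel
from slimfunnel.synthetic import GeneratorConfig, PlantRequest, generate

spec = [
    PlantRequest("canonical", 5),
    PlantRequest("expanded", 5),
    PlantRequest("canonical", 3, in_idr=False),        # fails filter 1
    PlantRequest("canonical", 3, give_phospho=False),  # fails filter 2
    PlantRequest("expanded", 3, give_pxixit=False),    # fails filter 3
]
dataset = generate(GeneratorConfig(seed=11, n_proteins=40), spec)
report = run_funnel(dataset.proteome, dataset.profiles, dataset.phospho, FunnelConfig())
for stage in report.stages:
    print(stage.name, stage.motif_count, stage.protein_count)
print(evaluate_recovery(report, dataset.truth).recall)
```

prints

```
raw_scan 22 21
idr_filter 16 16
phospho_filter 13 13
pxixit_filter 13 13
intersection 10 10
1.0
```

The raw scan finds 22 motif occurrences in 21 proteins (the 19 planted
ones plus background chance hits); the disorder filter removes the three
plants placed in ordered sequence plus the background hits, the two
protein-level filters each remove their three designed defectors, and
all 10 fully-qualifying plants survive to the intersection — recall 1.0,
with every loss attributed to the filter designed to cause it.

The same flow is available from the shell:

```bash
slimfunnel simulate --seed 17 --out sim/
slimfunnel funnel --fasta sim/proteome.fasta --disorder sim/disorder.tsv \
    --phospho sim/phospho.tsv --report report.json --matches matches.tsv
slimfunnel distances --matches matches.tsv --phospho sim/phospho.tsv
slimfunnel logo --matches matches.tsv
```

See `examples/` for narrative scripts covering scanning/classification,
the funnel with recovery scoring, phosphosite geometry and logo
matrices, and conserved-interactor searches.

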
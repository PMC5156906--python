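# Methods

## Motif model

All motifs are exact position-class patterns: an ordered list of
allowed-residue sets, with `x` a wildcard over the 20 canonical amino
acids. Matching is binary set membership per position — no
position-weight scoring, no affinity prediction — because the
discovery procedure this package implements is an exact
ScanProsite-style search. Coordinates are 1-based inclusive throughout,
matching the superscript convention used for protein sites in the
literature (QYLAVP at 384–390 of NFATc1). Sequences are uppercased
before matching; overlapping occurrences are all reported (no
leftmost-longest consumption). Ambiguity codes (X, B, Z, U, O) fail
every constrained position and satisfy wildcards, so a match is never
claimed on unknown residues.

The scanner compiles each pattern to a regular expression inside a
lookahead (for overlap) — the test suite checks it against an
independent brute-force per-window oracle rather than trusting the
translation.

The LxVP family is stored as three nested six-residue definitions. The
−2 position admits the polar hydrogen-bond donor/acceptor residues
N, Q, D, E, S, R, T, H; the −1 position the residues observed in
experimentally confirmed sites (Y, T, D, F, I, L, V — the printed
bracket set is followed even where prose shorthand calls the class
"hydrophobic"). The canonical tail is V-P; the expanded tail [VPL]-[PK]
reflects the residues favored in confirmed-interactor alignments; the
structural tail [VPLIH]-x is everything the rigid Val/Pro binding
pockets accommodate. Because each class's sets contain the previous
class's ({V} ⊂ {V,P,L} ⊂ {V,P,L,I,H}; {P} ⊂ {P,K} ⊂ any), the match
languages are strictly nested, and hexamer classification uses the
precedence canonical > expanded_only > structural_only > no_match;
ties are impossible. Under an iid uniform background the per-window
match probabilities are exact products of class sizes over 20⁶:
1120/20⁶ ≈ 1.75×10⁻⁵ (canonical), 6720/20⁶ ≈ 1.05×10⁻⁴ (expanded),
112000/20⁶ = 1.75×10⁻³ (structural); these are the calibration targets
for the generator.

Two PxIxIT dialects are provided — `P-x-x-x-[IV]-[TDH]` (PVIVIT-like)
and `P-x-x-x-x-[IV]-[TDH]` (AKAP79-like, one extra spacer residue) —
and scanned as a labeled union.

## Filter cascade

Disorder scores are consumed through an input contract (one score in
[0, 1] per residue, from any predictor or from the generator), never
computed: the pipeline only ever thresholds them, so re-implementing a
disorder predictor would change no downstream logic and would pin the
package to one predictor build.

A motif window passes the disorder filter when the aggregation of its
per-residue scores meets the threshold (default 0.4). The default
aggregation is the window **mean**, which is robust to single-residue
dips; `all` and `any` are provided because "the motif is in a
disordered region" genuinely admits both readings, and the choice is
config-exposed rather than silently fixed.

The phosphosite filter keeps proteins with at least one observed
pSer/pThr anywhere in the sequence (substrate evidence is a
protein-level property). The PxIxIT filter keeps proteins whose
sequence contains at least one selected-dialect site passing the same
disorder criterion; `require_pxixit_in_idr=False` bypasses the
disorder requirement for this filter only. Both branch in parallel
from the disorder stage and are intersected, so the report can expose
the complements (phospho-only, PxIxIT-only — candidate regulators —
and neither). Per-motif provenance is retained, so motif and protein
counts can differ at every stage, and the report validates its own set
algebra (nesting, motif ≥ protein counts, both + only = branch totals)
on construction.

The conserved-interactor search (`validate_conserved`) deliberately
omits all three filters: for experimentally confirmed binding partners
the question is raw sequence compatibility with a definition, and its
per-protein match lists feed logo building.

## Phosphosite geometry

Distances are anchored at the motif's nearest edge: C-terminal distance
= site − motif end, N-terminal distance = motif start − site; sites
inside the motif are ignored. The default cutoffs (9 residues
C-terminal, 20 N-terminal) are read as **minimum** separations — the
slack a docked disordered segment needs to reach across the ~30 Å gap
to the active site; since the wording "cutoff" also admits a
maximum-distance reading, `cutoff_is_minimum=False` flips the
interpretation behind one flag. Each match is assigned the orientation
of its nearest qualifying site ("first" is read as nearest in
sequence, flagged in the config rather than hard-coded); equidistant
ties resolve C-terminal, the majority orientation, deterministically.
Aggregates report orientation fractions, the fraction within a
50-residue near-window, and the mean nearest distance.

## Position probability matrices

Probabilities are raw per-column frequencies over the aligned
instances — no pseudocounts or small-sample correction, matching how
logos of curated instance sets are drawn. Information content per
column is log₂ 20 − H(column) bits, in [0, log₂ 20]. Export formats:
MEME minimal motif text and TSV.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs —
not their biology. Defaults, chosen once as a realistic desk-scale
corpus:

| parameter | default | rationale |
|---|---|---|
| proteins × length | 150 × U(300, 800) | typical curated-proteome protein lengths at a size every test can afford |
| background composition | uniform over 20 | makes the analytic window probabilities exact; a human-like frequency preset (`HUMAN_AA_FREQS`) is included for realism checks |
| disorder | ~Poisson(2) blocks/protein of 30–120 residues scoring U(0.5, 1.0) over an ordered baseline U(0.0, 0.3) | a two-level block model; the pipeline only reads thresholded windows, so block structure is the minimal sufficient statistic, and the score bands keep every window unambiguously above or below the 0.4 threshold under any aggregation |
| phosphosites | 90% of proteins carry 1–3 background sites; planted sites are C-terminal with probability 0.8 at 9–45 residues, N-terminal at 20–45 | mirrors the reported ~80/20 orientation preference and keeps planted sites within the qualifying and near-window ranges |
| localization | nucleus 0.33, membrane 0.18, intracellular transport 0.13, other 0.36 | the reported candidate-set distribution |

Planted instances are sampled uniformly from the requested definition's
exact match language and written into free (non-overlapping) sequence;
their windows receive disorder scores wholly inside the disordered or
ordered band per the `in_idr` flag, so the flag is unambiguous under
any aggregation mode. Plants requesting a PxIxIT receive a
short-dialect site in a disordered window; plants requesting a
phosphosite receive one S/T at a drawn orientation and distance. Two
interventions keep deliberately defective plants diagnostic:
plant-hosting proteins get no background phosphosites, and hosts of
`give_pxixit=False` plants have accidental in-IDR PxIxIT occurrences
mutated away (a constrained position is rewritten to Gly, which
satisfies no constrained class here, so the rewrite cannot create new
occurrences). Each generated dataset re-verifies its own truth manifest
against the emitted sequences, scores and tables before it is returned.
Generation is fully driven by one seeded NumPy generator; the same seed
yields byte-identical files.

What the generator does **not** model: residue autocorrelation of real
disorder scores, annotation bias in curated phosphosite/localization
data, homology between proteins, and compositional biases of real
disordered regions. Passing recovery tests therefore demonstrates the
correctness of the filtering logic and the calibration of the
statistical machinery — not performance on a real proteome, where hit
counts depend on the sequence database and predictor releases used.

## Recovery scoring

Recall is over fully-qualifying plants (in an IDR, with a phosphosite
and an in-IDR PxIxIT): each must appear among the intersection-stage
matches at its planted coordinates. Precision counts final-stage
matches at non-planted coordinates as false positives. Every lost
plant is attributed to the first stage that dropped it (raw scan,
disorder, phosphosite, PxIxIT). A truth manifest with no
fully-qualifying plants makes recall undefined and raises; a manifest
whose proteins are absent from the report is rejected as a dataset
mismatch.

## Problem sizes

The shipped tests and the acceptance script use desk-scale corpora
chosen for statistical resolution: ~1.5M windows (300 × 5000 residues)
for background-rate calibration (≥ 4-binomial-SD resolution on all
three rates), 400 planted sites for the orientation split
(4 SD ≈ 0.08), 10⁵ random hexamers for containment, and 200 random
sequences for scanner/oracle equivalence. The full suite runs in a few
seconds.

## Known limitations

- Exact class matching cannot rank candidates; two matches are equally
  "good". Affinity differences between sites are real but out of scope.
- The disorder filter inherits whatever biases the upstream predictor
  has; the 0.4 threshold is a convention, not a fitted value.
- Proteome-scale candidate counts from the literature are not
  reproduction targets: they depend on specific database and predictor
  releases.
- The CLI reads whole proteomes into memory; it is sized for proteome
  files in the tens of megabytes, not metagenomes.
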
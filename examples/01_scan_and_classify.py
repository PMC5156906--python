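"""Scan a peptide for docking motifs and classify candidate hexamers.

Builds the motif library, scans the NFATc1 LxVP-bearing decamer for the
canonical six-residue definition, and classifies a few experimentally
reported interactor hexamers into the nested motif classes.
"""

from slimfunnel import build_motif_library, classify_hexamer, scan, scan_pxixit

library = build_motif_library()
for name, motif in library.items():
    print(f"{name:20s} {motif.to_prosite()}")

# The NFATc1 docking segment: QYLAVP sits at residues 3-8 of this decamer
# (384-390 in the full-length protein).
peptide = "DDQYLAVPQH"
for match in scan(peptide, library["canonical_pilxvp"]):
    print(f"\ncanonical match in {peptide!r}: {match.sequence} at [{match.start}, {match.end}]")

# Nested classes: canonical sites have the strict V-P tail, expanded-only
# sites relax it to [VPL]-[PK], e.g. the KCNK18 site with Leu in the Val
# pocket; hexamers outside all three languages are no_match.
for hexamer in ("QYLAVP", "SFLKVP", "NTLQLP", "NFLCVK", "AAAAAA"):
    print(f"{hexamer} -> {classify_hexamer(hexamer)}")

# The second docking motif: PxIxIT dialects with 3- or 4-residue spacers.
for m in scan_pxixit("ESPRIEITS", {"short", "long"}):
    print(f"\nPxIxIT ({m.dialect}): {m.sequence} at [{m.start}, {m.end}]")
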
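import numpy as np
import pytest

from slimfunnel.synthetic import GeneratorConfig, PlantRequest, generate

# Experimentally reported calcineurin-interactor hexamers and the motif
# class each satisfies: `canonical` sites fit [NQDESRTH]-[YTDFILV]-L-x-V-P,
# `expanded_only` sites need the relaxed [VPL]-[PK] tail.  These are the
# curated worked examples the classifier must reproduce exactly.
CURATED_HEXAMERS = {
    # canonical pi-phi-L-x-V-P sites
    "QYLAVP": "canonical",  # NFATc1
    "SFLKVP": "canonical",  # CRYBG3
    "NILDVP": "canonical",  # MAP3K7/TAK1
    "SYLSVP": "canonical",  # MAP3K10
    "SYLGVP": "canonical",  # HERC2
    "SVLAVP": "canonical",  # MSL1
    "DLLSVP": "canonical",  # SIX4
    "NTLGVP": "canonical",  # MED1
    "RVLSVP": "canonical",  # SYDE2
    "RFLKVP": "canonical",  # KLRG2
    "TDLTVP": "canonical",  # MEF2A
    # expanded-only pi-phi-L-x-[VPL]-[PK] sites
    "QLLTVK": "expanded_only",  # AKAP12
    "RDLQPP": "expanded_only",  # MAP3K11
    "NYLDLK": "expanded_only",  # MAP3K19
    "SVLIPP": "expanded_only",  # PALB2
    "DYLRLK": "expanded_only",  # BRCA2
    "QVLAVK": "expanded_only",  # EMSY
    "DLLIPP": "expanded_only",  # CBLB
    "RDLPPP": "expanded_only",  # CBL
    "RILRLK": "expanded_only",  # RNF8
    "TILTPK": "expanded_only",  # CUX1
    "QLLPLP": "expanded_only",  # MED12
    "NILLLP": "expanded_only",  # MED14
    "TLLSPK": "expanded_only",  # Cabin1
    "RDLMPK": "expanded_only",  # Dynamin1
    "SLLQPP": "expanded_only",  # SIK3
    "NTLQLP": "expanded_only",  # KCNK18 (Leu in the Val pocket)
    "NFLCVK": "expanded_only",  # A238L (Lys across the Pro pocket)
}

# Independent definition of the position classes for brute-force oracles:
# a list of allowed-residue sets, None meaning wildcard.
PI = set("NQDESRTH")
PHI = set("YTDFILV")
ORACLE_CLASSES = {
    "core_lxvp": [{"L"}, None, {"V"}, {"P"}],
    "canonical_pilxvp": [PI, PHI, {"L"}, None, {"V"}, {"P"}],
    "expanded_pilxvp": [PI, PHI, {"L"}, None, set("VPL"), set("PK")],
    "structural_pilxvp": [PI, PHI, {"L"}, None, set("VPLIH"), None],
    "pxixit_short": [{"P"}, None, None, None, set("IV"), set("TDH")],
    "pxixit_long": [{"P"}, None, None, None, None, set("IV"), set("TDH")],
}


def naive_scan(sequence, classes):
    """Brute-force per-window position-class oracle (independent of scan())."""
    seq = sequence.upper()
    w = len(classes)
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if all(c is None or window[j] in c for j, c in enumerate(classes)):
            hits.append((i + 1, window))
    return hits


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def mixed_plant_dataset():
    """A synthetic proteome with fully-qualifying and deliberately defective plants."""
    spec = [
        PlantRequest("canonical", 5),
        PlantRequest("expanded", 5),
        PlantRequest("canonical", 3, in_idr=False),
        PlantRequest("canonical", 3, give_phospho=False),
        PlantRequest("expanded", 3, give_pxixit=False),
    ]
    return generate(GeneratorConfig(seed=11, n_proteins=40), spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
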
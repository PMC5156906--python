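"""Motif definitions, PROSITE round-trips, scanning, and hexamer classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimfunnel.motifs import (
    CANONICAL_AA,
    MotifDefinition,
    MotifMatch,
    ResidueClass,
    build_motif_library,
    classify_hexamer,
    parse_prosite,
    scan,
    scan_pxixit,
)

from conftest import CURATED_HEXAMERS, ORACLE_CLASSES, naive_scan, random_protein


@pytest.fixture(scope="module")
def library():
    return build_motif_library()


class TestDefinitions:
    def test_library_contains_all_six_motifs(self, library):
        assert set(library) == {
            "core_lxvp",
            "canonical_pilxvp",
            "expanded_pilxvp",
            "structural_pilxvp",
            "pxixit_short",
            "pxixit_long",
        }

    def test_canonical_position_classes(self, library):
        pos = library["canonical_pilxvp"].positions
        assert pos[0].allowed == set("NQDESRTH")
        assert pos[1].allowed == set("YTDFILV")
        assert pos[2].allowed == {"L"}
        assert pos[3].wildcard
        assert pos[4].allowed == {"V"}
        assert pos[5].allowed == {"P"}

    def test_expanded_and_structural_tails(self, library):
        assert library["expanded_pilxvp"].positions[4].allowed == set("VPL")
        assert library["expanded_pilxvp"].positions[5].allowed == set("PK")
        assert library["structural_pilxvp"].positions[4].allowed == set("VPLIH")
        assert library["structural_pilxvp"].positions[5].wildcard

    def test_pxixit_dialects(self, library):
        short, long = library["pxixit_short"], library["pxixit_long"]
        assert short.length == 6 and long.length == 7
        for d in (short, long):
            assert d.positions[0].allowed == {"P"}
            assert d.positions[-2].allowed == {"I", "V"}
            assert d.positions[-1].allowed == {"T", "D", "H"}

    def test_prosite_round_trip_is_bit_exact(self, library):
        for name, motif in library.items():
            text = motif.to_prosite()
            assert parse_prosite(name, text).to_prosite() == text

    def test_residue_class_invariants(self):
        with pytest.raises(ValueError):
            ResidueClass("")
        with pytest.raises(ValueError):
            ResidueClass("AXZ")  # X not canonical
        with pytest.raises(ValueError):
            ResidueClass("AA")
        assert ResidueClass(wildcard=True).allowed == CANONICAL_AA

    def test_motif_minimum_length(self):
        with pytest.raises(ValueError):
            MotifDefinition("too_short", (ResidueClass("L"), ResidueClass("P")))


class TestScan:
    def test_worked_example_coordinates(self, library):
        # QYLAVP inside the decamer DDQYLAVPQH, 1-based inclusive
        hits = scan("DDQYLAVPQH", library["canonical_pilxvp"])
        assert len(hits) == 1
        m = hits[0]
        assert (m.start, m.end, m.sequence) == (3, 8, "QYLAVP")

    def test_empty_sequence(self, library):
        for motif in library.values():
            assert scan("", motif) == []

    def test_non_string_sequence_raises(self, library):
        with pytest.raises(TypeError):
            scan(12345, library["core_lxvp"])

    def test_lowercase_input_is_uppercased(self, library):
        assert scan("ntlqlp", library["structural_pilxvp"])[0].sequence == "NTLQLP"

    def test_overlapping_matches_all_reported(self, library):
        # two overlapping L-x-V-P cores: LLVPVP -> LxVP at 1 and VPVP? no;
        # use LVLVPVP: LxVP windows at 2 (VLVP? no)... construct explicitly
        seq = "LAVPLAVP"  # core at 1 and 5
        hits = scan(seq, library["core_lxvp"])
        assert [(m.start, m.sequence) for m in hits] == [(1, "LAVP"), (5, "LAVP")]
        # genuinely overlapping: LLLVVP has core LxVP? L L L V V P -> LVVP at 3
        hits2 = scan("LLVPVPVP", library["core_lxvp"])
        assert [m.start for m in hits2] == [1]

    def test_ambiguity_codes_fail_constrained_and_pass_wildcards(self, library):
        assert scan("LXVP", library["core_lxvp"])  # X at wildcard
        assert not scan("XAVP", library["core_lxvp"])  # X at constrained L
        assert not scan("LAXP", library["core_lxvp"])

    def test_matches_brute_force_on_fixed_pseudorandom_sequence(self, library, rng):
        seq = random_protein(rng, 200, alphabet="ACDEFGHIKLMNPQRSTVWYX")
        for name, motif in library.items():
            got = [(m.start, m.sequence) for m in scan(seq, motif)]
            assert got == naive_scan(seq, ORACLE_CLASSES[name]), name

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWYXBZU", min_size=0, max_size=80),
        st.sampled_from(sorted(ORACLE_CLASSES)),
    )
    def test_scan_equals_oracle_property(self, seq, name):
        motif = build_motif_library()[name]
        got = [(m.start, m.sequence) for m in scan(seq, motif)]
        assert got == naive_scan(seq, ORACLE_CLASSES[name])

    def test_match_invariants(self, library, rng):
        seq = random_protein(rng, 500)
        for motif in library.values():
            for m in scan(seq, motif):
                assert m.end - m.start + 1 == motif.length
                assert seq[m.start - 1 : m.end] == m.sequence
                assert motif.accepts(m.sequence)


class TestScanPxixit:
    def test_short_dialect_worked_examples(self):
        assert [m.sequence for m in scan_pxixit("PTSPVT", {"short"})] == ["PTSPVT"]
        hits = scan_pxixit("ESPRIEITS", {"short"})
        assert [(m.start, m.sequence) for m in hits] == [(3, "PRIEIT")]

    def test_long_vs_short_on_seven_mer(self):
        assert len(scan_pxixit("PAAAAVT", {"long"})) == 1
        assert scan_pxixit("PAAAAVT", {"short"}) == []

    def test_union_is_labeled_and_sorted(self):
        # PVIVIT-like site matches short at 1; embed a long-only site after
        seq = "PAIVITAAAPAAAAVD"
        hits = scan_pxixit(seq, {"short", "long"})
        assert all(h.dialect in {"short", "long"} for h in hits)
        starts = [(h.start, h.dialect) for h in hits]
        assert starts == sorted(starts)
        assert len(set(starts)) == len(starts)  # dedup by (start, dialect)

    def test_empty_dialect_set_raises(self):
        with pytest.raises(ValueError):
            scan_pxixit("PAIVIT", set())


class TestClassifyHexamer:
    @pytest.mark.parametrize("hexamer,label", sorted(CURATED_HEXAMERS.items()))
    def test_curated_sites_classify_to_reported_class(self, hexamer, label):
        assert classify_hexamer(hexamer) == label

    @pytest.mark.parametrize(
        "hexamer,label",
        [
            ("AAAAAA", "no_match"),
            ("NTLAIA", "structural_only"),  # Ile in the Val pocket, free tail
            ("QYLAHG", "structural_only"),  # His in the Val pocket
        ],
    )
    def test_non_curated_labels(self, hexamer, label):
        assert classify_hexamer(hexamer) == label

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            classify_hexamer("QYLAV")
        with pytest.raises(ValueError):
            classify_hexamer("QYLAVPP")

    def test_containment_chain_on_curated_sites(self):
        lib = build_motif_library()
        for hexamer in CURATED_HEXAMERS:
            if lib["canonical_pilxvp"].accepts(hexamer):
                assert lib["expanded_pilxvp"].accepts(hexamer)
            if lib["expanded_pilxvp"].accepts(hexamer):
                assert lib["structural_pilxvp"].accepts(hexamer)

    def test_containment_chain_random_sampling(self, rng):
        lib = build_motif_library()
        can, exp, stru = (
            lib["canonical_pilxvp"],
            lib["expanded_pilxvp"],
            lib["structural_pilxvp"],
        )
        aa = np.array(sorted(CANONICAL_AA))
        hexamers = ["".join(row) for row in rng.choice(aa, size=(100_000, 6))]
        for h in hexamers:
            if can.accepts(h):
                assert exp.accepts(h)
            if exp.accepts(h):
                assert stru.accepts(h)

    def test_labels_exclusive_and_exhaustive(self, rng):
        labels = {"canonical", "expanded_only", "structural_only", "no_match"}
        aa = np.array(sorted(CANONICAL_AA))
        for row in rng.choice(aa, size=(2000, 6)):
            assert classify_hexamer("".join(row)) in labels


class TestBackgroundRates:
    """Per-window match probabilities under an iid uniform background.

    Counting class-size products: canonical 8*7*1*20*1*1 = 1120 of 20^6
    windows, expanded 8*7*1*20*3*2 = 6720, structural 8*7*1*20*5*20 =
    112000.  Empirical frequencies must fall within 4 binomial SD.
    """

    EXPECTED = {
        "canonical_pilxvp": 1120 / 20**6,
        "expanded_pilxvp": 6720 / 20**6,
        "structural_pilxvp": 112000 / 20**6,
    }

    def test_empirical_window_frequencies(self, library):
        rng = np.random.default_rng(77)
        seqs = [random_protein(rng, 5000) for _ in range(60)]
        n_windows = sum(len(s) - 5 for s in seqs)
        for name, p in self.EXPECTED.items():
            count = sum(len(scan(s, library[name])) for s in seqs)
            sd = np.sqrt(n_windows * p * (1 - p))
            assert abs(count - n_windows * p) <= 4 * sd, (name, count, n_windows * p)


def test_motif_match_coordinate_consistency_guard():
    with pytest.raises(ValueError):
        MotifMatch("p", 1, 3, "QYLAVP", "canonical_pilxvp")
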
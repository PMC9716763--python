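"""Length-signature calling, identity fallback and the full classify pipeline."""
import random
from functools import lru_cache

import pytest

from igstyper.classify import (
    ReferencePanel,
    call_by_igs2_length,
    call_by_length,
    classify,
    percent_identity,
)
from igstyper.dissect import AnchorFailure, TrnaReferenceSet
from igstyper.seqs import reverse_complement
from igstyper.signatures import build_default_table
from igstyper.synthetic import NoiseModel, apply_noise, make_amplicon


def brute_force_identity_set(a, b, gap_open=-2.0, gap_extend=-1.0):
    """Oracle: enumerate every global alignment of two tiny strings, return
    the identities (matches/columns * 100) achieved by optimal-score ones."""
    best = {"score": float("-inf"), "idents": set()}

    def walk(i, j, state, score, matches, columns):
        if i == len(a) and j == len(b):
            if score > best["score"]:
                best["score"], best["idents"] = score, set()
            if score == best["score"]:
                best["idents"].add(100.0 * matches / columns if columns else 100.0)
            return
        if i < len(a) and j < len(b):
            delta = 1.0 if a[i] == b[j] else -1.0
            walk(i + 1, j + 1, "m", score + delta,
                 matches + (a[i] == b[j]), columns + 1)
        if i < len(a):
            cost = gap_extend if state == "ga" else gap_open
            walk(i + 1, j, "ga", score + cost, matches, columns + 1)
        if j < len(b):
            cost = gap_extend if state == "gb" else gap_open
            walk(i, j + 1, "gb", score + cost, matches, columns + 1)

    walk(0, 0, None, 0.0, 0, 0)
    return best["idents"]


class TestCallByLength:
    @pytest.mark.parametrize(
        "length,species",
        [
            (40, "Ceratitis capitata"),
            (2, "Ceratitis cosyra"),
            (62, "Ceratitis quilicii"),
            (63, "Ceratitis quilicii"),
            (64, "Ceratitis quilicii"),
            (34, "Ceratitis rosa"),
            (0, "Bactrocera dorsalis"),
        ],
    )
    def test_printed_lengths_map_to_their_species(self, table, length, species):
        call = call_by_length(length, table)
        assert call.status == "unambiguous"
        assert call.species == species
        assert call.evidence["matched_window"] == table.igs1_window(species)

    def test_off_signature_length_gives_no_call(self, table):
        assert call_by_length(20, table).status == "no_call"

    def test_exhaustive_lengths_have_unique_status(self, table):
        """Pure function of (length, table): every length 0..100 maps to
        exactly one status and never to an ambiguous multi-species call."""
        for length in range(101):
            call = call_by_length(length, table)
            assert call.status in {"unambiguous", "no_call"}
            if call.status == "unambiguous":
                assert call.species in table.species()
                assert len(call.candidates) == 1

    def test_unambiguous_calls_carry_confounder_caveats(self, table):
        call = call_by_length(2, table)
        assert ("Ceratitis pallidula", 97.04) in call.caveats


class TestCallByIgs2Length:
    def test_shared_length_is_ambiguous_for_the_pair(self, table):
        call = call_by_igs2_length(18, table)
        assert call.status == "ambiguous"
        assert set(call.candidates) == {"Ceratitis rosa", "Ceratitis quilicii"}

    def test_single_window_match_is_still_not_unambiguous(self, table):
        call = call_by_igs2_length(16, table)
        assert call.status != "unambiguous"
        assert call.candidates == ("Ceratitis quilicii",)
        assert any("weak" in note for note in call.notes)

    def test_out_of_window_length_gives_no_call(self, table):
        assert call_by_igs2_length(40, table).status == "no_call"


class TestPercentIdentity:
    @pytest.mark.parametrize("seq", ["A", "ACGT", "TTTTTTTT"])
    def test_self_identity_is_100(self, seq):
        assert percent_identity(seq, seq) == 100.0

    def test_single_mismatch(self):
        assert percent_identity("ACGT", "ACGA") == 75.0

    def test_terminal_gap_counts_in_denominator(self):
        assert percent_identity("ACGT", "ACG") == 75.0

    @pytest.mark.parametrize(
        "a,b", [("ACGT", "ACG"), ("ACGT", "AGT"), ("AAAA", "AATA"),
                ("ACG", "TGC"), ("AC", "ACGT")]
    )
    def test_matches_brute_force_enumeration(self, a, b):
        assert percent_identity(a, b) in brute_force_identity_set(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")


class TestClassifyPipeline:
    def test_zero_noise_round_trip_small(self, species_list):
        for species in species_list:
            for seed in range(5):
                amp = make_amplicon(species, rng_seed=seed)
                call = classify(amp.sequence, TrnaReferenceSet.for_species(species))
                assert call.status == "unambiguous"
                assert call.species == species

    def test_quilicii_call_carries_fasciventris_caveat(self):
        amp = make_amplicon("Ceratitis quilicii", rng_seed=1)
        call = classify(amp.sequence, TrnaReferenceSet.for_species("Ceratitis quilicii"))
        assert ("Ceratitis fasciventris", 100.0) in call.caveats

    def test_orientation_invariance(self, species_list):
        for species in species_list:
            amp = make_amplicon(species, rng_seed=8)
            refs = TrnaReferenceSet.for_species(species)
            fwd = classify(amp.sequence, refs)
            rev = classify(reverse_complement(amp.sequence), refs)
            assert (fwd.status, fwd.species) == (rev.status, rev.species)
            assert fwd.evidence["igs1_len"] == rev.evidence["igs1_len"]

    def test_igs2_contradiction_downgrades_call(self):
        """A rosa-length IGS-I with a quilicii-length IGS-II is suspicious:
        the call drops to ambiguous instead of trusting either region."""
        amp = make_amplicon("Ceratitis rosa", rng_seed=2, igs2_len_override=16)
        call = classify(amp.sequence, TrnaReferenceSet.for_species("Ceratitis rosa"))
        assert call.status == "ambiguous"
        assert set(call.candidates) == {"Ceratitis rosa", "Ceratitis quilicii"}

    def test_igs2_corroboration_noted(self):
        amp = make_amplicon("Ceratitis rosa", rng_seed=2)
        call = classify(amp.sequence, TrnaReferenceSet.for_species("Ceratitis rosa"))
        assert call.status == "unambiguous"
        assert any("corroborates" in note for note in call.notes)

    def test_anchor_failure_propagates_without_panel(self):
        rng = random.Random(7)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        with pytest.raises(AnchorFailure):
            classify(seq, TrnaReferenceSet.for_species("Ceratitis capitata"))

    def test_random_queries_never_unambiguous_with_panel(self):
        """Nearest-neighbour fallback refuses junk: 50 random 300-mers yield
        zero unambiguous calls at the default margin and identity floor."""
        rng = random.Random(4242)
        panel = ReferencePanel.default_synthetic(seed=0)
        refs = TrnaReferenceSet.for_species("Ceratitis capitata")
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            call = classify(seq, refs, panel=panel)
            assert call.status != "unambiguous"

    def test_indel_shifted_length_rescued_by_identity_fallback(self):
        """An IGS-I length pushed off-signature by simulated indels falls back
        to panel identity and still resolves to the right species."""
        amp = make_amplicon("Ceratitis capitata", rng_seed=3, igs1_len_override=43)
        panel = ReferencePanel.default_synthetic(seed=0)
        call = classify(amp.sequence, TrnaReferenceSet.for_species("Ceratitis capitata"),
                        panel=panel)
        assert call.status == "unambiguous"
        assert call.species == "Ceratitis capitata"
        assert call.identity_evidence is not None
        assert call.identity_evidence.margin >= 2.0
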
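"""RNA map tests: dot-bracket encoding, folding backends, exhaustive enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import simbias.rna as rna
from simbias.catalog import ResumableInterrupt
from simbias.rna import (
    FallbackFolder,
    MalformedStructureError,
    InvalidSequenceError,
    RNAStructure,
    decode_dotbracket,
    encode_dotbracket,
    enumerate_rna_map,
    fold,
    valid_structures,
)

from oracles import brute_force_max_pairs


class TestEncoding:
    def test_published_example(self):
        assert str(encode_dotbracket("..(((...)))....")) == \
            "000010101000000001010100000000"

    def test_all_dots(self):
        assert str(encode_dotbracket("." * 15)) == "0" * 30

    @settings(derandomize=True, max_examples=200)
    @given(st.sampled_from(list(valid_structures(9)) + list(valid_structures(12))))
    def test_roundtrip(self, db):
        assert decode_dotbracket(encode_dotbracket(db)).dotbracket == db

    @pytest.mark.parametrize("bad", ["((.", "())(", ".x.", "(((", ")"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(MalformedStructureError):
            encode_dotbracket(bad)


class TestFold:
    def test_unpairable_sequence_is_open_chain(self):
        for folder in ("fallback", "vienna"):
            assert fold("AAAAAAAAAAAAAAA", folder).dotbracket == "." * 15

    def test_deterministic(self):
        seq = "GCGCUUCGGCAAAUGGC"
        assert fold(seq, "fallback") == fold(seq, "fallback")
        assert fold(seq, "vienna") == fold(seq, "vienna")

    def test_invalid_sequence_rejected(self):
        with pytest.raises(InvalidSequenceError):
            fold("ACGTX", "fallback")

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGU", "nosuch")

    def test_fallback_hairpin_matches_brute_force(self):
        """Max pair count equals exhaustive enumeration over all pairings of a 12-mer."""
        for seq in ("GGGGAAAACCCC", "GCGCAAAAGCGC", "AUAUGCGCAUAU"):
            db = fold(seq, "fallback").dotbracket
            assert db.count("(") == brute_force_max_pairs(seq)

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=10))
    def test_fallback_pair_count_optimal_random(self, seq):
        db = fold(seq, "fallback").dotbracket
        assert db.count("(") == brute_force_max_pairs(seq)


class TestEnumeration:
    def test_l1_single_open_chain(self):
        emap = enumerate_rna_map(1, "fallback")
        assert emap.n_outputs == 1
        assert emap.table.loc[0, "output"] == "."
        assert emap.table.loc[0, "probability"] == 1.0

    def test_probabilities_normalized_and_conserved(self):
        emap = enumerate_rna_map(6, "fallback")
        assert emap.table["probability"].sum() == pytest.approx(1.0)
        assert emap.table["neutral_set_size"].sum() == 4 ** 6
        emap.validate()

    def test_matches_independent_per_sequence_refold(self):
        """Neutral set sizes at L=6 equal a naive one-at-a-time refold and tally."""
        emap = enumerate_rna_map(6, "fallback")
        folder = FallbackFolder()
        tally = {}
        for i in range(4 ** 6):
            seq = "".join("ACGU"[(i >> (2 * (5 - p))) & 3] for p in range(6))
            db = folder.fold(seq).dotbracket
            tally[db] = tally.get(db, 0) + 1
        got = dict(zip(emap.table["output"], emap.table["neutral_set_size"]))
        assert got == tally

    def test_delta_max_nonnegative(self):
        emap = enumerate_rna_map(7, "fallback")
        assert (emap.table["delta_max"] >= -1e-9).all()
        assert (emap.table["k_max_input"] <= emap.input_bits + 1e-9).all()

    def test_budget_checkpoint_resume(self, tmp_path, monkeypatch):
        """An interrupted run checkpoints and resumes to the identical catalogue."""
        monkeypatch.setattr(rna, "_CHUNK", 1024)
        ckpt = tmp_path / "rna.ckpt.json"
        with pytest.raises(ResumableInterrupt):
            enumerate_rna_map(6, "fallback", budget_seconds=0.0, checkpoint_path=str(ckpt))
        assert ckpt.exists()
        resumed = enumerate_rna_map(6, "fallback", checkpoint_path=str(ckpt))
        direct = enumerate_rna_map(6, "fallback")
        assert resumed.table.equals(direct.table)
        assert not ckpt.exists()  # consumed on completion

    def test_backend_version_recorded(self):
        emap = enumerate_rna_map(4, "fallback")
        assert emap.meta["backend"] == "fallback"
        assert "backend_version" in emap.meta


def test_structure_fixture_strings_are_valid(frozen):
    for key in ("s1", "s2"):
        s = frozen[key]
        assert isinstance(s, RNAStructure)
        assert s.length == 15
        assert s.dotbracket in set(valid_structures(15))


def test_read_fasta(tmp_path):
    fa = tmp_path / "seqs.fa"
    fa.write_text(">a\nACGT\n>b\nGGGCCC\n")
    recs = rna.read_fasta(fa)
    assert recs == [("a", "ACGU"), ("b", "GGGCCC")]
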
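import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from cypcensus import (
    AlignmentParams,
    NomenclatureThresholds,
    ReferenceEntry,
    ValidationError,
    align_stats,
    classify,
    classify_proteome,
    percent_identity,
)
from cypcensus.classifier import NovelNamer, _letters
from cypcensus.synthetic_data import (
    locked_motif_positions,
    mutate_to_exact_identity,
    mutate_to_identity,
)

from oracle_align import oracle_pid, oracle_stats

short_seq = st.text("ACGT", min_size=1, max_size=5)


class TestPercentIdentity:
    def test_identity_case(self):
        assert percent_identity("ACDEFG", "ACDEFG") == 100.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # ACDE/AC-E: 3 identities over 4 columns (oracle-derived)
            ("ACDE", "ACE", 75.0),
            ("AAAA", "AAAT", 75.0),
        ],
    )
    def test_short_examples_match_oracle(self, a, b, expected):
        assert percent_identity(a, b) == expected
        assert oracle_pid(a, b) == expected

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValidationError):
            percent_identity("", "ACDE")

    @settings(derandomize=True, max_examples=150)
    @given(a=short_seq, b=short_seq)
    def test_equals_bruteforce_oracle(self, a, b):
        score, ident, length = align_stats(a, b)
        assert (score, ident, length) == oracle_stats(a, b)

    @settings(derandomize=True, max_examples=60)
    @given(a=short_seq, b=short_seq)
    def test_symmetric(self, a, b):
        assert percent_identity(a, b) == percent_identity(b, a)

    def test_score_agrees_with_biopython_global_aligner(self):
        """Independent cross-check of the affine-gap score on long pairs."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(42)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aa), size=int(rng.integers(30, 80))))
            b = "".join(rng.choice(list(aa), size=int(rng.integers(30, 80))))
            score, _ident, _length = align_stats(a, b)
            assert score == aligner.score(a, b)

    def test_gap_params_validated(self):
        with pytest.raises(ValidationError):
            AlignmentParams(gap_open=0.2, gap_extend=0.5)


class TestClassify:
    thresholds = NomenclatureThresholds()

    def test_verbatim_reference_is_its_own_subfamily(self, library5):
        ref = library5[0]
        a = classify("q", ref.sequence, library5, self.thresholds)
        assert a.best_identity == 100.0
        assert a.family == ref.family
        assert a.subfamily_label == ref.subfamily_letter
        assert not a.is_novel_family and not a.is_novel_subfamily

    def test_half_identity_mutant_is_novel_subfamily(self, library5):
        """~50% identity: same family, new subfamily letter."""
        ref = library5[1]
        locked = locked_motif_positions(len(ref.sequence))
        q = mutate_to_identity(ref.sequence, 0.5, seed=3, lock_positions=locked)
        realized = percent_identity(q, ref.sequence)
        assert 40.0 < realized <= 55.0  # verify the construction landed in band
        a = classify("q", q, library5, self.thresholds)
        assert a.best_hit == ref.cyp_name
        assert a.family == ref.family
        assert a.is_novel_subfamily and not a.is_novel_family
        assert a.subfamily_label == "B"  # next unused letter after library's A

    def test_distant_query_founds_novel_family(self, library5):
        ref = library5[2]
        locked = locked_motif_positions(len(ref.sequence))
        q = mutate_to_identity(ref.sequence, 0.25, seed=9, lock_positions=locked)
        assert percent_identity(q, ref.sequence) <= 40.0
        a = classify("q", q, library5, self.thresholds)
        assert a.is_novel_family
        assert a.family == "CYPNOVEL1"

    def test_exact_family_threshold_falls_to_novel_family(self, library5):
        """Identity of exactly 40.0% is NOT >40%: new family (strict rule)."""
        ref = library5[0]
        locked = locked_motif_positions(len(ref.sequence))
        q = mutate_to_exact_identity(ref.sequence, 0.40, seed=21,
                                     lock_positions=locked)
        assert percent_identity(q, ref.sequence) == 40.0
        a = classify("q", q, library5, self.thresholds)
        assert a.is_novel_family

    def test_tie_broken_by_lexicographic_name(self, library5):
        seq = library5[0].sequence
        twins = [
            ReferenceEntry(cyp_name="CYP9102A1", sequence=seq),
            ReferenceEntry(cyp_name="CYP9101A1", sequence=seq),
        ]
        a = classify("q", seq, twins)
        assert a.best_hit == "CYP9101A1"

    def test_empty_library_is_error(self):
        with pytest.raises(ValidationError):
            classify("q", "MKV", [])

    def test_raising_family_threshold_never_unnovels(self, library5):
        """Monotonicity: a novel-family call stays novel as the family
        cut-off rises."""
        ref = library5[3]
        locked = locked_motif_positions(len(ref.sequence))
        for target, seed in ((0.25, 1), (0.45, 2), (0.70, 3)):
            q = mutate_to_identity(ref.sequence, target, seed=seed,
                                   lock_positions=locked)
            calls = []
            for fam_min in (30.0, 40.0, 50.0):
                th = NomenclatureThresholds(fam_min, 55.0)
                calls.append(classify("q", q, library5, th).is_novel_family)
            # once novel, always novel under a stricter threshold
            assert calls == sorted(calls)


class TestClassifyProteome:
    def test_mixed_batch(self, library5):
        locked = locked_motif_positions(400)
        queries = [
            ("known", library5[0].sequence),
            ("subfam", mutate_to_identity(library5[1].sequence, 0.5, 4, locked)),
            ("novel", mutate_to_identity(library5[2].sequence, 0.25, 4, locked)),
        ]
        out = classify_proteome(queries, library5)
        assert [a.protein_id for a in out] == ["known", "subfam", "novel"]
        families = {a.protein_id: a.family for a in out}
        assert families["known"] == library5[0].family
        assert families["subfam"] == library5[1].family
        assert families["novel"] == "CYPNOVEL1"

    def test_empty_candidates(self, library5):
        assert classify_proteome([], library5) == []

    def test_deterministic(self, library5):
        locked = locked_motif_positions(400)
        queries = [
            ("a", mutate_to_identity(library5[0].sequence, 0.5, 1, locked)),
            ("b", mutate_to_identity(library5[0].sequence, 0.25, 2, locked)),
        ]
        assert classify_proteome(queries, library5) == classify_proteome(
            queries, library5
        )

    def test_novel_labels_allocated_in_input_order(self, library5):
        locked = locked_motif_positions(400)
        queries = [
            (f"n{i}", mutate_to_identity(library5[0].sequence, 0.25, 10 + i, locked))
            for i in range(3)
        ]
        out = classify_proteome(queries, library5)
        assert [a.family for a in out] == ["CYPNOVEL1", "CYPNOVEL2", "CYPNOVEL3"]


class TestNovelNamer:
    def test_subfamily_letters_skip_used_and_extend_past_z(self):
        assert [_letters(i) for i in (0, 1, 25, 26, 27)] == ["A", "B", "Z", "AA", "AB"]
        lib = [ReferenceEntry(cyp_name="CYP900A3", sequence="MKV")]
        namer = NovelNamer(lib)
        assert namer.new_subfamily("CYP900") == "B"
        assert namer.new_subfamily("CYP900") == "C"

    def test_member_numbers_continue_after_library(self):
        lib = [
            ReferenceEntry(cyp_name="CYP900A3", sequence="MKV"),
            ReferenceEntry(cyp_name="CYP900A7", sequence="MKL"),
        ]
        namer = NovelNamer(lib)
        assert namer.next_member_number("CYP900", "A") == 8
        assert namer.next_member_number("CYP900", "A") == 9
        assert namer.next_member_number("CYP900", "B") == 1
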
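import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aabench.prep import (
    PreparationError,
    PreparedDataset,
    balance_negatives,
    binarize_affinity,
    detokenize,
    homology_filter,
    kmer_identity,
    length_filter,
    load_prepared,
    normalize_ic50,
    pad_protein,
    pad_trim_peptide,
    prepare_peptide_dataset,
    prepare_ppi_dataset,
    save_prepared,
    split_proteins,
    subset_fraction,
    tokenize,
)
from aabench.synthetic import PairRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestTokenize:
    def test_alanine_is_index_1(self):
        assert tokenize("AAA").tokens == (1, 1, 1)

    def test_unknown_residue_names_position(self):
        with pytest.raises(PreparationError, match="'X' at position 2"):
            tokenize("AXA")

    @given(st.text(alphabet=AA, min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, seq):
        assert detokenize(tokenize(seq)) == seq

    def test_empty_rejected(self):
        with pytest.raises(PreparationError):
            tokenize("")


class TestPadTrimPeptide:
    def test_short_left_padded(self):
        out = pad_trim_peptide(tokenize("A" * 9))
        assert len(out) == 26
        assert out.tokens[:17] == (0,) * 17
        assert out.tokens[17:] == (1,) * 9
        assert out.original_length == 9

    def test_long_keeps_last_26(self):
        toks = tuple(range(1, 21)) + tuple(range(1, 11))  # length 30
        out = pad_trim_peptide(toks)
        assert out.tokens == toks[4:]

    def test_exact_unchanged(self):
        toks = tuple([3] * 26)
        assert pad_trim_peptide(toks).tokens == toks

    def test_idempotent(self):
        once = pad_trim_peptide(tokenize("ACDEFGHIKLMNP"))
        assert pad_trim_peptide(once).tokens == once.tokens


class TestPadProtein:
    def test_short_left_padded(self):
        out = pad_protein(tuple([2] * 100))
        assert len(out) == 1000
        assert out.tokens[:900] == (0,) * 900

    def test_exact_unchanged(self):
        toks = tuple([4] * 1000)
        assert pad_protein(toks).tokens == toks

    def test_overlong_is_error(self):
        with pytest.raises(PreparationError, match="length_filter"):
            pad_protein(tuple([1] * 1001))

    def test_idempotent(self):
        once = pad_protein(tuple([5] * 321))
        assert pad_protein(once).tokens == once.tokens


class TestNormalizeIC50:
    def test_500nm_is_binder_threshold(self):
        assert round(normalize_ic50(500), 3) == 0.426

    def test_endpoints(self):
        assert normalize_ic50(1) == 1.0
        assert normalize_ic50(50000) == 0.0

    def test_strictly_decreasing(self):
        xs = np.logspace(0.1, math.log10(49000), 50)
        ys = [normalize_ic50(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(PreparationError):
            normalize_ic50(0.0)

    def test_binarize_composition(self):
        # the default threshold 0.426 is the 3-decimal rounding of the
        # exact 500 nM image (0.42576...), so test clear of the boundary
        assert binarize_affinity(normalize_ic50(450)) == 1
        assert binarize_affinity(normalize_ic50(550)) == 0


class TestBinarize:
    def test_tie_is_positive(self):
        assert binarize_affinity(0.426) == 1

    def test_extremes(self):
        assert binarize_affinity(0.0) == 0
        assert binarize_affinity(1.0) == 1


class TestLengthFilter:
    def test_strict_bounds(self):
        seqs = ["A" * n for n in (99, 100, 500, 1000, 1001)]
        kept = length_filter(seqs)
        assert [len(s) for s in kept] == [100, 500, 1000]

    def test_empty(self):
        assert length_filter([]) == []

    def test_all_passing_preserved(self):
        seqs = ["A" * 150, "C" * 300]
        assert length_filter(seqs) == seqs


class TestSplitProteins:
    def test_90_10(self):
        train, test = split_proteins(list(range(100)), seed=0)
        assert len(train) == 90 and len(test) == 10

    def test_disjoint_exhaustive(self):
        items = [f"p{i}" for i in range(37)]
        train, test = split_proteins(items, seed=1)
        assert set(train) | set(test) == set(items)
        assert not set(train) & set(test)

    def test_seeded(self):
        assert split_proteins(list(range(50)), seed=5) == \
            split_proteins(list(range(50)), seed=5)


class TestKmerIdentity:
    def test_identical(self):
        assert kmer_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_disjoint(self):
        assert kmer_identity("AAAAAA", "CCCCCC") == 0.0

    def test_hand_enumerated_quarter(self):
        # shared {ABCDE}; each side has 4 distinct 5-mers
        assert kmer_identity("ABCDEFGH", "ABCDEXYZ", k=5) == 0.25

    def test_symmetric(self, rng):
        a = "".join(rng.choice(list(AA), size=30))
        b = "".join(rng.choice(list(AA), size=40))
        assert kmer_identity(a, b) == kmer_identity(b, a)

    def test_short_sequence_rejected(self):
        with pytest.raises(PreparationError):
            kmer_identity("ACD", "ACDEFG", k=5)


class TestHomologyFilter:
    def test_exact_copy_removed(self):
        train = ["ACDEFGHIKLMNPQRSTVWY" * 5]
        test = [train[0], "W" * 100]
        assert homology_filter(test, train) == ["W" * 100]

    def test_random_proteins_all_kept(self, rng):
        # expected random shared-5-mer fraction is far below 0.40
        train = ["".join(rng.choice(list(AA), size=500)) for _ in range(10)]
        test = ["".join(rng.choice(list(AA), size=500)) for _ in range(10)]
        assert homology_filter(test, train) == test

    def test_empty_training_set(self):
        test = ["A" * 100]
        assert homology_filter(test, []) == test

    def test_monotone_in_training_set(self, rng):
        train = ["".join(rng.choice(list(AA), size=300)) for _ in range(5)]
        test = [train[0][:150] + "".join(rng.choice(list(AA), size=150))
                for _ in range(6)]
        kept_small = homology_filter(test, train[:1])
        kept_big = homology_filter(test, train)
        assert set(map(id, kept_big)) <= set(map(id, kept_small))


class TestBalanceNegatives:
    def _mock_positives(self, n, ids):
        out = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if len(out) == n:
                    return out
                out.append(PairRecord(ids[i], ids[j], 1))
        if len(out) == n:
            return out
        raise AssertionError("universe too small")

    def test_paper_training_count(self):
        ids = [f"p{i}" for i in range(1000)]
        positives = self._mock_positives(100_635, ids)
        balanced = balance_negatives(positives, ids, seed=0)
        assert len(balanced) == 201_270

    def test_paper_test_count(self):
        ids = [f"p{i}" for i in range(40)]
        positives = self._mock_positives(121, ids)
        balanced = balance_negatives(positives, ids, seed=0)
        assert len(balanced) == 242

    def test_no_negative_collides_with_positive(self):
        ids = [f"p{i}" for i in range(30)]
        positives = self._mock_positives(50, ids)
        balanced = balance_negatives(positives, ids, seed=3)
        pos_keys = {p.key for p in positives}
        negatives = [p for p in balanced if p.label == 0]
        assert len(negatives) == 50
        assert not any(p.key in pos_keys for p in negatives)
        assert len({p.key for p in negatives}) == 50

    def test_exclusion_respected(self):
        ids = [f"p{i}" for i in range(20)]
        positives = self._mock_positives(10, ids)
        exclude = {frozenset((ids[0], ids[19])), frozenset((ids[1], ids[18]))}
        balanced = balance_negatives(positives, ids, seed=1, exclude=exclude)
        assert not any(p.key in exclude for p in balanced if p.label == 0)

    def test_infeasible_errors(self):
        ids = ["a", "b", "c"]
        positives = self._mock_positives(3, ids)  # all pairs used
        with pytest.raises(PreparationError, match="candidate pairs"):
            balance_negatives(positives, ids, seed=0)

    def test_ratio_invariant(self):
        ids = [f"p{i}" for i in range(25)]
        for n in (5, 17, 60):
            balanced = balance_negatives(self._mock_positives(n, ids), ids, seed=n)
            labels = [p.label for p in balanced]
            assert sum(labels) == n and len(labels) == 2 * n


class TestSubsetFraction:
    def _dataset(self, n=1000):
        # rows are unique so they can act as lookup keys
        return PreparedDataset(np.arange(n * 3).reshape(n, 3),
                               np.linspace(0, 1, n))

    def test_quarter(self):
        assert subset_fraction(self._dataset(), 0.25, seed=0).n == 250

    def test_full_identity(self):
        ds = self._dataset(40)
        out = subset_fraction(ds, 1.0, seed=0)
        assert np.array_equal(out.inputs, ds.inputs)
        assert np.array_equal(out.targets, ds.targets)

    def test_seeded(self):
        a = subset_fraction(self._dataset(), 0.5, seed=9)
        b = subset_fraction(self._dataset(), 0.5, seed=9)
        assert np.array_equal(a.inputs, b.inputs)

    def test_pairing_preserved(self):
        ds = self._dataset(100)
        out = subset_fraction(ds, 0.3, seed=2)
        lookup = {tuple(row): t for row, t in zip(ds.inputs, ds.targets)}
        for row, t in zip(out.inputs, out.targets):
            assert lookup[tuple(row)] == t

    def test_out_of_range(self):
        with pytest.raises(PreparationError):
            subset_fraction(self._dataset(10), 0.0, seed=0)
        with pytest.raises(PreparationError):
            subset_fraction(self._dataset(10), 1.5, seed=0)


class TestPreparedIO:
    def test_peptide_roundtrip(self, tmp_path, peptide_records):
        ds = prepare_peptide_dataset(peptide_records[:20], split="train", seed=1)
        save_prepared(ds, tmp_path / "pep")
        back = load_prepared(tmp_path / "pep")
        assert np.array_equal(back.inputs, ds.inputs)
        assert np.allclose(back.targets, ds.targets)
        assert back.metadata["split"] == "train"

    def test_ppi_roundtrip(self, tmp_path, ppi_small):
        _, proteins, positives = ppi_small
        ds = prepare_ppi_dataset(proteins, positives[:15], target_length=200)
        save_prepared(ds, tmp_path / "ppi")
        back = load_prepared(tmp_path / "ppi")
        assert back.paired
        assert np.array_equal(back.inputs[0], ds.inputs[0])
        assert np.array_equal(back.inputs[1], ds.inputs[1])

    def test_unknown_pair_id_rejected(self, ppi_small):
        _, proteins, _ = ppi_small
        bad = [PairRecord("nope1", "nope2", 1)]
        with pytest.raises(PreparationError, match="unknown proteins"):
            prepare_ppi_dataset(proteins, bad, target_length=200)
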
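"""Mining and tokenization: worked examples, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dtimap.fcs import (
    MergeTable,
    TokenizedCorpus,
    apply_merge,
    count_adjacent_pairs,
    initialize_vocabulary,
    mine_fcs,
    tokenize,
    vocabulary_from_merge_table,
)
from oracles import oracle_mine


def corpus_of(*seqs):
    return TokenizedCorpus([list(s) for s in seqs], {c for s in seqs for c in s})


class TestInitializeVocabulary:
    def test_character_split(self):
        vocab, W = initialize_vocabulary(["AB", "BC"])
        assert {"A", "B", "C"} <= set(vocab.tokens)
        assert W.sequences == [["A", "B"], ["B", "C"]]
        assert vocab.tokens[:2] == ["<pad>", "<unk>"]

    def test_empty_sequence_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="dtimap"):
            vocab, W = initialize_vocabulary(["AB", "", "C"])
        assert len(W.sequences) == 2
        assert "empty" in caplog.text

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            initialize_vocabulary([])


class TestPairCounting:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            ((["A", "A", "A"],), {("A", "A"): 1}),
            ((["A", "B", "A", "B"],), {("A", "B"): 2, ("B", "A"): 1}),
            ((["A"],), {}),
            ((["A", "A", "A", "A"],), {("A", "A"): 2}),
        ],
    )
    def test_greedy_nonoverlapping(self, seqs, expected):
        W = TokenizedCorpus([list(s) for s in seqs], set())
        assert dict(count_adjacent_pairs(W)) == expected


class TestApplyMerge:
    def test_full_merge(self):
        W = apply_merge(corpus_of("ABAB"), ("A", "B"))
        assert W.sequences == [["AB", "AB"]]

    def test_greedy_left_to_right(self):
        W = apply_merge(corpus_of("AAA"), ("A", "A"))
        assert W.sequences == [["AA", "A"]]

    def test_absent_pair_is_noop(self):
        W = apply_merge(corpus_of("ABC"), ("X", "Y"))
        assert W.sequences == [["A", "B", "C"]]


class TestMineFcs:
    def test_worked_corpus(self):
        vocab, table = mine_fcs(["ABAB", "ABAB", "ABC"], theta=2)
        assert table.merges == [("A", "B"), ("AB", "AB")]
        assert set(vocab.tokens) == {"<pad>", "<unk>", "A", "B", "C", "AB", "ABAB"}

    def test_theta_above_all_counts_mines_nothing(self):
        vocab, table = mine_fcs(["ABC", "DEF"], theta=2)
        assert table.merges == []
        assert len(vocab) == 2 + 6

    def test_vocab_cap_allows_exactly_one_merge(self):
        # cap = reserved + alphabet + 1
        vocab, table = mine_fcs(["ABAB", "ABAB"], theta=1, max_vocab=2 + 2 + 1)
        assert len(table.merges) == 1
        assert table.merges[0] == ("A", "B")

    def test_recorded_frequencies_at_least_theta(self):
        _, table = mine_fcs(["ABABAB", "ABAB", "CDCD"], theta=2)
        assert all(f >= 2 for f in table.frequencies)

    def test_matches_bruteforce_oracle_on_random_corpora(self, rng):
        for _ in range(40):
            n_sym = int(rng.integers(2, 7))
            alphabet = "ABCDEF"[:n_sym]
            n_seq = int(rng.integers(1, 20))
            corpus = [
                "".join(rng.choice(list(alphabet), size=rng.integers(1, 31)))
                for _ in range(n_seq)
            ]
            theta = int(rng.integers(1, 6))
            vocab, table = mine_fcs(corpus, theta=theta)
            o_vocab, o_merges, o_freqs = oracle_mine(corpus, theta)
            assert table.merges == o_merges
            assert table.frequencies == o_freqs
            assert set(vocab.tokens) == set(o_vocab)


class TestTokenize:
    def test_replays_merges_in_order(self):
        table = MergeTable([("A", "B"), ("AB", "AB")], [2, 2], 2, None, list("ABC"))
        vocab = vocabulary_from_merge_table(table)
        assert tokenize("ABABC", vocab, table).tokens == ["ABAB", "C"]

    def test_empty_merge_table_gives_characters(self):
        table = MergeTable([], [], 1, None, list("ABC"))
        vocab = vocabulary_from_merge_table(table)
        assert tokenize("CAB", vocab, table).tokens == ["C", "A", "B"]

    def test_unseen_character_maps_to_unk_index_but_reconstructs(self):
        table = MergeTable([("A", "B")], [2], 1, None, list("AB"))
        vocab = vocabulary_from_merge_table(table)
        sub = tokenize("AZB", vocab, table)
        assert sub.join() == "AZB"
        assert vocab.index("Z") == 1  # UNK
        assert "Z" in sub.tokens

    def test_empty_sequence_raises(self):
        table = MergeTable([], [], 1, None, list("AB"))
        with pytest.raises(ValueError):
            tokenize("", vocabulary_from_merge_table(table), table)

    @given(
        st.lists(st.text(alphabet="ABCD", min_size=1, max_size=25), min_size=1, max_size=15),
        st.text(alphabet="ABCD", min_size=1, max_size=40),
    )
    def test_reconstruction_and_idempotence(self, corpus, seq):
        vocab, table = mine_fcs(corpus, theta=2)
        sub = tokenize(seq, vocab, table)
        assert sub.join() == seq
        again = tokenize(sub.join(), vocab, table)
        assert again.tokens == sub.tokens


class TestMergeTableRoundTrip:
    def test_save_load(self, tmp_path):
        _, table = mine_fcs(["ABAB", "ABAB", "ABC"], theta=2, max_vocab=10)
        path = tmp_path / "merges.tsv"
        table.save(path)
        loaded = MergeTable.load(path)
        assert loaded.merges == table.merges
        assert loaded.frequencies == table.frequencies
        assert loaded.theta == table.theta
        assert loaded.max_vocab == table.max_vocab
        assert loaded.alphabet == table.alphabet


def test_planted_motif_recovered_in_vocabulary(rng):
    """A motif far above theta ends up in V (possibly inside a larger token)."""
    from dtimap.synthetic import generate_corpus

    corpus = generate_corpus("ABCDEFGH", 60, (15, 25), [("FED", 0.9)], rng)
    vocab, _ = mine_fcs(corpus, theta=10)
    assert any("FED" in tok for tok in vocab.tokens[2:])
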
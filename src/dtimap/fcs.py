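"""Frequent consecutive sub-sequence (FCS) mining and tokenization.

A byte-pair-encoding-style procedure over molecular strings: start from the
single characters of a corpus (SMILES atoms/bonds or amino acids), repeatedly
find the most frequent adjacent token pair, merge it into a new vocabulary
token, and rewrite the corpus — the *scan, identify, update* loop — until the
best pair falls below a minimum frequency ``theta`` or the vocabulary reaches
a maximum size ``max_vocab``.  New sequences are tokenized by replaying the
learned merges in order.

Pair occurrences are counted greedily left-to-right without overlap (so
``"AAA"`` holds one occurrence of ``(A, A)``, not two), which makes counts
equal to the number of replacements a merge will actually realize.  Ties
between equally frequent pairs go to the lexicographically smallest
concatenated string, then to the smallest (left, right) pair, so mining is
deterministic across platforms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("dtimap")

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1

__all__ = [
    "Vocabulary",
    "MergeTable",
    "SubstructureSequence",
    "TokenizedCorpus",
    "initialize_vocabulary",
    "count_adjacent_pairs",
    "apply_merge",
    "mine_fcs",
    "tokenize",
    "PAD_TOKEN",
    "UNK_TOKEN",
    "PAD_INDEX",
    "UNK_INDEX",
]


@dataclass
class Vocabulary:
    """Ordered sub-structure vocabulary with PAD at index 0 and UNK at index 1."""

    tokens: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.tokens[:2] != [PAD_TOKEN, UNK_TOKEN]:
            self.tokens = [PAD_TOKEN, UNK_TOKEN] + list(self.tokens)
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.tokens)}

    def add(self, token: str) -> int:
        if token in self._index:
            return self._index[token]
        self._index[token] = len(self.tokens)
        self.tokens.append(token)
        return self._index[token]

    def index(self, token: str) -> int:
        """Index of `token`, or the UNK index for out-of-vocabulary tokens."""
        return self._index.get(token, UNK_INDEX)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class MergeTable:
    """Ordered learned merges; ``frequencies[i]`` is the corpus count of
    ``merges[i]`` at the round it was learned (always >= theta)."""

    merges: list[tuple[str, str]]
    frequencies: list[int]
    theta: int
    max_vocab: int | None
    alphabet: list[str]

    def __len__(self) -> int:
        return len(self.merges)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        mv = 0 if self.max_vocab is None else self.max_vocab
        lines = [
            f"# theta={self.theta}\tmax_vocab={mv}",
            "# alphabet=" + "".join(self.alphabet),
        ]
        for (left, right), freq in zip(self.merges, self.frequencies):
            lines.append(f"{left}\t{right}\t{freq}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MergeTable":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 2 or not lines[0].startswith("#") or not lines[1].startswith("#"):
            raise ValueError(f"{path}: missing merge-table header lines")
        head = dict(
            kv.split("=", 1) for kv in lines[0].lstrip("# ").split("\t")
        )
        theta = int(head["theta"])
        mv = int(head["max_vocab"])
        alphabet = list(lines[1].split("=", 1)[1])
        merges, freqs = [], []
        for ln in lines[2:]:
            if not ln.strip():
                continue
            left, right, freq = ln.split("\t")
            merges.append((left, right))
            freqs.append(int(freq))
        return cls(merges, freqs, theta, mv or None, alphabet)


@dataclass
class SubstructureSequence:
    """A sequence decomposed into vocabulary tokens.

    Unseen characters are kept verbatim in ``tokens`` (they map to the UNK
    index when embedded), so joining the tokens always reconstructs the
    original string.
    """

    tokens: list[str]
    source_kind: str = "drug"

    def join(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TokenizedCorpus:
    sequences: list[list[str]]
    alphabet: set[str]


def initialize_vocabulary(corpus: Sequence[str]) -> tuple[Vocabulary, TokenizedCorpus]:
    """Build the initial single-character vocabulary and character-tokenize
    the corpus.  Empty sequences are dropped with a warning."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    sequences: list[list[str]] = []
    alphabet: set[str] = set()
    n_dropped = 0
    for seq in corpus:
        if not seq:
            n_dropped += 1
            continue
        sequences.append(list(seq))
        alphabet.update(seq)
    if n_dropped:
        logger.warning("dropped %d empty sequence(s) from corpus", n_dropped)
    if not sequences:
        raise ValueError("corpus contains only empty sequences")
    vocab = Vocabulary([PAD_TOKEN, UNK_TOKEN] + sorted(alphabet))
    return vocab, TokenizedCorpus(sequences, alphabet)


def count_adjacent_pairs(W: TokenizedCorpus) -> Counter:
    """Corpus-wide counts of adjacent token pairs, greedy left-to-right and
    non-overlapping per pair type."""
    counts: Counter = Counter()
    for seq in W.sequences:
        last_end: dict[tuple[str, str], int] = {}
        for i in range(len(seq) - 1):
            pair = (seq[i], seq[i + 1])
            if i > last_end.get(pair, -1):
                counts[pair] += 1
                last_end[pair] = i + 1
    return counts


def _merge_sequence(seq: list[str], pair: tuple[str, str], merged: str) -> list[str]:
    out: list[str] = []
    i = 0
    n = len(seq)
    left, right = pair
    while i < n:
        if i + 1 < n and seq[i] == left and seq[i + 1] == right:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def apply_merge(W: TokenizedCorpus, pair: tuple[str, str]) -> TokenizedCorpus:
    """Rewrite every greedy left-to-right occurrence of `pair` as one token."""
    merged = pair[0] + pair[1]
    return TokenizedCorpus(
        [_merge_sequence(s, pair, merged) for s in W.sequences], W.alphabet
    )


def _best_pair(counts: Counter) -> tuple[tuple[str, str], int] | None:
    if not counts:
        return None
    best = min(
        counts.items(), key=lambda kv: (-kv[1], kv[0][0] + kv[0][1], kv[0])
    )
    return best


def mine_fcs(
    corpus: Sequence[str],
    theta: int,
    max_vocab: int | None = None,
) -> tuple[Vocabulary, MergeTable]:
    """Run the scan-identify-update loop over `corpus`.

    Parameters
    ----------
    theta : minimum corpus frequency for a pair to be merged (>= 1).
    max_vocab : cap on total vocabulary size including the two reserved
        tokens and the initial alphabet; ``None`` or 0 means unbounded,
        in which case mining stops on `theta` alone.
    """
    if theta < 1:
        raise ValueError("theta must be >= 1")
    if max_vocab == 0:
        max_vocab = None
    vocab, W = initialize_vocabulary(corpus)
    if max_vocab is not None and max_vocab < len(vocab):
        raise ValueError(
            f"max_vocab={max_vocab} smaller than initial vocabulary ({len(vocab)})"
        )
    merges: list[tuple[str, str]] = []
    freqs: list[int] = []
    while max_vocab is None or len(vocab) < max_vocab:
        best = _best_pair(count_adjacent_pairs(W))
        if best is None or best[1] < theta:
            break
        pair, freq = best
        W = apply_merge(W, pair)
        vocab.add(pair[0] + pair[1])
        merges.append(pair)
        freqs.append(freq)
    table = MergeTable(
        merges, freqs, theta, max_vocab, sorted(W.alphabet)
    )
    return vocab, table


def tokenize(
    sequence: str,
    vocab: Vocabulary,
    merge_table: MergeTable,
    source_kind: str = "drug",
) -> SubstructureSequence:
    """Decompose `sequence` by replaying the learned merges in order.

    Characters never seen at mining time are kept verbatim (they index to
    UNK downstream); they can never merge because every learned token is a
    concatenation of alphabet characters.
    """
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    tokens = list(sequence)
    for pair in merge_table.merges:
        if len(tokens) < 2:
            break
        tokens = _merge_sequence(tokens, pair, pair[0] + pair[1])
    return SubstructureSequence(tokens, source_kind)


def tokenize_corpus(
    corpus: Iterable[str],
    vocab: Vocabulary,
    merge_table: MergeTable,
    source_kind: str = "drug",
) -> list[SubstructureSequence]:
    return [tokenize(s, vocab, merge_table, source_kind) for s in corpus]


def vocabulary_from_merge_table(table: MergeTable) -> Vocabulary:
    """Rebuild the vocabulary implied by a merge table (alphabet + merges)."""
    vocab = Vocabulary([PAD_TOKEN, UNK_TOKEN] + sorted(table.alphabet))
    for left, right in table.merges:
        vocab.add(left + right)
    return vocab
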
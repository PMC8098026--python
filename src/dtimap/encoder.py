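"""Augmented transformer embedding of sub-structure sequences.

Each token sequence is mapped to indices (cut or PAD-filled to a fixed
maximum length), embedded as the sum of a learnable content lookup and a
learnable positional lookup, and then contextualized by a stack of
transformer encoder layers.  PAD positions are excluded from attention so
padding never leaks into real-token context; with zero layers the
contextualizer is the identity, which is also how the no-transformer
ablation is realized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fcs import PAD_INDEX, SubstructureSequence, Vocabulary
from .nn import EmbeddingTable, Module, Tensor, TransformerEncoder

__all__ = ["EncoderConfig", "IndexedSequence", "SequenceEncoder", "index_sequence"]

# published full-scale defaults
DRUG_MAX_LEN = 50
PROTEIN_MAX_LEN = 545


@dataclass
class EncoderConfig:
    vocab_size: int
    max_len: int = DRUG_MAX_LEN
    embed_dim: int = 384
    n_layers: int = 2
    n_heads: int = 12
    ffn_dim: int = 1536
    dropout: float = 0.1

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


@dataclass
class IndexedSequence:
    indices: np.ndarray  # (max_len,) int
    mask: np.ndarray  # (max_len,) {0,1}
    true_length: int


def index_sequence(
    sub: SubstructureSequence, vocab: Vocabulary, max_len: int
) -> IndexedSequence:
    """Map tokens to vocabulary indices, truncating to the first `max_len`
    tokens and PAD-filling shorter sequences.  Out-of-vocabulary tokens map
    to UNK."""
    if len(sub.tokens) == 0:
        raise ValueError("cannot index an empty token sequence")
    idx = [vocab.index(t) for t in sub.tokens[:max_len]]
    true_length = len(idx)
    indices = np.full(max_len, PAD_INDEX, dtype=np.int64)
    indices[:true_length] = idx
    mask = np.zeros(max_len, dtype=np.int64)
    mask[:true_length] = 1
    return IndexedSequence(indices=indices, mask=mask, true_length=true_length)


def stack_indexed(seqs: list[IndexedSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-sequence indices/masks into (B, max_len) batch arrays."""
    return (
        np.stack([s.indices for s in seqs]),
        np.stack([s.mask for s in seqs]),
    )


class SequenceEncoder(Module):
    """Content + positional embedding tables and a transformer stack."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.content = EmbeddingTable(config.vocab_size, config.embed_dim, rng)
        self.positional = EmbeddingTable(config.max_len, config.embed_dim, rng)
        self.transformer = TransformerEncoder(
            config.n_layers,
            config.embed_dim,
            config.n_heads,
            config.ffn_dim,
            config.dropout,
            rng,
        )

    def embed(self, indices: np.ndarray) -> Tensor:
        """E = content[token index] + positional[position], every position
        (PAD included; masking happens in attention / pooling)."""
        indices = np.atleast_2d(indices)
        B, L = indices.shape
        positions = np.broadcast_to(np.arange(L), (B, L))
        return self.content(indices) + self.positional(positions)

    def contextualize(self, E: Tensor, mask: np.ndarray) -> Tensor:
        if not np.all(np.isfinite(E.data)):
            raise ValueError("non-finite values in embedding input")
        mask = np.atleast_2d(mask)
        return self.transformer(E, mask)

    def __call__(self, indices: np.ndarray, mask: np.ndarray) -> Tensor:
        return self.contextualize(self.embed(indices), mask)
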
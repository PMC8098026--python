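"""Interaction prediction: pairwise sub-structure interaction map, CNN
aggregation and sigmoid decoder, plus the ablation variants.

The map ``I`` has one row per drug sub-structure position and one column per
protein sub-structure position; under the default dot-product interaction
function each cell is a scalar intensity, so ``I`` is a 2-D map that can be
read directly as "which sub-structure pairs drive the prediction".  A single
convolution (3 filters, 3x3 kernel, stride 1, valid padding, ReLU) aggregates
neighborhood interactions; the flattened output feeds one linear unit with a
logistic link.

Variants:

- ``full``        encoder -> map -> CNN -> decoder
- ``no_cnn``      the map is flattened straight into the decoder
- ``no_augembed`` transformer skipped; the raw content+positional embedding
                  feeds the map
- ``no_interaction`` transformer and map skipped; masked mean pooling of each
                  side's embeddings, concatenated into the decoder
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig, SequenceEncoder, index_sequence, stack_indexed
from .fcs import MergeTable, Vocabulary, tokenize, vocabulary_from_merge_table
from .io import DTIPair
from .nn import Conv2d, Linear, Module, Tensor, concatenate, conv2d_valid

__all__ = [
    "HeadConfig",
    "DecoderParams",
    "InteractionMap",
    "InteractionModel",
    "DTIModel",
    "interaction_map",
    "aggregate",
    "predict_probability",
    "bce_loss",
]

VARIANTS = ("full", "no_cnn", "no_augembed", "no_interaction")
INTERACTION_FNS = ("dot", "sum", "average")
EPS = 1e-7


@dataclass
class HeadConfig:
    interaction_fn: str = "dot"
    cnn_filters: int = 3
    kernel_size: int = 3
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.interaction_fn not in INTERACTION_FNS:
            raise ValueError(
                f"unknown interaction_fn {self.interaction_fn!r}; "
                f"choose from {INTERACTION_FNS}"
            )


@dataclass
class DecoderParams:
    W_o: np.ndarray  # (n_features,)
    b_o: float


@dataclass
class InteractionMap:
    """Labeled pairwise interaction intensities for one drug-protein pair."""

    matrix: np.ndarray  # (n_drug_tokens, n_protein_tokens)
    drug_tokens: list[str]
    protein_tokens: list[str]


# ----------------------------------------------------------------- functional
def interaction_map(E_d: np.ndarray, E_p: np.ndarray, fn: str = "dot") -> np.ndarray:
    """Pairwise map I[j, i] = F(E_d[j], E_p[i]) for a single pair.

    ``dot`` gives the scalar product; ``sum``/``average`` reduce the
    elementwise sum of the two embeddings to a scalar.
    """
    E_d, E_p = np.asarray(E_d, float), np.asarray(E_p, float)
    if E_d.ndim != 2 or E_p.ndim != 2 or E_d.shape[1] != E_p.shape[1]:
        raise ValueError(
            f"embedding dims differ: {E_d.shape} vs {E_p.shape}"
        )
    if fn == "dot":
        return E_d @ E_p.T
    if fn == "sum":
        return E_d.sum(1)[:, None] + E_p.sum(1)[None, :]
    if fn == "average":
        d = E_d.shape[1]
        return (E_d.sum(1)[:, None] + E_p.sum(1)[None, :]) / (2 * d)
    raise ValueError(f"unknown interaction fn {fn!r}")


def aggregate(I: np.ndarray, conv: Conv2d) -> np.ndarray:
    """Apply the CNN (single valid convolution + ReLU) to a 2-D map."""
    I = np.asarray(I, float)
    if I.ndim != 2:
        raise ValueError("interaction map must be 2-D")
    x = Tensor(I[None, None])
    out = conv(x).relu()
    return out.data[0]


def predict_probability(O: np.ndarray, decoder: DecoderParams) -> float:
    """P = logistic(W_o . flatten(O) + b_o)."""
    flat = np.asarray(O, float).ravel()
    w = np.asarray(decoder.W_o, float).ravel()
    if flat.shape != w.shape:
        raise ValueError(f"flattened O has {flat.size} features, W_o has {w.size}")
    z = float(flat @ w + decoder.b_o)
    return float(1.0 / (1.0 + np.exp(-z)))


def bce_loss(P, Y) -> Tensor:
    """Mean binary cross-entropy, -[Y log P + (1-Y) log(1-P)].

    Probabilities at or beyond the open interval (0, 1) are clamped to
    [1e-7, 1-1e-7] with a warning.
    """
    P = P if isinstance(P, Tensor) else Tensor(P)
    Y = np.asarray(Y, float)
    if np.any((P.data <= 0.0) | (P.data >= 1.0)):
        warnings.warn("probabilities clamped to [1e-7, 1-1e-7] before log")
    Pc = P.clip(EPS, 1.0 - EPS)
    ll = Tensor(Y) * Pc.log() + Tensor(1.0 - Y) * (1.0 - Pc).log()
    return -ll.mean()


# --------------------------------------------------------------------- model
class InteractionModel(Module):
    """End-to-end network: two sequence encoders, the interaction head and
    the decoder, switchable between the full model and its ablations."""

    def __init__(
        self,
        drug_config: EncoderConfig,
        protein_config: EncoderConfig,
        head_config: HeadConfig,
        seed: int = 0,
    ):
        super().__init__()
        if drug_config.embed_dim != protein_config.embed_dim:
            raise ValueError("drug and protein embed_dim must match")
        rng = np.random.default_rng(seed)
        self.drug_config = drug_config
        self.protein_config = protein_config
        self.head_config = head_config
        self.drug_encoder = SequenceEncoder(drug_config, rng)
        self.protein_encoder = SequenceEncoder(protein_config, rng)
        k = head_config.kernel_size
        self.conv = Conv2d(1, head_config.cnn_filters, k, rng)
        td, tp = drug_config.max_len, protein_config.max_len
        if head_config.variant in ("full", "no_augembed"):
            if td < k or tp < k:
                raise ValueError(f"map {td}x{tp} smaller than kernel {k}")
            n_features = head_config.cnn_filters * (td - k + 1) * (tp - k + 1)
        elif head_config.variant == "no_cnn":
            n_features = td * tp
        else:  # no_interaction
            n_features = 2 * drug_config.embed_dim
        self.decoder = Linear(n_features, 1, rng)

    # ------------------------------------------------------------- pieces
    def _encode(self, d_idx, d_mask, p_idx, p_mask, contextual: bool):
        Ed = self.drug_encoder.embed(d_idx)
        Ep = self.protein_encoder.embed(p_idx)
        if contextual:
            Ed = self.drug_encoder.contextualize(Ed, d_mask)
            Ep = self.protein_encoder.contextualize(Ep, p_mask)
        return Ed, Ep

    def _map(self, Ed: Tensor, Ep: Tensor) -> Tensor:
        fn = self.head_config.interaction_fn
        if fn == "dot":
            return Ed @ Ep.swapaxes(-1, -2)  # (B, Td, Tp)
        sd = Ed.sum(axis=-1)  # (B, Td)
        sp = Ep.sum(axis=-1)  # (B, Tp)
        B, td = sd.shape
        tp = sp.shape[1]
        I = sd.reshape(B, td, 1) + sp.reshape(B, 1, tp)
        if fn == "average":
            I = I * (1.0 / (2 * self.drug_config.embed_dim))
        return I

    def _decode(self, features: Tensor) -> Tensor:
        B = features.shape[0]
        flat = features.reshape(B, -1)
        return self.decoder(flat).reshape(B).sigmoid()

    # ------------------------------------------------------------- forward
    def forward(
        self,
        d_idx: np.ndarray,
        d_mask: np.ndarray,
        p_idx: np.ndarray,
        p_mask: np.ndarray,
    ) -> Tensor:
        """Interaction probabilities, shape (B,), each strictly in (0, 1)."""
        variant = self.head_config.variant
        if variant == "no_interaction":
            Ed, Ep = self._encode(d_idx, d_mask, p_idx, p_mask, contextual=False)
            pooled_d = _masked_mean(Ed, d_mask)
            pooled_p = _masked_mean(Ep, p_mask)
            return self._decode(concatenate([pooled_d, pooled_p], axis=-1))
        contextual = variant in ("full", "no_cnn")
        Ed, Ep = self._encode(d_idx, d_mask, p_idx, p_mask, contextual=contextual)
        I = self._map(Ed, Ep)
        if variant == "no_cnn":
            return self._decode(I)
        B, td, tp = I.shape
        O = conv2d_valid(
            I.reshape(B, 1, td, tp), self.conv.weight, self.conv.bias
        ).relu()
        return self._decode(O)

    __call__ = forward

    def interaction_map_batch(
        self, d_idx, d_mask, p_idx, p_mask, contextual: bool = True
    ) -> np.ndarray:
        """The raw map I for a batch (no gradient bookkeeping needed)."""
        Ed, Ep = self._encode(d_idx, d_mask, p_idx, p_mask, contextual=contextual)
        return self._map(Ed, Ep).data


def _masked_mean(E: Tensor, mask: np.ndarray) -> Tensor:
    m = np.atleast_2d(mask).astype(float)[:, :, None]  # (B, L, 1)
    total = (E * Tensor(m)).sum(axis=1)  # (B, D)
    count = m.sum(axis=1)  # (B, 1)
    return total * Tensor(1.0 / count)


# ------------------------------------------------------------------ pipeline
class DTIModel:
    """A trained pipeline bundle: merge tables, vocabularies, encoder and
    head configuration, and the network weights."""

    def __init__(
        self,
        drug_merges: MergeTable,
        protein_merges: MergeTable,
        drug_config: EncoderConfig,
        protein_config: EncoderConfig,
        head_config: HeadConfig,
        seed: int = 0,
    ):
        self.drug_merges = drug_merges
        self.protein_merges = protein_merges
        self.drug_vocab: Vocabulary = vocabulary_from_merge_table(drug_merges)
        self.protein_vocab: Vocabulary = vocabulary_from_merge_table(protein_merges)
        drug_config.vocab_size = len(self.drug_vocab)
        protein_config.vocab_size = len(self.protein_vocab)
        self.net = InteractionModel(drug_config, protein_config, head_config, seed)
        self.seed = seed

    # ----------------------------------------------------------- featurize
    def tokenize_drug(self, smiles: str):
        return tokenize(smiles, self.drug_vocab, self.drug_merges, "drug")

    def tokenize_protein(self, sequence: str):
        return tokenize(sequence, self.protein_vocab, self.protein_merges, "protein")

    def featurize(self, pairs: list[DTIPair]):
        """Token-index arrays for a list of pairs; sequences are tokenized
        once per unique string."""
        d_cache: dict[str, object] = {}
        p_cache: dict[str, object] = {}
        d_seqs, p_seqs, labels = [], [], []
        td = self.net.drug_config.max_len
        tp = self.net.protein_config.max_len
        for pair in pairs:
            s = pair.drug.smiles
            if s not in d_cache:
                d_cache[s] = index_sequence(self.tokenize_drug(s), self.drug_vocab, td)
            a = pair.protein.sequence
            if a not in p_cache:
                p_cache[a] = index_sequence(
                    self.tokenize_protein(a), self.protein_vocab, tp
                )
            d_seqs.append(d_cache[s])
            p_seqs.append(p_cache[a])
            labels.append(pair.label)
        d_idx, d_mask = stack_indexed(d_seqs)
        p_idx, p_mask = stack_indexed(p_seqs)
        return d_idx, d_mask, p_idx, p_mask, np.asarray(labels, float)

    def predict_proba(self, pairs: list[DTIPair], batch_size: int = 64) -> np.ndarray:
        self.net.eval()
        d_idx, d_mask, p_idx, p_mask, _ = self.featurize(pairs)
        out = []
        for s in range(0, len(pairs), batch_size):
            sl = slice(s, s + batch_size)
            out.append(
                self.net(d_idx[sl], d_mask[sl], p_idx[sl], p_mask[sl]).data
            )
        return np.concatenate(out) if out else np.empty(0)

    # ---------------------------------------------------------- checkpoint
    def save(self, run_dir: str | Path) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        self.drug_merges.save(run_dir / "drug_merges.tsv")
        self.protein_merges.save(run_dir / "protein_merges.tsv")
        meta = {
            "drug_config": asdict(self.net.drug_config),
            "protein_config": asdict(self.net.protein_config),
            "head_config": asdict(self.net.head_config),
            "seed": self.seed,
            "drug_merges_sha256": _sha256(run_dir / "drug_merges.tsv"),
            "protein_merges_sha256": _sha256(run_dir / "protein_merges.tsv"),
        }
        (run_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        np.savez(run_dir / "weights.npz", **self.net.state_dict())

    @classmethod
    def load(cls, run_dir: str | Path) -> "DTIModel":
        run_dir = Path(run_dir)
        meta = json.loads((run_dir / "meta.json").read_text())
        for side in ("drug", "protein"):
            if _sha256(run_dir / f"{side}_merges.tsv") != meta[f"{side}_merges_sha256"]:
                raise ValueError(
                    f"{side} merge table does not match the checkpoint hash"
                )
        model = cls(
            MergeTable.load(run_dir / "drug_merges.tsv"),
            MergeTable.load(run_dir / "protein_merges.tsv"),
            EncoderConfig(**meta["drug_config"]),
            EncoderConfig(**meta["protein_config"]),
            HeadConfig(**meta["head_config"]),
            seed=meta["seed"],
        )
        with np.load(run_dir / "weights.npz") as state:
            model.net.load_state_dict(dict(state))
        return model


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
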
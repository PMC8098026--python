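"""scikit-learn style estimators.

``FCSTokenizer`` is a transformer: fit learns the merge hierarchy from a
corpus of strings, transform decomposes strings into sub-structure tokens.

``DTIClassifier`` is a binary classifier over (SMILES, protein sequence)
string pairs: fit mines both vocabularies from the training corpora, trains
the interaction network with an internal validation split for epoch
selection, and stores the best-F1 validation threshold used by ``predict``.
Defaults are the published full-scale settings; ``DTIClassifier.desk()``
gives the small profile used throughout the test suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .encoder import EncoderConfig
from .fcs import mine_fcs, tokenize
from .io import DrugRecord, DTIPair, ProteinRecord
from .metrics import select_threshold
from .model import DTIModel, HeadConfig
from .train import TrainConfig, fit
from .workflow import PROFILES

__all__ = ["FCSTokenizer", "DTIClassifier"]


class FCSTokenizer(TransformerMixin, BaseEstimator):
    """Frequent-consecutive-subsequence tokenizer (BPE-style over one corpus).

    Parameters
    ----------
    theta : minimum corpus frequency for a merge (default 500, the
        published full-scale value).
    max_vocab : vocabulary cap including reserved tokens; None = unbounded.
    """

    def __init__(self, theta: int = 500, max_vocab: int | None = None):
        self.theta = theta
        self.max_vocab = max_vocab

    def fit(self, X, y=None):
        corpus = [str(s) for s in X]
        self.vocabulary_, self.merge_table_ = mine_fcs(
            corpus, theta=self.theta, max_vocab=self.max_vocab
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[list[str]]:
        check_is_fitted(self, "merge_table_")
        return [
            tokenize(str(s), self.vocabulary_, self.merge_table_).tokens for s in X
        ]


def _as_pairs(X, y=None) -> list[DTIPair]:
    X = np.asarray(X, dtype=object)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be of shape (n_samples, 2): SMILES, protein sequence")
    labels = np.zeros(len(X), int) if y is None else np.asarray(y, int)
    drug_ids: dict[str, str] = {}
    prot_ids: dict[str, str] = {}
    pairs = []
    for (smiles, seq), label in zip(X, labels):
        smiles, seq = str(smiles), str(seq)
        did = drug_ids.setdefault(smiles, f"D{len(drug_ids) + 1}")
        pid = prot_ids.setdefault(seq, f"P{len(prot_ids) + 1}")
        pairs.append(
            DTIPair(
                drug=DrugRecord(id=did, smiles=smiles),
                protein=ProteinRecord(id=pid, sequence=seq),
                label=int(label),
            )
        )
    return pairs


class DTIClassifier(ClassifierMixin, BaseEstimator):
    """Drug-target interaction classifier over string pairs.

    X is array-like of shape (n_samples, 2) with columns (SMILES, protein
    sequence); y is binary.  See the module docstring for the fit protocol.
    """

    def __init__(
        self,
        theta_drug: int = 500,
        theta_protein: int = 500,
        max_vocab: int | None = None,
        embed_dim: int = 384,
        n_layers: int = 2,
        n_heads: int = 12,
        ffn_dim: int = 1536,
        dropout: float = 0.1,
        max_len_drug: int = 50,
        max_len_protein: int = 545,
        interaction_fn: str = "dot",
        variant: str = "full",
        cnn_filters: int = 3,
        kernel_size: int = 3,
        lr: float = 1e-5,
        batch_size: int = 64,
        max_epochs: int = 30,
        validation_fraction: float = 0.125,
        random_state: int = 0,
    ):
        self.theta_drug = theta_drug
        self.theta_protein = theta_protein
        self.max_vocab = max_vocab
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.dropout = dropout
        self.max_len_drug = max_len_drug
        self.max_len_protein = max_len_protein
        self.interaction_fn = interaction_fn
        self.variant = variant
        self.cnn_filters = cnn_filters
        self.kernel_size = kernel_size
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    @classmethod
    def desk(cls, **overrides) -> "DTIClassifier":
        """The small profile for synthetic, laptop-scale experiments."""
        d = PROFILES["desk"]
        params = dict(
            theta_drug=d["theta_drug"],
            theta_protein=d["theta_protein"],
            embed_dim=d["embed_dim"],
            n_layers=d["n_layers"],
            n_heads=d["n_heads"],
            ffn_dim=d["ffn_dim"],
            dropout=d["dropout"],
            max_len_drug=d["drug_max_len"],
            max_len_protein=d["protein_max_len"],
            lr=d["lr"],
            batch_size=d["batch_size"],
            max_epochs=d["max_epochs"],
        )
        params.update(overrides)
        return cls(**params)

    def fit(self, X, y):
        pairs = _as_pairs(X, y)
        labels = np.asarray([p.label for p in pairs])
        self.classes_ = np.unique(labels)
        if len(self.classes_) != 2:
            raise ValueError("DTIClassifier requires both classes in y")
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(pairs))
        n_val = max(1, int(round(self.validation_fraction * len(pairs))))
        val_pairs = [pairs[i] for i in order[:n_val]]
        train_pairs = [pairs[i] for i in order[n_val:]]
        if len({p.label for p in val_pairs}) < 2 or len({p.label for p in train_pairs}) < 2:
            raise ValueError(
                "internal validation split is single-class; shuffle the data "
                "or adjust validation_fraction"
            )
        _, drug_merges = mine_fcs(
            sorted({p.drug.smiles for p in pairs}),
            theta=self.theta_drug,
            max_vocab=self.max_vocab,
        )
        _, protein_merges = mine_fcs(
            sorted({p.protein.sequence for p in pairs}),
            theta=self.theta_protein,
            max_vocab=self.max_vocab,
        )
        enc = dict(
            embed_dim=self.embed_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            ffn_dim=self.ffn_dim,
            dropout=self.dropout,
        )
        self.model_ = DTIModel(
            drug_merges,
            protein_merges,
            EncoderConfig(vocab_size=2, max_len=self.max_len_drug, **enc),
            EncoderConfig(vocab_size=2, max_len=self.max_len_protein, **enc),
            HeadConfig(
                interaction_fn=self.interaction_fn,
                cnn_filters=self.cnn_filters,
                kernel_size=self.kernel_size,
                variant=self.variant,
            ),
            seed=self.random_state,
        )
        cfg = TrainConfig(
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )
        self.history_ = fit(self.model_, train_pairs, val_pairs, cfg)
        val_scores = self.model_.predict_proba(val_pairs)
        self.threshold_ = select_threshold(val_scores, [p.label for p in val_pairs])
        self.n_features_in_ = 2
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p = self.model_.predict_proba(_as_pairs(X))
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold_).astype(int)
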
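"""End-to-end profiles and pipelines.

Two named profiles bundle the architectural settings:

- ``paper``: the published full-scale configuration (embedding 384, two
  2-layer/12-head transformer encoders with intermediate dimension 1536,
  max lengths 50/545, mining threshold 500, Adam lr 1e-5).
- ``desk``: a small configuration for laptop-scale synthetic experiments
  (embedding 16, 1 layer, 4 heads, intermediate 64, max lengths 24/48,
  mining thresholds 30/20, Adam lr 1e-3).

``run_experiment`` is the one-call pipeline used by the CLI and the
acceptance machinery: generate-or-take a labeled pair set, split 7:1:2,
mine sub-structure vocabularies on the corpora, train with validation-based
selection, pick the best-F1 threshold on validation, and evaluate held-out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig
from .fcs import MergeTable, mine_fcs
from .io import DatasetSplit, DTIPair, split_dataset
from .metrics import EvalReport, select_threshold
from .model import DTIModel, HeadConfig
from .train import TrainConfig, evaluate, fit

__all__ = ["PROFILES", "build_model", "mine_for_pairs", "run_experiment"]

PROFILES: dict[str, dict] = {
    "paper": dict(
        embed_dim=384,
        n_layers=2,
        n_heads=12,
        ffn_dim=1536,
        dropout=0.1,
        drug_max_len=50,
        protein_max_len=545,
        theta_drug=500,
        theta_protein=500,
        lr=1e-5,
        batch_size=64,
        max_epochs=30,
    ),
    "desk": dict(
        embed_dim=16,
        n_layers=1,
        n_heads=4,
        ffn_dim=64,
        dropout=0.1,
        drug_max_len=24,
        protein_max_len=48,
        theta_drug=30,
        theta_protein=20,
        lr=1e-3,
        batch_size=64,
        max_epochs=30,
    ),
}


def _profile(profile: str | dict, **overrides) -> dict:
    cfg = dict(PROFILES[profile]) if isinstance(profile, str) else dict(profile)
    cfg.update(overrides)
    return cfg


def build_model(
    drug_merges: MergeTable,
    protein_merges: MergeTable,
    profile: str | dict = "desk",
    variant: str = "full",
    interaction_fn: str = "dot",
    seed: int = 0,
    **overrides,
) -> DTIModel:
    cfg = _profile(profile, **overrides)
    enc = dict(
        embed_dim=cfg["embed_dim"],
        n_layers=cfg["n_layers"],
        n_heads=cfg["n_heads"],
        ffn_dim=cfg["ffn_dim"],
        dropout=cfg["dropout"],
    )
    return DTIModel(
        drug_merges,
        protein_merges,
        EncoderConfig(vocab_size=2, max_len=cfg["drug_max_len"], **enc),
        EncoderConfig(vocab_size=2, max_len=cfg["protein_max_len"], **enc),
        HeadConfig(interaction_fn=interaction_fn, variant=variant),
        seed=seed,
    )


def mine_for_pairs(
    pairs: list[DTIPair], profile: str | dict = "desk", **overrides
) -> tuple[MergeTable, MergeTable]:
    """Mine drug and protein merge tables on the (unlabeled) corpora behind
    a pair set.  Separate vocabularies per side, never shared."""
    cfg = _profile(profile, **overrides)
    drug_corpus = sorted({p.drug.smiles for p in pairs})
    protein_corpus = sorted({p.protein.sequence for p in pairs})
    _, drug_merges = mine_fcs(drug_corpus, theta=cfg["theta_drug"])
    _, protein_merges = mine_fcs(protein_corpus, theta=cfg["theta_protein"])
    return drug_merges, protein_merges


@dataclass
class ExperimentResult:
    model: DTIModel
    split: DatasetSplit
    history: list[dict]
    threshold: float
    report: EvalReport


def run_experiment(
    pairs: list[DTIPair],
    profile: str | dict = "desk",
    variant: str = "full",
    seed: int = 0,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    mine_on: list[DTIPair] | None = None,
    **overrides,
) -> ExperimentResult:
    """Split, mine, train, select threshold on validation, evaluate on test.

    `mine_on` optionally supplies a larger unlabeled pool for vocabulary
    mining (by default the corpora behind `pairs` are used).
    """
    cfg = _profile(profile, **overrides)
    split = split_dataset(pairs, ratios=ratios, seed=seed)
    drug_merges, protein_merges = mine_for_pairs(mine_on or pairs, cfg)
    model = build_model(drug_merges, protein_merges, cfg, variant=variant, seed=seed)
    tcfg = TrainConfig(
        lr=cfg["lr"],
        batch_size=cfg["batch_size"],
        max_epochs=cfg["max_epochs"],
        seed=seed,
    )
    history = fit(model, split.train, split.validation, tcfg)
    val_scores = model.predict_proba(split.validation)
    threshold = select_threshold(val_scores, [p.label for p in split.validation])
    report = evaluate(model, split.test, threshold=threshold)
    return ExperimentResult(model, split, history, threshold, report)
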
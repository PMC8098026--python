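import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def char_merge_tables():
    """Empty merge tables (character-level tokenization) for tiny models."""
    from dtimap.fcs import MergeTable

    drug = MergeTable([], [], 1, None, list("ABCD"))
    protein = MergeTable([], [], 1, None, list("EFGH"))
    return drug, protein


@pytest.fixture
def tiny_model(char_merge_tables):
    """A small full-variant model (embed 8, 1 layer) on character tables."""
    from dtimap.workflow import build_model

    drug, protein = char_merge_tables
    return build_model(
        drug,
        protein,
        "desk",
        embed_dim=8,
        n_heads=2,
        ffn_dim=16,
        drug_max_len=6,
        protein_max_len=7,
        seed=3,
    )


def _learnability_run(seed: int, label_noise: float, variant: str):
    from dtimap.synthetic import SyntheticSpec, generate_dti
    from dtimap.workflow import run_experiment

    ds = generate_dti(SyntheticSpec(seed=seed, label_noise=label_noise))
    return run_experiment(ds.pairs, profile="desk", variant=variant, seed=seed)


@pytest.fixture(scope="session")
def learnability_runs():
    """Desk-profile training runs on the motif-rule fixture, shared by the
    learnability and ablation acceptance tests.  Keys: (seed, noise, variant)
    -> held-out ROC-AUC."""
    out = {}
    for seed in (0, 1, 2):
        out[(seed, 0.0, "full")] = _learnability_run(seed, 0.0, "full").report.roc_auc
        out[(seed, 0.1, "full")] = _learnability_run(seed, 0.1, "full").report.roc_auc
        out[(seed, 0.0, "no_interaction")] = _learnability_run(
            seed, 0.0, "no_interaction"
        ).report.roc_auc
    return out
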
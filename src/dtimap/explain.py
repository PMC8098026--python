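"""Interaction-map interpretability.

A high cell in the interaction map marks a drug sub-structure / protein
sub-structure pair the model treats as an activated interaction.  This
module extracts the labeled map for one pair (PAD rows/columns removed),
filters it by top-k or by an absolute threshold, and exports the result as
TSV (and optionally a heat-map PNG).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoder import index_sequence
from .model import DTIModel, InteractionMap

__all__ = ["ExplanationReport", "extract_map", "top_interactions", "write_report"]


@dataclass
class ExplanationEntry:
    drug_token: str
    drug_position: int
    protein_token: str
    protein_position: int
    intensity: float


@dataclass
class ExplanationReport:
    entries: list[ExplanationEntry]
    threshold: float | None
    k: int | None
    map_shape: tuple[int, int]


def extract_map(model: DTIModel, smiles: str, protein_sequence: str) -> InteractionMap:
    """Forward pass captured at the pairwise-interaction layer, with axes
    labeled by the sub-structure tokens; PAD positions are excluded."""
    model.net.eval()
    d_sub = model.tokenize_drug(smiles)
    p_sub = model.tokenize_protein(protein_sequence)
    td = model.net.drug_config.max_len
    tp = model.net.protein_config.max_len
    d_ix = index_sequence(d_sub, model.drug_vocab, td)
    p_ix = index_sequence(p_sub, model.protein_vocab, tp)
    contextual = model.net.head_config.variant in ("full", "no_cnn")
    I = model.net.interaction_map_batch(
        d_ix.indices[None], d_ix.mask[None], p_ix.indices[None], p_ix.mask[None],
        contextual=contextual,
    )[0]
    nd, np_ = d_ix.true_length, p_ix.true_length
    return InteractionMap(
        matrix=I[:nd, :np_],
        drug_tokens=d_sub.tokens[:nd],
        protein_tokens=p_sub.tokens[:np_],
    )


def top_interactions(
    imap: InteractionMap,
    threshold: float | None = None,
    k: int | None = None,
) -> ExplanationReport:
    """Entries above `threshold`, or the `k` most intense cells (exactly one
    selector must be given), sorted by intensity descending with ties broken
    by (drug position, protein position)."""
    if (threshold is None) == (k is None):
        raise ValueError("give exactly one of threshold= or k=")
    M = np.asarray(imap.matrix, float)
    nd, np_ = M.shape
    cells = [
        (float(M[i, j]), i, j) for i in range(nd) for j in range(np_)
    ]
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    if threshold is not None:
        cells = [c for c in cells if c[0] >= threshold]
    else:
        cells = cells[:k]
    entries = [
        ExplanationEntry(
            drug_token=imap.drug_tokens[i],
            drug_position=i,
            protein_token=imap.protein_tokens[j],
            protein_position=j,
            intensity=v,
        )
        for v, i, j in cells
    ]
    return ExplanationReport(
        entries=entries, threshold=threshold, k=k, map_shape=(nd, np_)
    )


def write_report(
    imap: InteractionMap,
    report: ExplanationReport,
    out_dir: str | Path,
    heatmap: bool = False,
) -> None:
    """Write the full labeled matrix (map.tsv), the filtered entries
    (entries.tsv) and, optionally, a heat-map PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "\t".join([""] + [
        f"{t}@{j}" for j, t in enumerate(imap.protein_tokens)
    ])
    lines = [header]
    for i, t in enumerate(imap.drug_tokens):
        row = "\t".join(f"{v:.6g}" for v in imap.matrix[i])
        lines.append(f"{t}@{i}\t{row}")
    (out_dir / "map.tsv").write_text("\n".join(lines) + "\n")
    ent = ["drug_token\tdrug_position\tprotein_token\tprotein_position\tintensity"]
    for e in report.entries:
        ent.append(
            f"{e.drug_token}\t{e.drug_position}\t{e.protein_token}\t"
            f"{e.protein_position}\t{e.intensity:.6g}"
        )
    (out_dir / "entries.tsv").write_text("\n".join(ent) + "\n")
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(imap.protein_tokens)),
                     max(3, 0.25 * len(imap.drug_tokens)))
        )
        im = ax.imshow(imap.matrix, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(imap.protein_tokens)))
        ax.set_xticklabels(imap.protein_tokens, rotation=90, fontsize=6)
        ax.set_yticks(range(len(imap.drug_tokens)))
        ax.set_yticklabels(imap.drug_tokens, fontsize=6)
        ax.set_xlabel("protein sub-structures")
        ax.set_ylabel("drug sub-structures")
        fig.colorbar(im, ax=ax, label="interaction intensity")
        fig.tight_layout()
        fig.savefig(out_dir / "heatmap.png", dpi=150)
        plt.close(fig)
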
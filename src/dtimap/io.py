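"""Readers/writers and dataset assembly for drug-target interaction corpora.

Formats: FASTA for proteins (via Biopython), one-SMILES-per-line (optionally
``smiles<TAB>id``) for drugs, and a tab-separated pair table
``drug_id  drug_smiles  protein_id  protein_sequence  label`` (a bare
three-column ``smiles  sequence  label`` form is also accepted).  A header
row is detected by a literal ``smiles`` token on the first line.

Dataset assembly covers the usual protocol for binary interaction data:
binarize dissociation constants (Kd < 30 positive), sample negatives
uniformly from unseen drug x protein pairs, and split 7:1:2 by a seeded
permutation.  All randomness flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("dtimap")

# 20 standard amino acids + B (Asx), Z (Glx), U (Sec); X is the unknown symbol
AMINO_ACID_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZU"
UNKNOWN_AA = "X"

__all__ = [
    "DrugRecord",
    "ProteinRecord",
    "DTIPair",
    "DatasetSplit",
    "FastaFormatError",
    "read_fasta",
    "read_smiles",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "binarize_affinity",
    "sample_negatives",
    "split_dataset",
    "AMINO_ACID_ALPHABET",
]


class FastaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class DrugRecord:
    id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles or any(c.isspace() for c in self.smiles):
            raise ValueError(f"drug {self.id!r}: SMILES must be non-empty, no whitespace")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass
class DTIPair:
    drug: DrugRecord
    protein: ProteinRecord
    label: int
    affinity: float | None = None

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug.id, self.protein.id)


@dataclass
class DatasetSplit:
    train: list[DTIPair]
    validation: list[DTIPair]
    test: list[DTIPair]
    seed: int
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)


# --------------------------------------------------------------------- readers
def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file; the header token before the first
    whitespace becomes the record id and sequences are uppercased."""
    path = Path(path)
    # pre-scan: sequence data before any header is a format error with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def read_smiles(path: str | Path) -> list[DrugRecord]:
    """Read one SMILES per line, optionally ``smiles<TAB>id``.  Blank interior
    lines are skipped with a warning; missing ids become ``D<line-number>``."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.warning("%s: line %d is blank, skipped", path, lineno)
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            drug_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"D{lineno}"
            records.append(DrugRecord(id=drug_id, smiles=smiles))
    return records


_PAIR_COLUMNS = ["drug_id", "drug_smiles", "protein_id", "protein_sequence", "label"]


def write_pairs_tsv(pairs: Sequence[DTIPair], path: str | Path, header: bool = False) -> None:
    df = pd.DataFrame(
        [
            (p.drug.id, p.drug.smiles, p.protein.id, p.protein.sequence, p.label)
            for p in pairs
        ],
        columns=_PAIR_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=header, index=False)


def read_pairs_tsv(
    path: str | Path, affinity_threshold: float = 30.0
) -> list[DTIPair]:
    """Read a labeled pair TSV.

    Accepts 5 columns (id, smiles, id, sequence, label) or 3 columns
    (smiles, sequence, label).  A real-valued final column is treated as an
    affinity (Kd) and binarized with `affinity_threshold`.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = "smiles" in first.lower()
    df = pd.read_csv(
        path, sep="\t", header=0 if has_header else None, dtype=str
    )
    if df.shape[1] == 5:
        df.columns = _PAIR_COLUMNS
    elif df.shape[1] == 3:
        df.columns = ["drug_smiles", "protein_sequence", "label"]
        df["drug_id"] = [f"D{i+1}" for i in range(len(df))]
        df["protein_id"] = [f"P{i+1}" for i in range(len(df))]
    else:
        raise ValueError(f"{path}: expected 3 or 5 tab-separated columns, got {df.shape[1]}")
    pairs = []
    for row in df.itertuples(index=False):
        raw = float(row.label)
        if raw in (0.0, 1.0):
            label, affinity = int(raw), None
        else:
            affinity = raw
            label = binarize_affinity(affinity, affinity_threshold)
        pairs.append(
            DTIPair(
                drug=DrugRecord(id=str(row.drug_id), smiles=str(row.drug_smiles)),
                protein=ProteinRecord(
                    id=str(row.protein_id), sequence=str(row.protein_sequence)
                ),
                label=label,
                affinity=affinity,
            )
        )
    return pairs


# ----------------------------------------------------------------- assembly
def binarize_affinity(affinity: float, threshold: float = 30.0) -> int:
    """Label a dissociation constant: Kd strictly below `threshold` is
    positive (1); the boundary value itself is negative (0)."""
    if not math.isfinite(affinity) or affinity < 0:
        raise ValueError(f"affinity must be finite and >= 0, got {affinity!r}")
    return 1 if affinity < threshold else 0


def sample_negatives(
    positives: Sequence[DTIPair],
    drugs: Sequence[DrugRecord],
    proteins: Sequence[ProteinRecord],
    ratio: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[DTIPair]:
    """Draw ``floor(ratio * len(positives))`` label-0 pairs uniformly without
    replacement from the drug x protein pairs absent from `positives`."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_needed = int(ratio * len(positives))
    positive_keys = {p.key for p in positives}
    n_d, n_p = len(drugs), len(proteins)
    unseen_flat = [
        i * n_p + j
        for i in range(n_d)
        for j in range(n_p)
        if (drugs[i].id, proteins[j].id) not in positive_keys
    ]
    if len(unseen_flat) < n_needed:
        raise ValueError(
            f"need {n_needed} unseen pairs but only {len(unseen_flat)} exist "
            f"(shortfall {n_needed - len(unseen_flat)})"
        )
    chosen = rng.choice(len(unseen_flat), size=n_needed, replace=False)
    out = []
    for c in sorted(int(x) for x in chosen):
        flat = unseen_flat[c]
        out.append(DTIPair(drug=drugs[flat // n_p], protein=proteins[flat % n_p], label=0))
    return out


def split_dataset(
    pairs: Sequence[DTIPair],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Permute by `seed` and slice contiguously into train/validation/test.

    Sizes follow the largest-remainder rule, so each part differs from its
    exact ratio share by less than one pair.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    exact = [r * n for r in ratios]
    sizes = [int(math.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    shuffled = [pairs[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(
        train=shuffled[:a],
        validation=shuffled[a:b],
        test=shuffled[b:],
        seed=seed,
        ratios=tuple(ratios),
    )
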
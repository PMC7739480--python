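"""The 56-dimensional peptide descriptor.

Two blocks, concatenated:

* 20 amino-acid composition fractions, count(r)/L, residues ordered
  alphabetically by one-letter code (A..Y);
* 36 reduced-alphabet dipeptide frequencies.  The 20 residues are mapped to
  six hydropathy groups; every ordered pair of adjacent residues (overlapping
  windows, L-1 of them) is translated to an ordered group pair and counted,
  then normalised by L-1.

Each block sums to 1 for every valid sequence, so the descriptor lives on a
product of two simplices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import AMINO_ACIDS, PeptideRecord

#: Six hydropathy groups covering the 20 canonical residues exactly once
#: (sizes 7, 6, 4, 1, 1, 1).  S/T/Y/W sit between the strong classes and are
#: kept as a single weakly-hydropathic group.
GROUP_NAMES = (
    "strongly_hydrophilic",
    "strongly_hydrophobic",
    "weakly_hydro",
    "proline",
    "glycine",
    "cysteine",
)
GROUP_RESIDUES = ("RDENQKH", "LIAVMF", "STYW", "P", "G", "C")
N_GROUPS = len(GROUP_RESIDUES)

RESIDUE_TO_GROUP: dict[str, int] = {
    res: g for g, members in enumerate(GROUP_RESIDUES) for res in members
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_COMPOSITION = 20
N_DIPEPTIDE = N_GROUPS * N_GROUPS  # 36
N_FEATURES = N_COMPOSITION + N_DIPEPTIDE  # 56


def residue_group(residue: str) -> int:
    """Hydropathy group index in 0..5 for a canonical residue letter."""
    try:
        return RESIDUE_TO_GROUP[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


def composition20(sequence: str) -> np.ndarray:
    """Amino-acid composition: entry for residue r is count(r) / L."""
    if len(sequence) < 1:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = np.zeros(N_COMPOSITION)
    for ch in sequence:
        try:
            counts[_AA_INDEX[ch]] += 1
        except KeyError:
            raise ValueError(f"unknown residue {ch!r} in sequence") from None
    return counts / len(sequence)


def reduced_dipeptide36(sequence: str) -> np.ndarray:
    """Reduced-alphabet dipeptide frequencies n_(g,h) / (L-1).

    The entry for ordered group pair (g, h) is the number of overlapping
    adjacent positions whose residues map to g then h, divided by L-1.
    Row-major pair order: index = 6*g + h with groups in ``GROUP_NAMES``
    order.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError(
            "dipeptide frequencies need L >= 2 (the normaliser is L-1)"
        )
    groups = [residue_group(ch) for ch in sequence]
    counts = np.zeros(N_DIPEPTIDE)
    for g, h in zip(groups[:-1], groups[1:]):
        counts[N_GROUPS * g + h] += 1
    return counts / (L - 1)


@dataclass(frozen=True)
class FeatureVector:
    """The 56-d descriptor of one peptide: 20-d composition + 36-d dipeptide."""

    composition: np.ndarray
    dipeptide: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.composition, self.dipeptide])


def featurize(record: PeptideRecord) -> FeatureVector:
    """Compute the full 56-d descriptor for one peptide record."""
    return FeatureVector(
        composition=composition20(record.sequence),
        dipeptide=reduced_dipeptide36(record.sequence),
    )


def featurize_batch(records: Sequence[PeptideRecord]) -> np.ndarray:
    """N x 56 feature matrix, rows in input order."""
    if not records:
        return np.empty((0, N_FEATURES))
    return np.vstack([featurize(r).combined for r in records])


def feature_names() -> list[str]:
    """Stable names for the 56 dimensions, for TSV headers and plots."""
    names = [f"comp_{aa}" for aa in AMINO_ACIDS]
    for g in GROUP_NAMES:
        for h in GROUP_NAMES:
            names.append(f"dipep_{g}__{h}")
    return names


def class_mean_composition(
    records: Iterable[PeptideRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean 20-d composition: (ACP mean, non-ACP mean).

    The classic exploratory view of an ACP dataset: which residues are
    enriched in actives versus inactives.
    """
    pos, neg = [], []
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label")
        (pos if r.label == 1 else neg).append(composition20(r.sequence))
    if not pos:
        raise ValueError("ACP (label=1) class is empty")
    if not neg:
        raise ValueError("non-ACP (label=0) class is empty")
    return np.mean(pos, axis=0), np.mean(neg, axis=0)


def plot_class_composition(records, ax=None):
    """Grouped bar chart of per-class mean composition (ACP vs non-ACP)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pos_mean, neg_mean = class_mean_composition(records)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    x = np.arange(N_COMPOSITION)
    ax.bar(x - 0.2, pos_mean, width=0.4, label="ACP", color="tab:blue")
    ax.bar(x + 0.2, neg_mean, width=0.4, label="non-ACP", color="tab:red")
    ax.set_xticks(x, list(AMINO_ACIDS))
    ax.set_xlabel("amino acid")
    ax.set_ylabel("mean fraction of sequence")
    ax.legend()
    return ax
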
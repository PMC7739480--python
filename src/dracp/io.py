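"""Peptide I/O and synthetic fixture generation.

Reads and writes peptide sequences in FASTA, attaches binary activity labels
(1 = anticancer peptide, 0 = non-ACP) from a second FASTA file or a
two-column TSV, and generates labeled synthetic peptide sets with a planted
compositional class signal so the full pipeline can be exercised offline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("dracp")

#: The 20 canonical residues, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL = frozenset(AMINO_ACIDS)
#: Ambiguity / non-standard codes that the feature math cannot handle.
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")


class PeptideParseError(ValueError):
    """Raised for malformed FASTA/TSV input, naming the offending record."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence with an optional binary activity label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideParseError("peptide record has an empty id")
        if len(self.sequence) < 2:
            raise PeptideParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} < 2 "
                "(dipeptide features divide by L-1)"
            )
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise PeptideParseError(
                f"record {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def with_label(self, label: int) -> "PeptideRecord":
        return PeptideRecord(self.id, self.sequence, label)


def read_fasta(path: str | Path, ambiguous: str = "reject") -> list[PeptideRecord]:
    """Read peptides from a FASTA file, in file order, uppercased.

    Parameters
    ----------
    path:
        FASTA file with one entry per peptide.
    ambiguous:
        Policy for sequences containing ambiguity codes (B,J,O,U,X,Z) or any
        other non-canonical letter: ``"reject"`` (default) raises naming the
        record; ``"drop-record"`` skips the record with a warning.
    """
    if ambiguous not in ("reject", "drop-record"):
        raise ValueError(f"unknown ambiguous-residue policy {ambiguous!r}")
    path = Path(path)
    records: list[PeptideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().strip("*")
        rid = entry.id
        if not rid:
            raise PeptideParseError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise PeptideParseError(f"{path}: record {rid!r} has an empty sequence")
        bad = set(seq) - _CANONICAL
        if bad:
            if ambiguous == "drop-record":
                warnings.warn(
                    f"{path}: dropping record {rid!r} with non-canonical "
                    f"residue(s) {sorted(bad)}",
                    stacklevel=2,
                )
                continue
            raise PeptideParseError(
                f"{path}: record {rid!r} contains non-canonical residue(s) "
                f"{sorted(bad)}"
            )
        records.append(PeptideRecord(rid, seq))
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records to FASTA (inverse of :func:`read_fasta`)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (id, label in {0,1}) into a dict."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PeptideParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        rid, lab = parts
        if lab not in ("0", "1"):
            raise PeptideParseError(f"{path}:{lineno}: label for {rid!r} must be 0 or 1")
        if rid in labels:
            raise PeptideParseError(f"{path}:{lineno}: duplicate id {rid!r}")
        labels[rid] = int(lab)
    return labels


def write_labels(records: Iterable[PeptideRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label to write")
        lines.append(f"{r.id}\t{r.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def attach_labels(
    records: Sequence[PeptideRecord], labels: dict[str, int]
) -> list[PeptideRecord]:
    """Attach labels from a TSV mapping; every record must be covered."""
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise PeptideParseError(f"no label for record(s): {missing[:5]}")
    return [r.with_label(labels[r.id]) for r in records]


def load_labeled(
    pos_path: str | Path, neg_path: str | Path, ambiguous: str = "reject"
) -> list[PeptideRecord]:
    """Load positives (label 1) then negatives (label 0) from two FASTA files.

    Mirrors how ACP benchmark sets are distributed: one file of experimentally
    verified ACPs and one of presumed-inactive peptides.
    """
    pos = [r.with_label(1) for r in read_fasta(pos_path, ambiguous)]
    neg = [r.with_label(0) for r in read_fasta(neg_path, ambiguous)]
    dup = sorted({r.id for r in pos} & {r.id for r in neg})
    if dup:
        raise PeptideParseError(f"duplicate id(s) across positive/negative files: {dup}")
    if not neg:
        logger.warning("negative file %s is empty; all labels are 1", neg_path)
    if not pos:
        logger.warning("positive file %s is empty; all labels are 0", pos_path)
    return pos + neg


# --- synthetic fixtures ----------------------------------------------------

#: Default class-conditional hydropathy-group sampling weights.  Positives
#: emulate the amphipathic / cysteine-stabilised character of anticancer
#: peptides (hydrophobic- and Cys-enriched); negatives emulate generic
#: soluble peptides (hydrophilic-enriched).  Order follows the six-group
#: reduced alphabet in :mod:`dracp.features`.
DEFAULT_POS_WEIGHTS = (0.15, 0.45, 0.15, 0.05, 0.05, 0.15)
DEFAULT_NEG_WEIGHTS = (0.40, 0.20, 0.25, 0.05, 0.05, 0.05)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic labeled-peptide generator.

    Each residue is drawn by first sampling a hydropathy group from the
    class's 6-vector of group weights, then sampling a residue uniformly
    within that group, planting a class signal exactly in the feature space
    the classifier uses.
    """

    n_pos: int = 150
    n_neg: int = 150
    length_range: tuple[int, int] = (12, 50)
    pos_group_weights: tuple[float, ...] = DEFAULT_POS_WEIGHTS
    neg_group_weights: tuple[float, ...] = DEFAULT_NEG_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be non-negative")
        lo, hi = self.length_range
        if not (2 <= lo <= hi <= 1000):
            raise ValueError("length_range must satisfy 2 <= lo <= hi <= 1000")
        for name, w in (
            ("pos_group_weights", self.pos_group_weights),
            ("neg_group_weights", self.neg_group_weights),
        ):
            w = np.asarray(w, dtype=float)
            if w.shape != (6,):
                raise ValueError(f"{name} must have exactly 6 entries")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be non-negative and sum to 1")


def generate_synthetic(spec: SyntheticSpec) -> list[PeptideRecord]:
    """Generate ``n_pos + n_neg`` labeled peptides, positives first.

    Reproducible given ``spec.seed``; lengths uniform on ``length_range``.
    """
    from .features import GROUP_RESIDUES  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[PeptideRecord] = []
    for label, count, weights, tag in (
        (1, spec.n_pos, spec.pos_group_weights, "acp"),
        (0, spec.n_neg, spec.neg_group_weights, "neg"),
    ):
        weights = np.asarray(weights, dtype=float)
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            groups = rng.choice(6, size=length, p=weights)
            seq = "".join(
                GROUP_RESIDUES[g][rng.integers(len(GROUP_RESIDUES[g]))]
                for g in groups
            )
            records.append(PeptideRecord(f"{tag}_{i + 1:04d}", seq, label))
    return records
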
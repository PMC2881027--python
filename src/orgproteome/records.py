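"""Core record types and the residue alphabet shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

#: The 20 standard residues, alphabetically ordered. Every sequence handled by
#: this package is validated against this alphabet.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Truth labels used by the synthetic generator and partition-recovery tests:
#: organellar-soluble (A), cell-envelope-soluble (P), membrane (TM), cytoplasmic (CYT).
TRUTH_LABELS = ("A", "P", "TM", "CYT")


def validate_sequence(seq: str, name: str = "sequence") -> str:
    """Validate that *seq* is a nonempty string over the 20-letter alphabet.

    Returns the uppercased sequence; raises ``ValueError`` naming the first
    offending symbol otherwise.
    """
    if not isinstance(seq, str) or not seq:
        raise ValueError(f"{name} must be a nonempty residue string")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _AA_SET:
            raise ValueError(
                f"{name} contains non-standard residue {ch!r} at position {i + 1}"
            )
    return seq


@dataclass
class ProteinRecord:
    """A protein sequence with optional ground-truth annotation.

    Parameters
    ----------
    id : str
        Unique identifier.
    sequence : str
        Residue string over the 20 standard amino acids.
    truth_label : str, optional
        One of ``A``, ``P``, ``TM``, ``CYT`` for synthetic records.
    sp_truth : int, optional
        1-based cleavage index ``k``; the signal peptide spans residues
        ``1..k`` and the mature protein ``k+1..end``.
    """

    id: str
    sequence: str
    truth_label: Optional[str] = None
    sp_truth: Optional[int] = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, name=f"record {self.id!r}")
        if self.truth_label is not None and self.truth_label not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {self.truth_label!r}")
        if self.sp_truth is not None:
            if not (1 <= self.sp_truth < len(self.sequence)):
                raise ValueError(
                    f"record {self.id!r}: cleavage index {self.sp_truth} must lie "
                    f"strictly inside the sequence (length {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def signal_peptide(self) -> Optional[str]:
        if self.sp_truth is None:
            return None
        return self.sequence[: self.sp_truth]

    @property
    def mature(self) -> str:
        """Mature sequence (the whole sequence when no cleavage index is set)."""
        if self.sp_truth is None:
            return self.sequence
        return self.sequence[self.sp_truth:]


def hydropathy(seq: str) -> list[float]:
    """Per-residue Kyte-Doolittle hydropathy values."""
    return [KYTE_DOOLITTLE[ch] for ch in seq]
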
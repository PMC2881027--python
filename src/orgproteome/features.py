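"""Composition features and physicochemical indices.

The classifier's input space is the frequency of single residues (order 1,
20 features) or of two adjacent residues (order 2, 400 features), where a
frequency is the raw count divided by the full sequence length. Two exclusion
variants reflect the concern that heme c attachment (the CxxCH motif) could
dominate the signal of cytochrome-rich training sets: ``drop_CH`` removes every
feature involving C or H from the feature space, and ``mask_CxxCH`` zeroes the
residues inside CxxCH motif occurrences before counting.

Physicochemical descriptors (GRAVY, aliphatic index, residue-class
prevalences) quantify the hydropathy/aliphaticity contrast between the
organellar and cell-envelope classes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.base import BaseEstimator, TransformerMixin

from .records import AMINO_ACIDS, KYTE_DOOLITTLE, ProteinRecord, validate_sequence

REGIONS = ("full", "sp", "mature")
EXCLUSION_MODES = ("none", "drop_CH", "mask_CxxCH")

#: Residue classes used in the physicochemical comparison of the two
#: soluble classes (hydrophobic, aromatic, small, polar, charged groupings).
RESIDUE_CLASSES: tuple[str, ...] = (
    "ILV", "FWY", "AILVMFWYC", "AGS", "ST", "GNP", "DE", "DN", "KR", "EQ",
    "DENQ", "HKR", "DENQHKR", "DENQHKRST",
)

_CXXCH = re.compile(r"(?=(C..CH))")


def feature_names(order: int, exclusion_mode: str = "none") -> List[str]:
    """Ordered feature names for a composition vector.

    Order 1 yields the 20 residues (18 under ``drop_CH``); order 2 yields the
    400 ordered residue pairs (324 under ``drop_CH``).
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order!r}")
    if exclusion_mode not in EXCLUSION_MODES:
        raise ValueError(f"unknown exclusion_mode {exclusion_mode!r}")
    alphabet = AMINO_ACIDS
    if exclusion_mode == "drop_CH":
        alphabet = "".join(a for a in AMINO_ACIDS if a not in "CH")
    if order == 1:
        return list(alphabet)
    return ["".join(p) for p in itertools.product(alphabet, repeat=2)]


@dataclass
class CompositionVector:
    """Named monomer/dimer frequencies with region and exclusion metadata."""

    region: str
    order: int
    exclusion_mode: str
    values: Dict[str, float]

    def as_array(self) -> np.ndarray:
        names = feature_names(self.order, self.exclusion_mode)
        return np.array([self.values[n] for n in names], dtype=float)


def _masked_positions(seq: str) -> set[int]:
    """0-based positions covered by any CxxCH motif occurrence."""
    masked: set[int] = set()
    for m in _CXXCH.finditer(seq):
        masked.update(range(m.start(), m.start() + 5))
    return masked


def composition(
    seq: str,
    order: int = 2,
    exclusion_mode: str = "none",
    region: str = "full",
) -> CompositionVector:
    """Monomer (order 1) or adjacent-pair (order 2) frequency vector.

    Frequencies are counts divided by the full sequence length ``L`` in every
    mode, so an order-1 vector without exclusion sums to 1 and an order-2
    vector sums to ``(L - 1) / L``.

    Raises
    ------
    ValueError
        If the sequence is shorter than *order* or contains a non-standard
        residue (the offending symbol is named).
    """
    seq = validate_sequence(seq)
    names = feature_names(order, exclusion_mode)
    if len(seq) < order:
        raise ValueError(
            f"sequence of length {len(seq)} is too short for order-{order} features"
        )
    counts: Dict[str, float] = {n: 0.0 for n in names}
    masked = _masked_positions(seq) if exclusion_mode == "mask_CxxCH" else set()
    L = len(seq)
    if order == 1:
        for i, ch in enumerate(seq):
            if i in masked:
                continue
            if ch in counts:
                counts[ch] += 1.0
    else:
        for i in range(L - 1):
            if i in masked or (i + 1) in masked:
                continue
            pair = seq[i : i + 2]
            if pair in counts:
                counts[pair] += 1.0
    values = {n: c / L for n, c in counts.items()}
    return CompositionVector(region=region, order=order, exclusion_mode=exclusion_mode, values=values)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value over the sequence."""
    seq = validate_sequence(seq)
    return float(np.mean([KYTE_DOOLITTLE[c] for c in seq]))


def aliphatic_index(seq: str) -> float:
    """Aliphatic index after Ikai: X(A) + 2.9 X(V) + 3.9 (X(I) + X(L)).

    ``X`` is the mole percent of the residue; the index gauges the relative
    volume occupied by aliphatic side chains and ranges from 0 to 390.
    """
    seq = validate_sequence(seq)
    L = len(seq)
    x = {a: 100.0 * seq.count(a) / L for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def class_prevalences(seq: str) -> Dict[str, float]:
    """Fraction of the sequence falling in each of the 14 residue classes."""
    seq = validate_sequence(seq)
    L = len(seq)
    return {
        cls: sum(seq.count(a) for a in cls) / L
        for cls in RESIDUE_CLASSES
    }


@dataclass
class PhyschemProfile:
    gravy: float
    aliphatic_index: float
    class_prevalences: Dict[str, float]


def physchem_profile(seq: str) -> PhyschemProfile:
    return PhyschemProfile(
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        class_prevalences=class_prevalences(seq),
    )


# ---------------------------------------------------------------------------
# redundancy filtering


def _make_aligner() -> Align.PairwiseAligner:
    # match=1, mismatch=0, gap=-1 global alignment; identity = matches / columns
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches divided by alignment columns."""
    aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    matches = alignment.counts().identities
    return matches / alignment.length


def redundancy_filter(
    records: Sequence[ProteinRecord], identity_threshold: float = 0.85
) -> List[ProteinRecord]:
    """Remove redundant sequences above a pairwise-identity threshold.

    While any pair exceeds the threshold the shorter member is removed (on
    equal length, the later one in input order), scanning pairs in input
    order; the result is deterministic for a given input order.
    """
    if not records:
        raise ValueError("redundancy_filter requires at least one record")
    kept = list(records)
    while True:
        removed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                ident = pairwise_identity(kept[i].sequence, kept[j].sequence)
                if ident > identity_threshold:
                    if len(kept[i].sequence) < len(kept[j].sequence):
                        victim = i
                    else:
                        victim = j  # equal length -> drop the later record
                    del kept[victim]
                    removed = True
                    break
            if removed:
                break
        if not removed:
            return kept


# ---------------------------------------------------------------------------
# sklearn transformer


class CompositionVectorizer(TransformerMixin, BaseEstimator):
    """Turn protein records into a composition feature matrix.

    A stateless scikit-learn transformer: ``transform`` maps a sequence
    collection to an ``(n_samples, n_features)`` array of residue or
    residue-pair frequencies.

    Parameters
    ----------
    region : {"full", "sp", "mature"}
        Which part of each protein to featurize. ``sp`` and ``mature``
        require records carrying a cleavage index.
    order : {1, 2}
        Single-residue or adjacent-pair frequencies.
    exclusion_mode : {"none", "drop_CH", "mask_CxxCH"}
        Feature-space / counting variant, see :func:`composition`.
    """

    def __init__(self, region: str = "full", order: int = 2, exclusion_mode: str = "none"):
        self.region = region
        self.order = order
        self.exclusion_mode = exclusion_mode

    def _check_params(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order!r}")
        if self.exclusion_mode not in EXCLUSION_MODES:
            raise ValueError(f"unknown exclusion_mode {self.exclusion_mode!r}")

    def _extract(self, item: Union[ProteinRecord, str]) -> str:
        if isinstance(item, str):
            if self.region != "full":
                raise ValueError(
                    f"region {self.region!r} requires ProteinRecord inputs with a cleavage index"
                )
            return item
        if self.region == "full":
            return item.sequence
        if item.sp_truth is None:
            raise ValueError(
                f"record {item.id!r} has no cleavage index; region {self.region!r} unavailable"
            )
        return item.signal_peptide if self.region == "sp" else item.mature

    def fit(self, X: Iterable[Union[ProteinRecord, str]], y=None) -> "CompositionVectorizer":
        self._check_params()
        self.feature_names_ = feature_names(self.order, self.exclusion_mode)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[Union[ProteinRecord, str]]) -> np.ndarray:
        self._check_params()
        names = feature_names(self.order, self.exclusion_mode)
        rows = []
        for item in X:
            seq = self._extract(item)
            vec = composition(seq, order=self.order, exclusion_mode=self.exclusion_mode,
                              region=self.region)
            rows.append([vec.values[n] for n in names])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self.order, self.exclusion_mode), dtype=object)

    def to_frame(self, records: Sequence[ProteinRecord]) -> pd.DataFrame:
        """Feature matrix as a DataFrame indexed by record id."""
        mat = self.transform(records)
        return pd.DataFrame(mat, index=[r.id for r in records],
                            columns=feature_names(self.order, self.exclusion_mode))
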
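"""Signal-peptide analysis: predictor vote combination, n/h/c architecture
parsing, anchored segmental alignments, and surrogate Tat/TMH scanners.

External signal-peptide predictors are never executed here; their calls are
ingested as a tabular vote file and combined by strict majority. The n/h/c
delineation replaces an expert's manual call with an explicit hydropathy-
window heuristic so that results are reproducible: the h-region is the
mean-hydropathy-maximal window (length >= 6, mean Kyte-Doolittle >= 1.0)
within the signal peptide, ties resolved toward longer then leftmost windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, KYTE_DOOLITTLE, validate_sequence

VOTE_COLUMNS = ["protein_id", "predictor", "call", "cleavage_pos"]

H_REGION_MIN_LEN = 6
H_REGION_MIN_MEAN_KD = 1.0
TMH_MIN_LEN = 18
TMH_MAX_LEN = 25
TMH_MIN_MEAN_KD = 1.6
TAT_POLAR = set("STGNQDE")

ANCHORS = ("n_terminus", "h_start", "c_start", "cleavage_site")
GAP = "-"


class NoHRegionError(ValueError):
    """No window inside the signal peptide meets the hydropathy floor."""


@dataclass
class SignalPeptideAnnotation:
    """n/h/c partition of a signal peptide spanning residues 1..k.

    Regions are half-open 1-based intervals ``(start, stop)``; ``n`` may be
    empty, ``h`` is never empty, ``c`` ends at the cleavage index ``k``.
    The annotated sequence is retained so segment strings can be sliced.
    """

    sequence: str
    k: int
    n: Tuple[int, int]
    h: Tuple[int, int]
    c: Tuple[int, int]

    def _slice(self, iv: Tuple[int, int]) -> str:
        return self.sequence[iv[0] - 1 : iv[1] - 1]

    @property
    def n_region(self) -> str:
        return self._slice(self.n)

    @property
    def h_region(self) -> str:
        return self._slice(self.h)

    @property
    def c_region(self) -> str:
        return self._slice(self.c)

    @property
    def signal_peptide(self) -> str:
        return self.sequence[: self.k]


def majority_vote(table: pd.DataFrame, n_predictors: int) -> Dict[str, bool]:
    """Combine per-predictor boolean calls into a strict-majority decision.

    A protein is positive iff its positive calls exceed ``n_predictors / 2``
    (missing rows count as negative votes); even-count ties are negative.
    """
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    _check_vote_table(table)
    positives = (
        table[table["call"].astype(int) == 1].groupby("protein_id").size()
    )
    out: Dict[str, bool] = {}
    for pid in table["protein_id"].unique():
        out[pid] = int(positives.get(pid, 0)) > n_predictors / 2
    return out


def consensus_cleavage(table: pd.DataFrame) -> Dict[str, int]:
    """Median (rounded down) of cleavage positions among positive callers."""
    _check_vote_table(table)
    pos = table[(table["call"].astype(int) == 1) & (table["cleavage_pos"] != "")]
    out: Dict[str, int] = {}
    for pid, grp in pos.groupby("protein_id"):
        vals = [int(v) for v in grp["cleavage_pos"] if not pd.isna(v)]
        if vals:
            out[pid] = int(np.floor(np.median(vals)))
    return out


def _check_vote_table(table: pd.DataFrame) -> None:
    missing = [c for c in VOTE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"vote table missing required columns {missing}")
    dup = table.duplicated(subset=["protein_id", "predictor"])
    if dup.any():
        raise ValueError("vote table has duplicate (protein_id, predictor) rows")


def parse_regions(seq: str, k: int) -> SignalPeptideAnnotation:
    """Partition a signal peptide (residues 1..k) into n/h/c regions.

    The h-region is the window of length >= 6 within ``1..k`` maximising mean
    Kyte-Doolittle hydropathy, required to reach mean >= 1.0 (ties: longer,
    then leftmost). n is everything before it, c everything after up to ``k``.
    """
    seq = validate_sequence(seq)
    if not (4 <= k <= min(len(seq), 50)):
        raise ValueError(f"cleavage index {k} outside the valid range 4..min(len, 50)")
    # hydropathy scale values are multiples of 0.1: use scaled-integer sums and
    # exact rational comparison so tied window means break by length, not by
    # floating-point noise
    kd10 = [round(KYTE_DOOLITTLE[c] * 10) for c in seq[:k]]
    prefix = [0]
    for v in kd10:
        prefix.append(prefix[-1] + v)
    best: Optional[Tuple[Fraction, int, int]] = None  # (mean, length, -start)
    best_iv: Optional[Tuple[int, int]] = None
    for length in range(H_REGION_MIN_LEN, k + 1):
        for start in range(0, k - length + 1):
            mean = Fraction(prefix[start + length] - prefix[start], length)
            if mean < 10 * H_REGION_MIN_MEAN_KD:
                continue
            key = (mean, length, -start)
            if best is None or key > best:
                best = key
                best_iv = (start + 1, start + length + 1)
    if best_iv is None:
        raise NoHRegionError(
            f"no window of length >= {H_REGION_MIN_LEN} with mean hydropathy "
            f">= {H_REGION_MIN_MEAN_KD} within residues 1..{k}"
        )
    h_start, h_stop = best_iv
    return SignalPeptideAnnotation(
        sequence=seq, k=k, n=(1, h_start), h=(h_start, h_stop), c=(h_stop, k + 1)
    )


@dataclass
class SegmentalAlignment:
    """Ungapped per-segment alignment relative to one architectural anchor."""

    anchor: str
    rows: List[str]
    col_coords: List[int]

    @property
    def width(self) -> int:
        return len(self.col_coords)


def _segment_bounds(ann: SignalPeptideAnnotation) -> Dict[str, Tuple[int, int]]:
    """Half-open 1-based segment intervals whose concatenation is the SP.

    The cleavage-site segment is the final three residues (the -3..-1 motif
    window); the other three regions are truncated at its start so the four
    segments tile residues 1..k exactly.
    """
    tail_len = min(3, ann.k)
    cut = ann.k - tail_len + 1  # first residue of the cleavage-site segment
    clip = lambda iv: (min(iv[0], cut), min(iv[1], cut))
    return {
        "n_terminus": clip(ann.n),
        "h_start": clip(ann.h),
        "c_start": clip(ann.c),
        "cleavage_site": (cut, ann.k + 1),
    }


def segmental_align(
    annotations: Sequence[SignalPeptideAnnotation], anchor: str
) -> SegmentalAlignment:
    """Ungapped alignment of one architectural segment across signal peptides.

    Segments anchored at the N-terminus, h-region start and c-region start are
    left-justified (gap sentinel pads ragged right ends, columns 0, 1, ...);
    the cleavage-site segment is right-justified ending at the cleavage index
    (columns ..., -3, -2, -1). Joining the four alignments row-wise, gaps
    removed, reproduces each input signal peptide exactly.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}")
    if not annotations:
        raise ValueError("segmental_align requires at least one annotation")
    segments = [ann._slice(_segment_bounds(ann)[anchor]) for ann in annotations]
    width = max(len(s) for s in segments)
    if anchor == "cleavage_site":
        rows = [GAP * (width - len(s)) + s for s in segments]
        coords = list(range(-width, 0))
    else:
        rows = [s + GAP * (width - len(s)) for s in segments]
        coords = list(range(width))
    return SegmentalAlignment(anchor=anchor, rows=rows, col_coords=coords)


def join_alignments(alignments: Sequence[SegmentalAlignment]) -> List[str]:
    """Row-wise join of the four segmental alignments with gaps removed."""
    joined = []
    for row_parts in zip(*[a.rows for a in alignments]):
        joined.append("".join(row_parts).replace(GAP, ""))
    return joined


def position_frequency_matrix(alignment: SegmentalAlignment) -> pd.DataFrame:
    """Per-column residue fractions (gap-excluded denominator).

    Rows are the 20 residues, columns the anchor-relative coordinates; each
    column with at least one residue sums to 1.
    """
    if not alignment.rows:
        raise ValueError("empty alignment")
    data = np.zeros((20, alignment.width))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for row in alignment.rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                data[aa_index[ch], j] += 1.0
    totals = data.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, data / totals, 0.0)
    return pd.DataFrame(freq, index=list(AMINO_ACIDS), columns=alignment.col_coords)


def h_region_phe_count(annotations: Iterable[SignalPeptideAnnotation]) -> float:
    """Mean number of phenylalanine residues per h-region."""
    counts = [ann.h_region.count("F") for ann in annotations]
    if not counts:
        raise ValueError("no annotations given")
    return float(np.mean(counts))


def tat_scan(seq: str) -> bool:
    """Surrogate twin-arginine (Tat) motif scan.

    Positive iff an RR pair starts at positions 2..35, the residue preceding
    it is polar (S/T/G/N/Q/D/E), and a hydrophobic stretch (>= 10 residues,
    mean Kyte-Doolittle >= 1.0) begins within 6 residues downstream of the
    pair. A simplified stand-in for dedicated Tat predictors.
    """
    seq = validate_sequence(seq)
    kd = [KYTE_DOOLITTLE[c] for c in seq]
    prefix = np.concatenate([[0.0], np.cumsum(kd)])
    L = len(seq)
    for i in range(2, min(35, L - 1) + 1):  # 1-based start of the first R
        if seq[i - 1 : i + 1] != "RR":
            continue
        if seq[i - 2] not in TAT_POLAR:
            continue
        for start in range(i + 2, min(i + 7, L) + 1):  # 1-based window start
            max_len = L - start + 1
            for length in range(10, min(max_len, 40) + 1):
                s0 = start - 1
                if (prefix[s0 + length] - prefix[s0]) / length >= 1.0:
                    return True
    return False


def tmh_scan(seq: str) -> List[Tuple[int, int]]:
    """Surrogate transmembrane-helix scan.

    Greedy left-to-right detection of non-overlapping hydrophobic windows:
    at the leftmost start admitting any window of 18-25 residues with mean
    Kyte-Doolittle hydropathy >= 1.6, the longest such window is taken and
    scanning resumes after it. Returns 1-based inclusive intervals.
    """
    seq = validate_sequence(seq)
    kd = [KYTE_DOOLITTLE[c] for c in seq]
    prefix = np.concatenate([[0.0], np.cumsum(kd)])
    L = len(seq)
    intervals: List[Tuple[int, int]] = []
    s = 0  # 0-based candidate start
    while s + TMH_MIN_LEN <= L:
        best_len = 0
        for length in range(TMH_MIN_LEN, min(TMH_MAX_LEN, L - s) + 1):
            if (prefix[s + length] - prefix[s]) / length >= TMH_MIN_MEAN_KD:
                best_len = length
        if best_len:
            intervals.append((s + 1, s + best_len))
            s += best_len
        else:
            s += 1
    return intervals
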
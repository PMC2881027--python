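"""In-silico tryptic digestion and cleavage-site validation.

A predicted signal-peptide cleavage site is treated as experimentally
confirmed when the peptide evidence satisfies three criteria: the protein was
identified with at least three peptides; an observed peptide starts exactly
at the first mature residue and is semi-tryptic on its N-side; and that
peptide is the first detectable one, i.e. no fully tryptic peptide upstream
of it falls inside the mass spectrometer's detectability window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from pyteomics import mass as _ptmass

from .records import validate_sequence

#: Default peptide monoisotopic-mass detectability window in Daltons.
DEFAULT_MASS_RANGE: Tuple[float, float] = (600.0, 4000.0)

#: Cleavage sites beyond this bound are not considered plausible signal
#: peptides (configurable; mirrors an N-terminal search depth of 50 residues).
MAX_CLEAVAGE_INDEX = 50


def monoisotopic_mass(peptide: str) -> float:
    """Neutral monoisotopic peptide mass in Da (residues + one water)."""
    return float(_ptmass.fast_mass(validate_sequence(peptide)))


@dataclass
class DigestPeptide:
    parent_id: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    sequence: str
    tryptic_status: str  # fully_tryptic / semi_N / semi_C
    mass: float


def _cut_sites(seq: str) -> List[int]:
    """1-based positions i such that trypsin cuts after residue i
    (C-terminal to K/R unless followed by proline)."""
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]


def tryptic_digest(
    seq: str, missed_cleavages: int = 0, parent_id: str = ""
) -> List[DigestPeptide]:
    """Fully tryptic fragments of *seq*, including merged fragments with up
    to *missed_cleavages* internal missed cuts.

    At zero missed cleavages the fragments tile the input exactly.
    """
    seq = validate_sequence(seq)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = [0] + _cut_sites(seq) + [len(seq)]
    peptides: List[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 1 + missed_cleavages + 1, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            frag = seq[start - 1 : end]
            peptides.append(
                DigestPeptide(
                    parent_id=parent_id, start=start, end=end, sequence=frag,
                    tryptic_status="fully_tryptic", mass=monoisotopic_mass(frag),
                )
            )
    return peptides


def is_semi_tryptic_n_side(protein: str, start: int) -> bool:
    """True when a peptide starting at *start* (1-based) does not conform to
    trypsin specificity on its N-side: the preceding residue is not K/R, or
    it is K/R immediately followed by proline (no cut there either way a
    tryptic digest could not have produced this N-terminus)."""
    if start <= 1:
        return False  # protein N-terminus is a valid tryptic boundary
    prev = protein[start - 2]
    return not (prev in "KR" and protein[start - 1] != "P")


@dataclass
class CleavageVerdict:
    """Per-criterion outcome of the three-rule cleavage-site validation."""

    protein_id: str
    k: int
    enough_peptides: bool        # >= min_peptides observed for the protein
    semi_tryptic_at_site: bool   # observed peptide starts at k+1, semi-N
    first_detectable: bool       # nothing detectable wholly upstream
    confirmed: bool
    n_observed: int
    supporting_peptide: Optional[str] = None


def validate_cleavage(
    protein: str,
    k: int,
    observed_peptides: Sequence[Tuple[str, int]],
    min_peptides: int = 3,
    mass_range: Tuple[float, float] = DEFAULT_MASS_RANGE,
    max_cleavage_index: int = MAX_CLEAVAGE_INDEX,
    protein_id: str = "",
) -> CleavageVerdict:
    """Apply the three acceptance criteria to a predicted cleavage index.

    ``observed_peptides`` are ``(sequence, start)`` pairs with 1-based start
    coordinates; each must match the protein substring at its stated position.
    """
    protein = validate_sequence(protein)
    if not (1 <= k <= min(len(protein) - 1, max_cleavage_index)):
        raise ValueError(
            f"cleavage index {k} outside 1..min(len-1, {max_cleavage_index})"
        )
    for pep, start in observed_peptides:
        pep = validate_sequence(pep)
        if protein[start - 1 : start - 1 + len(pep)] != pep:
            raise ValueError(
                f"observed peptide {pep!r} does not match protein at position {start}"
            )

    enough = len(observed_peptides) >= min_peptides

    site_peptides = [
        (pep, start) for pep, start in observed_peptides if start == k + 1
    ]
    semi_at_site = any(
        is_semi_tryptic_n_side(protein, start) for _, start in site_peptides
    )
    supporting = site_peptides[0][0] if site_peptides else None

    lo, hi = mass_range
    upstream_detectable = [
        p for p in tryptic_digest(protein, parent_id=protein_id)
        if p.end <= k and lo <= p.mass <= hi
    ]
    first_detectable = not upstream_detectable

    return CleavageVerdict(
        protein_id=protein_id, k=k,
        enough_peptides=enough,
        semi_tryptic_at_site=semi_at_site,
        first_detectable=first_detectable,
        confirmed=enough and semi_at_site and first_detectable,
        n_observed=len(observed_peptides),
        supporting_peptide=supporting,
    )
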
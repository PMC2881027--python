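"""Synthetic protein sets with the statistical structure the analysis assumes.

Two soluble classes (organellar-like ``A`` and cell-envelope-like ``P``) are
drawn from class-specific first-order residue-transition models. A divergence
parameter ``delta`` blends a shared background chain with class-specific
biased chains: at ``delta = 0`` the two classes are identically distributed
(an exact null), and the compositional contrast grows monotonically with
``delta``. The A-class bias tilts toward hydrophobic/aliphatic residues so
that mean GRAVY(A) > mean GRAVY(P) for ``delta > 0``, mirroring the
physicochemical separation the classifier is meant to exploit.

Every soluble protein carries a canonical Sec signal peptide with an
n/h/c architecture (positively charged n-region, hydrophobic h-region,
polar c-region ending in an A-x-A cleavage motif); signal peptides are drawn
from one shared model for both classes, so the discriminative signal lives in
the mature sequence. Membrane proteins carry 1-6 hydrophobic helices of
18-25 residues; cytoplasmic proteins are signal-less and helix-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, ProteinRecord
from .signalpep import tmh_scan

# Background residue frequencies (Swiss-Prot-like averages), normalised in code.
BASE_FREQUENCIES: Dict[str, float] = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.022, "I": 0.059,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.038, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.068,
}

# Class-bias residue distributions: A tilts hydrophobic/aliphatic, P tilts
# polar/charged. These fix the direction of the GRAVY/aliphatic-index contrast.
_A_BIAS: Dict[str, float] = {
    "A": 0.13, "I": 0.07, "L": 0.10, "V": 0.09, "F": 0.05, "M": 0.03,
    "G": 0.12, "T": 0.10, "S": 0.06, "P": 0.02, "Y": 0.06, "W": 0.02,
    "N": 0.02, "Q": 0.02, "D": 0.02, "E": 0.02, "K": 0.02, "R": 0.02,
    "C": 0.005, "H": 0.005,
}
_P_BIAS: Dict[str, float] = {
    "D": 0.10, "E": 0.10, "K": 0.09, "R": 0.07, "N": 0.08, "Q": 0.08,
    "S": 0.10, "T": 0.05, "G": 0.06, "P": 0.06, "A": 0.04, "L": 0.04,
    "I": 0.02, "V": 0.03, "F": 0.015, "M": 0.01, "Y": 0.02, "W": 0.005,
    "C": 0.005, "H": 0.005,
}

_HYDROPHOBIC = set("AILMFV")
_POLAR_CHARGED = set("STNQGDEKR")
_SAME_CATEGORY_BOOST = 0.6  # first-order coupling so dipeptides add signal

_H_REGION_RESIDUES = ("L", "A", "V", "I", "F")
_H_REGION_WEIGHTS = (0.45, 0.15, 0.15, 0.12, 0.13)
_C_REGION_POLAR = ("S", "T", "G", "N", "Q")
_HELIX_RESIDUES = ("I", "L", "V", "F", "A")
_HELIX_WEIGHTS = (0.25, 0.30, 0.25, 0.10, 0.10)
_LINKER_RESIDUES = ("D", "E", "K", "R", "N", "Q", "S", "T", "G", "P")


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the training-set sizes of the study design (30 organellar
    vs 59 cell-envelope proteins) with a moderate compositional divergence.
    """

    seed: int = 0
    n_A: int = 30
    n_P: int = 59
    n_tm: int = 30
    n_cyt: int = 60
    length_range: Tuple[int, int] = (100, 300)
    divergence: float = 1.0
    n_region_range: Tuple[int, int] = (2, 6)
    h_region_range: Tuple[int, int] = (7, 17)
    c_region_range: Tuple[int, int] = (3, 6)
    shared_sp_model: bool = True

    def validate(self) -> None:
        for name in ("n_A", "n_P", "n_tm", "n_cyt"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.divergence < 0:
            raise ConfigurationError("divergence must be nonnegative")
        for name in ("length_range", "n_region_range", "h_region_range", "c_region_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < min <= max, got {(lo, hi)}")
        if self.n_region_range[0] < 2:
            raise ConfigurationError("n-region must be at least 2 residues (Met + charge)")
        if self.c_region_range[0] < 3:
            raise ConfigurationError("c-region must be at least 3 residues to host A-x-A")


def _normalise(weights: Dict[str, float]) -> np.ndarray:
    v = np.array([weights[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


def _bias_transition_matrix(bias: Dict[str, float]) -> np.ndarray:
    """Row-stochastic matrix with same-category coupling on top of *bias*."""
    d = _normalise(bias)
    T = np.tile(d, (20, 1))
    for i, a in enumerate(AMINO_ACIDS):
        boost = np.ones(20)
        for j, b in enumerate(AMINO_ACIDS):
            if (a in _HYDROPHOBIC and b in _HYDROPHOBIC) or (
                a in _POLAR_CHARGED and b in _POLAR_CHARGED
            ):
                boost[j] = 1.0 + _SAME_CATEGORY_BOOST
        row = T[i] * boost
        T[i] = row / row.sum()
    return T


def mixing_weight(divergence: float) -> float:
    """Convex blending weight w = delta / (delta + 1/2) in [0, 1).

    Zero at delta = 0 (exact null) and saturating fast enough that delta >= 3
    puts the two classes at near-complete compositional separation.
    """
    return divergence / (0.5 + divergence)


def transition_matrices(cfg: GeneratorConfig) -> Dict[str, np.ndarray]:
    """The mature-sequence chain models actually used at cfg.divergence.

    Returns row-stochastic 20x20 matrices (residues in alphabetical order)
    keyed by class label, plus the initial-state distributions under key
    ``<label>_init``. Exposed so tests can compare recovered feature
    importances against the true generative contrast.
    """
    w = mixing_weight(cfg.divergence)
    base_d = _normalise(BASE_FREQUENCIES)
    T_base = np.tile(base_d, (20, 1))
    out: Dict[str, np.ndarray] = {}
    for label, bias in (("A", _A_BIAS), ("P", _P_BIAS)):
        T = (1.0 - w) * T_base + w * _bias_transition_matrix(bias)
        init = (1.0 - w) * base_d + w * _normalise(bias)
        out[label] = T
        out[f"{label}_init"] = init
    return out


def _sample_chain(rng: np.random.Generator, T: np.ndarray, init: np.ndarray, length: int) -> str:
    idx = np.empty(length, dtype=int)
    idx[0] = rng.choice(20, p=init)
    for i in range(1, length):
        idx[i] = rng.choice(20, p=T[idx[i - 1]])
    return "".join(AMINO_ACIDS[j] for j in idx)


def make_signal_peptide(rng: np.random.Generator, cfg: GeneratorConfig) -> Tuple[str, int, int, int]:
    """One canonical Sec signal peptide: returns (sp, n_len, h_len, c_len).

    n-region: initiator Met followed by K/R; h-region: hydrophobic residues;
    c-region: small/polar residues with Ala forced at positions -3 and -1
    relative to the cleavage site.
    """
    n_len = int(rng.integers(cfg.n_region_range[0], cfg.n_region_range[1] + 1))
    h_len = int(rng.integers(cfg.h_region_range[0], cfg.h_region_range[1] + 1))
    c_len = int(rng.integers(cfg.c_region_range[0], cfg.c_region_range[1] + 1))
    n_region = "M" + "".join(rng.choice(["K", "R"], size=n_len - 1))
    h_region = "".join(
        rng.choice(_H_REGION_RESIDUES, size=h_len, p=_H_REGION_WEIGHTS)
    )
    c = list(rng.choice(_C_REGION_POLAR, size=c_len))
    c[-1] = "A"
    c[-3] = "A"
    return n_region + h_region + "".join(c), n_len, h_len, c_len


def _sample_soluble_mature(
    rng: np.random.Generator, cfg: GeneratorConfig, label: str, models: Dict[str, np.ndarray]
) -> str:
    """Mature sequence for a soluble class; rejection-sampled to contain no
    membrane-spanning hydrophobic window (a soluble protein by contract)."""
    lo, hi = cfg.length_range
    for _ in range(200):
        length = int(rng.integers(lo, hi + 1))
        seq = _sample_chain(rng, models[label], models[f"{label}_init"], length)
        if not tmh_scan(seq):
            return seq
    raise RuntimeError(
        "could not draw a soluble mature sequence without a membrane-like window; "
        "divergence/bias settings are implausibly hydrophobic"
    )


def generate_training_sets(cfg: GeneratorConfig) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """Generate the two soluble training sets (A-like, P-like).

    Each record carries a shared-model signal peptide prepended to a
    class-specific mature sequence and records the true cleavage index.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    models = transition_matrices(cfg)
    sets: Dict[str, List[ProteinRecord]] = {"A": [], "P": []}
    for label, n in (("A", cfg.n_A), ("P", cfg.n_P)):
        for i in range(n):
            sp, *_ = make_signal_peptide(rng, cfg)
            mature = _sample_soluble_mature(rng, cfg, label, models)
            sets[label].append(
                ProteinRecord(
                    id=f"{label}_{i:04d}",
                    sequence=sp + mature,
                    truth_label=label,
                    sp_truth=len(sp),
                )
            )
    return sets["A"], sets["P"]


def _sample_membrane_mature(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """Alternating hydrophilic linkers and 18-25 residue hydrophobic helices."""
    n_helices = int(rng.integers(1, 7))
    parts: List[str] = []
    for h in range(n_helices):
        linker_len = int(rng.integers(10, 41))
        parts.append("".join(rng.choice(_LINKER_RESIDUES, size=linker_len)))
        helix_len = int(rng.integers(18, 26))
        parts.append("".join(rng.choice(_HELIX_RESIDUES, size=helix_len, p=_HELIX_WEIGHTS)))
    parts.append("".join(rng.choice(_LINKER_RESIDUES, size=int(rng.integers(10, 41)))))
    return "".join(parts)


def _sample_cytoplasmic(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    base_d = _normalise(BASE_FREQUENCIES)
    T = np.tile(base_d, (20, 1))
    lo, hi = cfg.length_range
    for _ in range(200):
        length = int(rng.integers(lo, hi + 1))
        seq = "M" + _sample_chain(rng, T, base_d, length - 1)
        if not tmh_scan(seq):
            return seq
    raise RuntimeError("could not draw a helix-free cytoplasmic sequence")


def generate_proteome(cfg: GeneratorConfig) -> List[ProteinRecord]:
    """A mixed proteome covering all four subcellular sets.

    Emits ``n_A`` + ``n_P`` signal-peptide-bearing soluble proteins, ``n_tm``
    membrane proteins (even-indexed ones carry a signal peptide, odd-indexed
    ones do not, so both membrane sets are represented), and ``n_cyt``
    cytoplasmic proteins. Truth labels and cleavage indices are retained for
    partition-recovery tests.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])  # distinct stream from the training sets
    models = transition_matrices(cfg)
    records: List[ProteinRecord] = []
    for label, n in (("A", cfg.n_A), ("P", cfg.n_P)):
        for i in range(n):
            sp, *_ = make_signal_peptide(rng, cfg)
            mature = _sample_soluble_mature(rng, cfg, label, models)
            records.append(ProteinRecord(f"prot_{label}_{i:04d}", sp + mature,
                                         truth_label=label, sp_truth=len(sp)))
    for i in range(cfg.n_tm):
        mature = _sample_membrane_mature(rng, cfg)
        if i % 2 == 0:  # SP-bearing membrane protein
            sp, *_ = make_signal_peptide(rng, cfg)
            records.append(ProteinRecord(f"prot_TM_{i:04d}", sp + mature,
                                         truth_label="TM", sp_truth=len(sp)))
        else:
            records.append(ProteinRecord(f"prot_TM_{i:04d}", "M" + mature,
                                         truth_label="TM"))
    for i in range(cfg.n_cyt):
        records.append(ProteinRecord(f"prot_CYT_{i:04d}", _sample_cytoplasmic(rng, cfg),
                                     truth_label="CYT"))
    return records


def simulate_vote_table(
    records: List[ProteinRecord],
    n_predictors: int = 15,
    flip_rate: float = 0.0,
    cleavage_jitter: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated per-predictor signal-peptide calls derived from ground truth.

    At ``flip_rate = 0`` and ``cleavage_jitter = 0`` every predictor reports
    the truth (noiseless calls); otherwise each predictor independently flips
    its boolean call with probability ``flip_rate`` and jitters the reported
    cleavage position uniformly in ``+/- cleavage_jitter``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        truth = rec.sp_truth is not None
        for p in range(n_predictors):
            call = truth
            if flip_rate > 0 and rng.random() < flip_rate:
                call = not call
            pos: object = ""
            if call and truth:
                k = rec.sp_truth
                if cleavage_jitter:
                    k = max(4, rec.sp_truth + int(rng.integers(-cleavage_jitter,
                                                               cleavage_jitter + 1)))
                pos = k
            elif call:
                pos = int(rng.integers(15, 31))  # false positive invents a site
            rows.append({"protein_id": rec.id, "predictor": f"pred_{p:02d}",
                         "call": int(call), "cleavage_pos": pos})
    return pd.DataFrame(rows, columns=["protein_id", "predictor", "call", "cleavage_pos"])
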
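"""Whole-proteome partition into four subcellular sets and the final
organellar-sub-proteome call.

Sets: 1 = signal-peptide-bearing soluble, 2 = signal-peptide-bearing
membrane, 3 = membrane without signal peptide, 4 = cytoplasmic. Only
translocated proteins (sets 1-3) are candidates for the organellar vs
cell-envelope classifier; predicted type-IV secretion substrates are excluded
before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from .records import ProteinRecord
from .signalpep import tmh_scan

SET_LABELS = ("set1", "set2", "set3", "set4")
FINAL_LABELS = ("organellar", "cell_envelope", "excluded_typeIV", "not_translocated")


@dataclass
class ProteomePartition:
    """Disjoint assignment of every protein to one of the four sets."""

    labels: Dict[str, str]                 # protein id -> set1..set4
    provenance: Dict[str, Dict[str, object]]
    sp_calls: Dict[str, Optional[int]]     # id -> cleavage index (None = SP-negative)

    @property
    def counts(self) -> Dict[str, int]:
        c = {s: 0 for s in SET_LABELS}
        for lab in self.labels.values():
            c[lab] += 1
        return c

    def members(self, set_label: str) -> List[str]:
        return [pid for pid, lab in self.labels.items() if lab == set_label]


def partition(
    proteome: Sequence[ProteinRecord],
    sp_calls: Mapping[str, Optional[int]],
    tmh_calls: Optional[Mapping[str, bool]] = None,
) -> ProteomePartition:
    """Assign each protein to one of the four subcellular sets.

    ``sp_calls`` maps protein id to the consensus cleavage index (missing or
    None means SP-negative). ``tmh_calls`` maps id to a boolean membrane
    call; when absent, the surrogate hydrophobic-window scan is used, run on
    the mature region for SP-positive proteins (the signal peptide, itself a
    hydrophobic stretch, is masked first).
    """
    ids = [r.id for r in proteome]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    labels: Dict[str, str] = {}
    provenance: Dict[str, Dict[str, object]] = {}
    kept_sp: Dict[str, Optional[int]] = {}
    for rec in proteome:
        k = sp_calls.get(rec.id)
        has_sp = k is not None
        if tmh_calls is not None:
            has_tmh = bool(tmh_calls.get(rec.id, False))
            tmh_source = "external"
        else:
            scan_seq = rec.sequence[k:] if has_sp else rec.sequence
            has_tmh = bool(tmh_scan(scan_seq)) if len(scan_seq) >= 18 else False
            tmh_source = "surrogate_scan_masked" if has_sp else "surrogate_scan"
        if has_sp:
            labels[rec.id] = "set2" if has_tmh else "set1"
        else:
            labels[rec.id] = "set3" if has_tmh else "set4"
        kept_sp[rec.id] = k
        provenance[rec.id] = {"sp_positive": has_sp, "tmh_positive": has_tmh,
                              "tmh_source": tmh_source}
    return ProteomePartition(labels=labels, provenance=provenance, sp_calls=kept_sp)


@dataclass
class OrganellePrediction:
    """Final per-protein organellar calls with pooled classifier votes."""

    votes: Dict[str, Tuple[float, float]]  # id -> (vote_A, vote_P)
    final_labels: Dict[str, str]
    excluded: Set[str]
    best_run_index: Optional[int]

    @property
    def counts(self) -> Dict[str, int]:
        c = {lab: 0 for lab in FINAL_LABELS}
        for lab in self.final_labels.values():
            c[lab] += 1
        return c

    @property
    def fraction_organellar(self) -> float:
        c = self.counts
        candidates = c["organellar"] + c["cell_envelope"]
        return c["organellar"] / candidates if candidates else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, lab in self.final_labels.items():
            va, vp = self.votes.get(pid, (float("nan"), float("nan")))
            rows.append({"protein_id": pid, "final_label": lab,
                         "votes_A": va, "votes_P": vp})
        return pd.DataFrame(rows)


def predict_organellar(
    part: ProteomePartition,
    proteome: Sequence[ProteinRecord],
    model: Pipeline,
    typeIV_calls: Optional[Set[str]] = None,
) -> OrganellePrediction:
    """Classify every translocated protein (sets 1-3) as organellar or
    cell-envelope with a fitted vectorizer+classifier pipeline.

    Proteins flagged as type-IV secretion substrates are excluded before
    counting; set-4 proteins are labelled ``not_translocated``. For models
    using sp/mature regions the consensus cleavage index recorded in the
    partition is attached to each record before featurization.
    """
    typeIV_calls = typeIV_calls or set()
    by_id = {r.id: r for r in proteome}
    translocated = [pid for pid in part.labels if part.labels[pid] != "set4"]
    if not translocated:
        raise ValueError("no translocated proteins (sets 1-3 empty)")
    candidates = [pid for pid in translocated if pid not in typeIV_calls]

    final: Dict[str, str] = {}
    votes: Dict[str, Tuple[float, float]] = {}
    for pid in part.members("set4"):
        final[pid] = "not_translocated"
    for pid in translocated:
        if pid in typeIV_calls:
            final[pid] = "excluded_typeIV"

    if candidates:
        recs = []
        for pid in candidates:
            rec = by_id[pid]
            k = part.sp_calls.get(pid)
            if k is not None and rec.sp_truth != k:
                rec = ProteinRecord(rec.id, rec.sequence, truth_label=rec.truth_label,
                                    sp_truth=k)
            recs.append(rec)
        clf = model.named_steps[list(model.named_steps)[-1]]
        proba = model.predict_proba(recs)
        classes = list(clf.classes_)
        j_a = classes.index(clf.minority_label_)
        j_p = 1 - j_a
        preds = model.predict(recs)
        for pid, p, row in zip(candidates, preds, proba):
            votes[pid] = (float(row[j_a]), float(row[j_p]))
            final[pid] = "organellar" if p == clf.minority_label_ else "cell_envelope"

    best_idx = None
    clf = model.named_steps[list(model.named_steps)[-1]]
    if hasattr(clf, "selection_"):
        best_idx = clf.selection_.best_run_index
    return OrganellePrediction(votes=votes, final_labels=final,
                               excluded=set(typeIV_calls) & set(translocated),
                               best_run_index=best_idx)
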
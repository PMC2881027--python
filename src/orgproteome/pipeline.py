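"""End-to-end pipeline driver.

Runs: synthetic generation -> redundancy filtering -> feature construction ->
imbalance-randomized forest training -> whole-proteome partition ->
organellar prediction -> signal-peptide architecture analysis -> cleavage-
site digest validation, and writes a JSON summary. All randomness flows from
one base seed; per-stage seeds are derived deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.pipeline import Pipeline

from . import io as _io
from .classify import ProtocolConfig, run_protocol
from .digest import tryptic_digest, validate_cleavage
from .features import CompositionVectorizer, aliphatic_index, gravy, redundancy_filter
from .partition import partition, predict_organellar
from .records import ProteinRecord
from .signalpep import (
    SignalPeptideAnnotation,
    consensus_cleavage,
    h_region_phe_count,
    join_alignments,
    majority_vote,
    parse_regions,
    position_frequency_matrix,
    segmental_align,
    ANCHORS,
    NoHRegionError,
)
from .simulate import GeneratorConfig, generate_proteome, generate_training_sets, simulate_vote_table

logger = logging.getLogger("orgproteome")


@dataclass
class PipelineConfig:
    """Seed-driven configuration for the synthetic end-to-end pipeline."""

    seed: int = 0
    out_dir: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: ProtocolConfig = field(default_factory=lambda: ProtocolConfig(
        n_trees=200, n_randomizations=50))
    n_predictors: int = 15
    vote_flip_rate: float = 0.0
    cleavage_jitter: int = 0
    identity_threshold: float = 0.85
    n_digest_examples: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        if "generator" in raw and isinstance(raw["generator"], dict):
            gknown = {f.name for f in dataclasses.fields(GeneratorConfig)}
            gunknown = set(raw["generator"]) - gknown
            if gunknown:
                raise ValueError(f"unknown generator keys: {sorted(gunknown)}")
            g = dict(raw["generator"])
            for key in ("length_range", "n_region_range", "h_region_range", "c_region_range"):
                if key in g:
                    g[key] = tuple(g[key])
            raw["generator"] = GeneratorConfig(**g)
        if "protocol" in raw and isinstance(raw["protocol"], dict):
            pknown = {f.name for f in dataclasses.fields(ProtocolConfig)}
            punknown = set(raw["protocol"]) - pknown
            if punknown:
                raise ValueError(f"unknown protocol keys: {sorted(punknown)}")
            raw["protocol"] = ProtocolConfig(**raw["protocol"])
        return cls(**raw)

    def to_dict(self) -> Dict:
        def tuples_to_lists(obj):
            if isinstance(obj, dict):
                return {k: tuples_to_lists(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [tuples_to_lists(v) for v in obj]
            return obj

        return tuples_to_lists(asdict(self))


def _derived_seed(base: int, stage: int) -> int:
    # deterministic per-stage stream, kept below 2**31
    return (base * 1_000_003 + stage * 7919) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute every stage on synthetic data and return the summary dict.

    When ``cfg.out_dir`` is set, module outputs (FASTA, TSV tables, JSON
    summary) are written there as well.
    """
    gen = dataclasses.replace(cfg.generator, seed=_derived_seed(cfg.seed, 1))
    proto = dataclasses.replace(cfg.protocol, base_seed=_derived_seed(cfg.seed, 2))
    chash = _io.config_hash(cfg.to_dict())

    # 1. synthetic data
    set_A, set_P = generate_training_sets(gen)
    proteome = generate_proteome(gen)

    # 2. training-set redundancy filtering
    set_A = redundancy_filter(set_A, cfg.identity_threshold)
    set_P = redundancy_filter(set_P, cfg.identity_threshold)

    # 3. classifier protocol
    runs, selection, clf = run_protocol(set_A, set_P, proto)
    vec = CompositionVectorizer(region=proto.region, order=proto.order,
                                exclusion_mode=proto.exclusion_mode).fit([])
    model = Pipeline([("features", vec), ("classifier", clf)])

    # 4. predictor votes, partition, organellar prediction
    votes = simulate_vote_table(
        proteome, n_predictors=cfg.n_predictors, flip_rate=cfg.vote_flip_rate,
        cleavage_jitter=cfg.cleavage_jitter, seed=_derived_seed(cfg.seed, 3),
    )
    sp_majority = majority_vote(votes, cfg.n_predictors)
    sp_sites = consensus_cleavage(votes)
    sp_calls = {pid: sp_sites.get(pid) for pid, pos in sp_majority.items() if pos}
    part = partition(proteome, sp_calls)
    prediction = predict_organellar(part, proteome, model)

    # 5. signal-peptide architecture analysis on the training sets
    annotations: List[SignalPeptideAnnotation] = []
    parse_failures = 0
    for rec in list(set_A) + list(set_P):
        try:
            annotations.append(parse_regions(rec.sequence, rec.sp_truth))
        except NoHRegionError:
            parse_failures += 1
    alignments = {a: segmental_align(annotations, a) for a in ANCHORS}
    pfm = position_frequency_matrix(alignments["cleavage_site"])
    roundtrip_ok = join_alignments([alignments[a] for a in ANCHORS]) == [
        ann.signal_peptide for ann in annotations
    ]
    phe_mean = h_region_phe_count(annotations)

    physchem = {
        label: {
            "gravy_mean": float(np.mean([gravy(r.mature) for r in recs])),
            "aliphatic_index_mean": float(np.mean([aliphatic_index(r.mature) for r in recs])),
        }
        for label, recs in (("A", set_A), ("P", set_P))
    }

    # 6. digest validation on a few SP-bearing proteins with simulated evidence
    digest_results = []
    for rec in (set_A + set_P)[: cfg.n_digest_examples]:
        k = rec.sp_truth
        mature_frags = [p for p in tryptic_digest(rec.sequence) if p.start > k]
        observed: List[Tuple[str, int]] = []
        site_frag = rec.sequence[k : k + min(12, len(rec.sequence) - k)]
        observed.append((site_frag, k + 1))
        observed.extend((p.sequence, p.start) for p in mature_frags[:2])
        verdict = validate_cleavage(rec.sequence, k, observed, protein_id=rec.id)
        digest_results.append(verdict)
    n_confirmed = sum(v.confirmed for v in digest_results)

    truth_recall = _organellar_recall(prediction, proteome)

    summary = {
        "config_hash": chash,
        "seed": cfg.seed,
        "coordinate_convention": "1-based inclusive",
        "training": {
            "n_A": len(set_A), "n_P": len(set_P),
            "best_run_index": selection.best_run_index,
            "best_accuracy": selection.accuracy,
            "best_recall_A": selection.recall_A,
            "oob_error_mean": selection.oob_error_mean,
            "oob_error_sd": selection.oob_error_sd,
            "top_features": selection.top_features[:10],
        },
        "partition_counts": part.counts,
        "organellar": {
            "counts": prediction.counts,
            "fraction_organellar": prediction.fraction_organellar,
            "recall_vs_truth": truth_recall,
        },
        "signal_peptides": {
            "n_annotated": len(annotations),
            "parse_failures": parse_failures,
            "h_region_phe_mean": phe_mean,
            "cleavage_minus1_argmax": str(pfm[-1].idxmax()),
            "cleavage_minus3_argmax": str(pfm[-3].idxmax()),
            "segment_roundtrip_exact": bool(roundtrip_ok),
        },
        "physicochemistry": physchem,
        "digest_validation": {
            "n_tested": len(digest_results),
            "n_confirmed": int(n_confirmed),
        },
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_fasta(set_A, out / "set_A.fasta")
        _io.write_fasta(set_P, out / "set_P.fasta")
        _io.write_fasta(proteome, out / "proteome.fasta")
        _io.write_truth_sidecar(proteome, out / "proteome_truth.tsv")
        _io.write_vote_table(votes, out / "votes.tsv")
        runs_df = pd.DataFrame(
            [{"run_index": r.run_index, "oob_error": r.oob_error,
              "accuracy": r.accuracy, "recall_A": r.recall_A} for r in runs]
        )
        runs_df.to_csv(out / "runs.tsv", sep="\t", index=False)
        prediction.to_frame().to_csv(out / "organellar_predictions.tsv", sep="\t", index=False)
        pfm.to_csv(out / "cleavage_pfm.tsv", sep="\t")
        _io.write_json(summary, out / "summary.json")
    return summary


def _organellar_recall(prediction, proteome) -> float:
    """Fraction of truth-A proteins labelled organellar (NaN when no truth)."""
    truth_a = [r.id for r in proteome if r.truth_label == "A"]
    if not truth_a:
        return float("nan")
    hit = sum(prediction.final_labels.get(pid) == "organellar" for pid in truth_a)
    return hit / len(truth_a)
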
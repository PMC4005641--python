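"""End-to-end orchestration: featurize -> screen -> forest -> rule.

One call runs the whole structure-toxicity analysis on an annotated
sequence table (or a synthetic dataset) and writes every artifact as
delimited text plus a JSON run manifest: the normalized dataset, the
k-mer feature matrix, the chi-square screen report, the motif
distribution table, the forest summary (confusion, per-class metrics,
mean-decrease-accuracy importances) and the motif-rule evaluation.

Stage-level logging records counts in and out of each stage (records
-> testable motifs -> selected motifs -> forest features), so the
catalogue reduction is auditable from the log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .gapmer_data import Dataset, GapmerValidationError, read_dataset, write_dataset
from .kmer_features import FeatureMatrix, enumerate_motifs, featurize
from .motif_rules import MotifRule, evaluate_rule, rule_predict
from .motif_screen import (
    ScreenResult,
    motif_distribution_table,
    screen_motifs,
    screen_table,
    selected_motifs,
)
from .rf_model import ForestConfig, ForestResult, forest_summary, predict, train_forest

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the analysis, with the study defaults.

    ``rule_motifs=None`` derives the rule from the screen itself: the
    selected motifs that have zero non-toxic carriers.
    """

    input: Optional[str] = None
    kmin: int = 2
    kmax: int = 5
    alpha: float = 0.05
    continuity_correction: bool = False
    fdr_method: Optional[str] = None
    binarize: bool = False
    n_tree: int = 1000
    m_try_rule: str = "p_over_3"
    m_try: Optional[int] = None
    vote_threshold: float = 0.5
    rule_motifs: Optional[list[str]] = None
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_tree=self.n_tree,
            m_try_rule=self.m_try_rule,
            m_try=self.m_try,
            seed=self.seed,
            vote_threshold=self.vote_threshold,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output."""

    config: PipelineConfig
    dataset: Dataset
    features: FeatureMatrix
    screen: list[ScreenResult]
    selected: list[str]
    forest: ForestResult
    rule: MotifRule
    rule_confusion: "object"
    rule_agreement: pd.DataFrame
    distribution: pd.DataFrame
    manifest: dict


def _derive_rule(screen: Sequence[ScreenResult]) -> MotifRule:
    """Default rule: screen-selected motifs never seen in a non-toxic sequence.

    Falls back to the canonical TGC/TCC rule (with a warning) when no
    selected motif has zero non-toxic carriers, which happens on very
    small datasets.
    """
    motifs = {r.motif for r in screen if r.selected and r.table.c == 0}
    if not motifs:
        logger.warning(
            "no selected motif has zero non-toxic carriers; "
            "falling back to the default TGC/TCC rule"
        )
        return MotifRule()
    return MotifRule(frozenset(motifs))


def run_pipeline(
    config: PipelineConfig, dataset: Optional[Dataset] = None
) -> PipelineResult:
    """Run the full analysis; write artifacts if ``config.outdir`` is set.

    Either pass a :class:`Dataset` directly or set ``config.input`` to
    a delimited sequence table.  Deterministic for a fixed config and
    input: rerunning writes byte-identical report tables.
    """
    if dataset is None:
        if config.input is None:
            raise ValueError("run_pipeline needs a dataset or config.input")
        logger.info("stage load: reading %s", config.input)
        dataset = read_dataset(config.input)
    labeled = dataset.labeled()
    logger.info(
        "stage load: %d records (%d toxic / %d non-toxic labeled)",
        len(dataset), labeled.n_toxic, labeled.n_nontoxic,
    )

    index = enumerate_motifs(config.kmin, config.kmax)
    features = featurize(dataset, index, binarize=config.binarize)
    logger.info("stage featurize: %d motifs in catalogue", features.p)

    screen = screen_motifs(
        features,
        alpha=config.alpha,
        continuity_correction=config.continuity_correction,
        fdr_method=config.fdr_method,
    )
    n_testable = sum(r.testable for r in screen)
    selected = selected_motifs(screen)
    logger.info(
        "stage screen: %d testable motifs, %d selected at alpha=%g",
        n_testable, len(selected), config.alpha,
    )
    if not selected:
        raise ValueError("screen selected no motifs; nothing for the forest")

    forest_features = features.subset_motifs(selected)
    forest = train_forest(forest_features, config.forest_config())
    logger.info(
        "stage forest: n_tree=%d m_try=%d OOB sensitivity=%.3f specificity=%.3f",
        forest.config.n_tree, forest.m_try, forest.sensitivity, forest.specificity,
    )

    rule = (
        MotifRule(frozenset(config.rule_motifs))
        if config.rule_motifs
        else _derive_rule(screen)
    )
    rule_confusion, rule_agreement = evaluate_rule(dataset, rule)
    logger.info(
        "stage rule: motifs=%s TP=%d FN=%d TN=%d FP=%d",
        sorted(rule.motifs), rule_confusion.tp, rule_confusion.fn,
        rule_confusion.tn, rule_confusion.fp,
    )

    distribution = motif_distribution_table(screen)

    manifest = {
        "tool": "toxsar",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "counts": {
            "records": len(dataset),
            "labeled_toxic": labeled.n_toxic,
            "labeled_nontoxic": labeled.n_nontoxic,
            "catalogue_motifs": features.p,
            "testable_motifs": n_testable,
            "selected_motifs": len(selected),
            "forest_features": forest_features.p,
        },
        "forest": forest_summary(forest),
        "rule": {
            "motifs": sorted(rule.motifs),
            "tp": rule_confusion.tp,
            "fn": rule_confusion.fn,
            "tn": rule_confusion.tn,
            "fp": rule_confusion.fp,
        },
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        features=features,
        screen=screen,
        selected=selected,
        forest=forest,
        rule=rule,
        rule_confusion=rule_confusion,
        rule_agreement=rule_agreement,
        distribution=distribution,
        manifest=manifest,
    )
    if config.outdir is not None:
        write_reports(result, config.outdir)
    return result


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Write every artifact as delimited text plus the JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(result.dataset, out / "dataset.tsv")
    result.features.to_frame().to_csv(out / "features.tsv", sep="\t")
    screen_table(result.screen).to_csv(out / "screen.tsv", sep="\t", index=False)
    result.distribution.to_csv(out / "motif_distribution.tsv", sep="\t", index=False)
    imp = result.forest.importance_table()
    imp.to_csv(out / "importance.tsv", sep="\t", index=False)
    pd.DataFrame([result.manifest["forest"]]).to_csv(
        out / "forest_summary.tsv", sep="\t", index=False
    )
    result.rule_agreement.to_csv(out / "rule_agreement.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    logger.info("reports written to %s", out)


def candidate_screen(
    candidates: Dataset,
    forest: ForestResult,
    rule: MotifRule,
    features: Optional[FeatureMatrix] = None,
) -> pd.DataFrame:
    """Rank unlabeled candidate sequences, safest first.

    Each candidate gets the rule verdict (with matched motifs), the
    forest toxic-vote fraction, and a combined flag (flagged if either
    flags).  Sorting: unflagged before flagged, then ascending vote
    fraction, then id.
    """
    if features is None:
        full = featurize(candidates, enumerate_motifs(2, 5))
        features = full.subset_motifs(list(forest.motifs))
    scores = predict(forest, features).set_index("id")
    rows = []
    for rec in candidates:
        pred = rule_predict(rec.bases, rule)
        vote = float(scores.loc[rec.id, "vote_fraction_toxic"])
        forest_flag = bool(scores.loc[rec.id, "predicted_toxic"])
        rows.append(
            {
                "id": rec.id,
                "sequence": rec.bases,
                "rule_flag": pred.toxic,
                "matched_motifs": ",".join(pred.matched_motifs),
                "forest_vote_fraction": vote,
                "forest_flag": forest_flag,
                "flagged": pred.toxic or forest_flag,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["flagged", "forest_vote_fraction", "id"], ascending=[True, True, True]
    ).reset_index(drop=True)
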
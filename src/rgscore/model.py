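"""Model/Results interface over the scoring pipeline.

``StabilityModel`` binds one condition's data (counts, sample sheet,
clinical table, annotations) to the component registry; ``fit()``
extracts the per-gene features, scores the 48 expression component
instances, aggregates them into ``S_exp``, applies the three
anti-scorings and returns a ``StabilityResults`` with the per-gene
scorecards, a tabular view, a ``summary()`` report and reference-gene
pair selection.  ``PanCancerModel`` pools fitted per-condition results
into the cross-condition power-mean aggregate.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as rgio
from .annotations import (GeneAnnotation, go_penalty, mutation_percentile,
                          publication_counts)
from .config import default_config, load_config
from .features import ExpressionDataset, extract_features
from .pairs import RGPair, select_pair
from .scoring import (ComponentValue, GeneScoreCard, PanCancerResult,
                      aggregate_expression_score, anti_scores,
                      build_component_registry, component_score, final_score,
                      pan_cancer_score)

__all__ = ["StabilityModel", "StabilityResults", "PanCancerModel", "PanCancerResults"]

logger = logging.getLogger(__name__)


class StabilityModel:
    """Reference-gene suitability scoring for one condition.

    Parameters
    ----------
    dataset : ExpressionDataset
        Counts, CPM, sample metadata and clinical table.
    annotations : mapping gene -> GeneAnnotation, optional
        Isoform/pseudogene/mutation counts and GO terms.  Genes missing
        an annotation get neutral anti-scorings (100) with a warning.
    mutation_counts : Series, optional
        Per-gene somatic-mutation tally for this condition; defaults to
        the ``mutation_count`` field of the annotations.
    corpus : DataFrame, optional
        Local abstract corpus (id, title, abstract) for advisory
        publication counting.
    config : mapping, optional
        Overrides of the shipped registry/threshold configuration.
    strict : bool
        Require exactly six clinical characteristics (the full design).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        annotations: Mapping[str, GeneAnnotation] | None = None,
        mutation_counts: pd.Series | None = None,
        corpus: pd.DataFrame | None = None,
        config: Mapping | None = None,
        strict: bool = True,
        condition: str = "condition",
    ) -> None:
        self.dataset = dataset
        self.annotations = dict(annotations or {})
        if mutation_counts is None and self.annotations:
            mutation_counts = pd.Series(
                {g: a.mutation_count for g, a in self.annotations.items()},
                name="mutation_count",
            )
        self.mutation_counts = mutation_counts
        self.corpus = corpus
        self.config = dict(default_config()) if config is None else dict(config)
        self.strict = strict
        self.condition = condition
        self.registry = build_component_registry(self.config, strict=strict)

    @classmethod
    def from_tables(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        clinical: pd.DataFrame,
        **kwargs,
    ) -> "StabilityModel":
        config = kwargs.get("config")
        dataset = ExpressionDataset.from_tables(counts, samples, clinical, config=config)
        return cls(dataset, **kwargs)

    @classmethod
    def from_files(
        cls,
        counts_path,
        samples_path,
        clinical_path,
        annotation_path=None,
        go_terms_path=None,
        mutations_path=None,
        corpus_path=None,
        config_path=None,
        **kwargs,
    ) -> "StabilityModel":
        config = load_config(config_path)
        counts = rgio.read_counts(counts_path)
        samples = rgio.read_samples(samples_path)
        clinical = rgio.read_clinical(clinical_path)
        annotations = None
        if annotation_path is not None:
            go = rgio.read_go_terms(go_terms_path) if go_terms_path else None
            annotations = rgio.read_annotations(annotation_path, go_terms=go)
        mutation_counts = rgio.read_mutations(mutations_path) if mutations_path else None
        corpus = rgio.read_corpus(corpus_path) if corpus_path else None
        return cls.from_tables(
            counts, samples, clinical, annotations=annotations,
            mutation_counts=mutation_counts, corpus=corpus, config=config,
            **kwargs,
        )

    def fit(self) -> "StabilityResults":
        """Extract features, score every gene and assemble the scorecards."""
        features = extract_features(self.dataset, self.config)
        cards: dict[str, GeneScoreCard] = {}
        for gene, feats in features.items():
            xs = feats.x_values()
            components: list[ComponentValue] = []
            flags = list(feats.flags)
            for inst in self.registry:
                x = xs[inst.instance_label]
                if math.isfinite(x):
                    score = component_score(x, inst.params)
                else:  # sentinel from feature extraction (e.g. low expression)
                    score = 0.0
                    if f"sentinel:{inst.instance_label}" not in flags:
                        flags.append(f"sentinel:{inst.instance_label}")
                components.append(
                    ComponentValue(inst.spec_id, inst.instance_label, x, score)
                )
            s_exp = aggregate_expression_score(components, self.registry)
            card = GeneScoreCard(gene=gene, components=components, s_exp=s_exp,
                                 flags=flags)
            self._apply_annotations(card)
            cards[gene] = card
        return StabilityResults(self, cards)

    def _apply_annotations(self, card: GeneScoreCard) -> None:
        ann = self.annotations.get(card.gene)
        if ann is None and self.annotations:
            logger.warning("gene %s lacks annotation; neutral anti-scorings", card.gene)
            card.flags.append("missing_annotation")
        if self.mutation_counts is not None and len(self.mutation_counts) >= 2:
            pct = mutation_percentile(card.gene, self.mutation_counts)
        else:
            pct = 0.0
        n_iso = ann.n_isoforms if ann else 1
        n_pse = ann.n_pseudogenes if ann else 0
        card.s_mut, card.s_isoforms, card.s_pseudogenes = anti_scores(
            pct, n_iso, n_pse, self.config
        )
        card.s_final = final_score(card.s_exp, card.s_mut, card.s_isoforms,
                                   card.s_pseudogenes)
        card.advisory["mutation_percentile"] = pct
        if ann is not None:
            gp = go_penalty(ann.go_terms, self.config.get("go_penalty"))
            card.advisory["go_raw_points"] = gp.raw_points
            card.advisory["go_penalty"] = gp.normalized_penalty
            card.advisory["go_insufficient"] = gp.insufficient
            if self.corpus is not None:
                kw = self.config["cancer_keywords"]
                pc = publication_counts(
                    self.corpus, ann, list(kw["core"]) + list(kw["extended"])
                )
                card.advisory["publications_total"] = pc.total_mentions
                card.advisory["publications_cancer"] = pc.cancer_mentions


class StabilityResults:
    """Fitted per-gene scorecards for one condition."""

    def __init__(self, model: StabilityModel, scorecards: dict[str, GeneScoreCard]):
        self.model = model
        self.scorecards = scorecards

    @property
    def frame(self) -> pd.DataFrame:
        """One row per gene: headline scores, advisory columns, breakdown."""
        rows = []
        for gene, card in self.scorecards.items():
            row = {
                "gene": gene,
                "s_exp": card.s_exp,
                "s_mut": card.s_mut,
                "s_isoforms": card.s_isoforms,
                "s_pseudogenes": card.s_pseudogenes,
                "s_final": card.s_final,
            }
            for key in ("mutation_percentile", "go_raw_points", "go_penalty",
                        "go_insufficient", "publications_total", "publications_cancer"):
                if key in card.advisory:
                    row[key] = card.advisory[key]
            row["flags"] = ";".join(card.flags)
            for cv in card.components:
                row[cv.instance_label] = cv.score
            rows.append(row)
        return (pd.DataFrame(rows)
                .sort_values(["s_final", "gene"], ascending=[False, True])
                .reset_index(drop=True))

    def top_k(self, k: int = 5, by: str = "s_exp") -> pd.DataFrame:
        cols = ["gene", "s_exp", "s_mut", "s_isoforms", "s_pseudogenes", "s_final"]
        return (self.frame[cols].sort_values([by, "gene"], ascending=[False, True])
                .head(k).reset_index(drop=True))

    def summary(self, k: int = 5) -> str:
        """Plain-text report: condition, sizes, top-k genes, best pair."""
        ds = self.model.dataset
        lines = [
            "Reference-gene expression stability scoring",
            "=" * 46,
            f"condition: {self.model.condition}",
            f"genes: {len(self.scorecards)}   tumor: {len(ds.tumor_samples)}   "
            f"normal: {len(ds.normal_samples)}   pairs: {len(ds.pairs)}",
            f"component instances: {len(self.model.registry)}",
            "",
            f"Top {k} genes by S_exp:",
        ]
        top = self.top_k(k)
        lines.append(top.to_string(
            index=False,
            float_format=lambda v: f"{v:8.1f}",
        ))
        try:
            best, _ = self.select_pair()
            lines += [
                "",
                f"Best pair: {best.gene_a} + {best.gene_b} "
                f"(S_exp {best.s_exp_a:.1f}/{best.s_exp_b:.1f}, "
                f"r_s={best.coexpression_r:.2f}, "
                f"{'eligible' if best.eligible else 'INELIGIBLE fallback'})",
            ]
        except ValueError:
            pass
        return "\n".join(lines)

    def select_pair(
        self,
        score_threshold: float | None = None,
        r_cutoff: float | None = None,
    ) -> tuple[RGPair, list[RGPair]]:
        """Optimal non-co-expressed pair (co-expression over tumor samples)."""
        thr = self.model.config["thresholds"]
        s_exp = {g: c.s_exp for g, c in self.scorecards.items()}
        return select_pair(
            s_exp,
            self.model.dataset.cpm,
            self.model.dataset.tumor_samples,
            score_threshold=thr["score_threshold"] if score_threshold is None else score_threshold,
            r_cutoff=thr["r_cutoff"] if r_cutoff is None else r_cutoff,
        )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


class PanCancerModel:
    """Cross-condition aggregation of fitted per-condition results.

    ``genes='union'`` scores every gene over the conditions it appears
    in (per-gene M, flagged when short); ``genes='intersection'``
    restricts to genes present in all conditions.
    """

    def __init__(
        self,
        results: Mapping[str, StabilityResults],
        annotations: Mapping[str, GeneAnnotation] | None = None,
        genes: str = "union",
        k: float | None = None,
        ca: float | None = None,
    ) -> None:
        if len(results) < 1:
            raise ValueError("at least one fitted condition required")
        self.results = dict(results)
        if annotations is None:
            annotations = {}
            for res in self.results.values():
                for g, a in res.model.annotations.items():
                    annotations.setdefault(g, a)
        self.annotations = dict(annotations)
        pan_cfg = next(iter(self.results.values())).model.config["pan_cancer"]
        self.k = float(pan_cfg["k"]) if k is None else float(k)
        self.ca = float(pan_cfg["CA"]) if ca is None else float(ca)
        self.genes_mode = genes

    def fit(self) -> "PanCancerResults":
        gene_sets = [set(r.scorecards) for r in self.results.values()]
        if self.genes_mode == "intersection":
            universe = sorted(set.intersection(*gene_sets))
            if len(universe) < max(map(len, gene_sets)):
                logger.info("gene universe mismatch: using %d shared genes",
                            len(universe))
        else:
            universe = sorted(set.union(*gene_sets))
        n_cond = len(self.results)
        out: dict[str, PanCancerResult] = {}
        for gene in universe:
            per_condition = [
                (cond, res.scorecards[gene].s_exp, res.scorecards[gene].s_mut)
                for cond, res in self.results.items()
                if gene in res.scorecards
            ]
            flags = []
            if len(per_condition) < n_cond:
                flags.append(f"partial:{len(per_condition)}/{n_cond}")
            ann = self.annotations.get(gene)
            from .scoring import ScoringParams  # anti params from shared config
            cfg = next(iter(self.results.values())).model.config["anti_scorings"]
            s_iso = component_score(
                float(ann.n_isoforms if ann else 1),
                ScoringParams.from_mapping(cfg["S_Isoforms"]["params"]))
            s_pse = component_score(
                float(ann.n_pseudogenes if ann else 0),
                ScoringParams.from_mapping(cfg["S_Pseudogenes"]["params"]))
            out[gene] = pan_cancer_score(
                per_condition, s_iso, s_pse, k=self.k, ca=self.ca,
                gene=gene, flags=flags,
            )
        return PanCancerResults(self, out)


class PanCancerResults:
    """Per-gene pan-cancer aggregates."""

    def __init__(self, model: PanCancerModel, results: dict[str, PanCancerResult]):
        self.model = model
        self.pan = results

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene,
                "s_exp_mut_pan": r.s_exp_mut_pan,
                "s_final_pan": r.s_final_pan,
                "m": r.m,
                "k": r.k,
                "ca": r.ca,
                "flags": ";".join(r.flags),
            }
            for r in self.pan.values()
        ]
        return (pd.DataFrame(rows)
                .sort_values(["s_final_pan", "gene"], ascending=[False, True])
                .reset_index(drop=True))

    def summary(self, k: int = 10) -> str:
        lines = [
            "Pan-cancer reference-gene aggregation",
            "=" * 42,
            f"conditions (M): {len(self.model.results)}   "
            f"power-mean exponent k: {self.model.k}   constant add: {self.model.ca}",
            "(aggregate carries the +CA offset of the power-mean formula)",
            "",
            f"Top {k} genes by pan-cancer final score:",
            self.frame.head(k).to_string(index=False,
                                         float_format=lambda v: f"{v:8.2f}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
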
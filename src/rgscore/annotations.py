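"""Annotation-derived penalties: GO keywords, publication counts, mutations.

A good qPCR reference gene should stay clear of processes that cancer
commonly rewires.  Six keyword categories over a gene's GO term names
(cell cycle 5, differentiation 4, stress response 3, immune response 2,
angiogenesis 2, intercellular interactions 2) sum to at most 18 penalty
points, normalized by the annotation depth ``n_terms**0.3``; genes with
fewer than 3 GO terms are considered insufficiently annotated and get a
flat 10 points.  Publication counting over a local abstract corpus and
the somatic-mutation-rate percentile provide the remaining inputs.  GO
and publication outputs are advisory report columns only; the mutation
percentile feeds the S_Mut anti-scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import default_config

__all__ = [
    "GeneAnnotation",
    "GoPenaltyResult",
    "PublicationCounts",
    "go_penalty",
    "publication_counts",
    "mutation_percentile",
]


@dataclass
class GeneAnnotation:
    """Static annotation of one gene."""

    gene: str
    aliases: list[str] = field(default_factory=list)
    n_isoforms: int = 1
    n_pseudogenes: int = 0
    mutation_count: int = 0
    go_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_isoforms, self.n_pseudogenes, self.mutation_count) < 0:
            raise ValueError(f"negative annotation count for {self.gene}")
        if self.gene not in self.aliases:
            self.aliases = [self.gene, *self.aliases]


@dataclass(frozen=True)
class GoPenaltyResult:
    raw_points: int
    category_hits: tuple[str, ...]
    n_terms: int
    normalized_penalty: float
    insufficient: bool


@dataclass(frozen=True)
class PublicationCounts:
    gene: str
    total_mentions: int
    cancer_mentions: int


def go_penalty(
    go_terms: Sequence[str],
    keyword_config: Mapping | None = None,
) -> GoPenaltyResult:
    """Penalty points for involvement in cancer-associated processes.

    A category contributes its points iff at least one of its keywords
    occurs (case-insensitive substring) in any of the gene's GO term
    names.  Fewer than 3 terms means the annotation is too thin to
    judge: the penalty is the flat insufficient value and is not divided
    by the depth coefficient.
    """
    cfg = (dict(default_config())["go_penalty"]
           if keyword_config is None else dict(keyword_config))
    n_terms = len(go_terms)
    if n_terms < int(cfg["insufficient_terms"]):
        pts = int(cfg["insufficient_points"])
        return GoPenaltyResult(pts, (), n_terms, float(pts), True)
    blob = " | ".join(t.lower() for t in go_terms)
    hits: list[str] = []
    raw = 0
    for cat, spec in cfg["categories"].items():
        if any(kw.lower() in blob for kw in spec["keywords"]):
            hits.append(cat)
            raw += int(spec["points"])
    norm = raw / (n_terms ** float(cfg["normalization_power"]))
    return GoPenaltyResult(raw, tuple(hits), n_terms, norm, False)


def _keyword_patterns(keywords: Iterable[str]) -> list[re.Pattern]:
    pats = []
    for kw in keywords:
        if kw.startswith("*"):
            pats.append(re.compile(r"\b\w*" + re.escape(kw[1:]) + r"s?\b", re.I))
        else:
            pats.append(re.compile(r"\b" + re.escape(kw) + r"s?\b", re.I))
    return pats


def publication_counts(
    corpus: pd.DataFrame,
    annotation: GeneAnnotation,
    cancer_keywords: Sequence[str] | None = None,
) -> PublicationCounts:
    """Count corpus records mentioning the gene, and the cancer-titled subset.

    ``corpus`` holds one record per row with ``title`` and ``abstract``
    columns.  Gene aliases match on word boundaries over title+abstract;
    cancer keywords match the title only, with ``*``-prefixed entries
    matching any word ending in that suffix (e.g. ``*carcinoma`` matches
    adenocarcinoma).
    """
    if cancer_keywords is None:
        kw = dict(default_config())["cancer_keywords"]
        cancer_keywords = list(kw["core"]) + list(kw["extended"])
    alias_pat = re.compile(
        r"\b(?:" + "|".join(re.escape(a) for a in annotation.aliases) + r")\b", re.I
    )
    cancer_pats = _keyword_patterns(cancer_keywords)
    total = 0
    cancer = 0
    for _, rec in corpus.iterrows():
        title = str(rec.get("title", "") or "")
        abstract = str(rec.get("abstract", "") or "")
        if alias_pat.search(title + " " + abstract):
            total += 1
            if any(p.search(title) for p in cancer_pats):
                cancer += 1
    return PublicationCounts(annotation.gene, total, cancer)


def mutation_percentile(
    gene: str,
    per_gene_mutation_counts: Mapping[str, int] | pd.Series,
    missing: str = "neutral",
) -> float:
    """Midrank percentile of a gene's mutation count across all genes.

    percentile = 100 * (genes strictly below + 0.5 * ties) / total.  A
    gene absent from the table gets percentile 0 (neutral, no penalty)
    when ``missing='neutral'``; ``missing='error'`` raises instead.
    """
    counts = pd.Series(per_gene_mutation_counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("mutation table must cover at least 2 genes")
    if gene not in counts.index:
        if missing == "error":
            raise KeyError(f"gene {gene!r} absent from mutation table")
        return 0.0
    c = counts.loc[gene]
    below = float((counts < c).sum())
    ties = float((counts == c).sum())
    return 100.0 * (below + 0.5 * ties) / len(counts)
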
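"""Selection of a non-co-expressed pair of high-scoring reference genes.

Normalizing qPCR data against two reference genes is only safer than one
if the two genes do not rise and fall together; a co-expressed pair
duplicates the same bias.  Candidate pairs therefore require both genes
to clear the expression-score threshold and the absolute Spearman
correlation of their CPM profiles (over tumor samples, the larger pool)
to stay below a cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RGPair", "coexpression", "select_pair"]


@dataclass(frozen=True)
class RGPair:
    gene_a: str
    gene_b: str
    s_exp_a: float
    s_exp_b: float
    coexpression_r: float
    eligible: bool

    @property
    def objective(self) -> float:
        """Geometric mean of the two expression scores."""
        return math.sqrt(max(self.s_exp_a, 0.0) * max(self.s_exp_b, 0.0))


def coexpression(
    cpm: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    sample_subset: Sequence[str],
) -> float:
    """Spearman correlation of two genes' CPM over a sample subset.

    A constant expression vector has no rank ordering; its correlation is
    reported as 0 (treated as no evidence of co-expression).
    """
    if len(sample_subset) < 3:
        raise ValueError("co-expression needs at least 3 samples")
    a = cpm.loc[gene_a, list(sample_subset)].to_numpy(dtype=float)
    b = cpm.loc[gene_b, list(sample_subset)].to_numpy(dtype=float)
    if len(set(a)) < 2 or len(set(b)) < 2:
        return 0.0
    r, _ = stats.spearmanr(a, b)
    return float(r) if math.isfinite(r) else 0.0


def select_pair(
    s_exp: Mapping[str, float],
    cpm: pd.DataFrame,
    sample_subset: Sequence[str],
    score_threshold: float = 65.0,
    r_cutoff: float = 0.5,
) -> tuple[RGPair, list[RGPair]]:
    """Best reference-gene pair and the ranked eligible list.

    Among pairs with both expression scores above ``score_threshold`` and
    ``|r_s|`` below ``r_cutoff``, the pair maximizing the geometric mean
    of the two scores wins; ties break lexicographically on gene ids.  If
    no pair is eligible the best-objective pair overall is returned
    flagged ineligible.
    """
    genes = sorted(s_exp)
    if len(genes) < 2:
        raise ValueError("pair selection needs at least 2 scored genes")
    candidates = [g for g in genes if s_exp[g] > score_threshold]
    search = candidates if len(candidates) >= 2 else genes
    pairs: list[RGPair] = []
    for ga, gb in combinations(search, 2):
        r = coexpression(cpm, ga, gb, sample_subset)
        eligible = (
            min(s_exp[ga], s_exp[gb]) > score_threshold and abs(r) < r_cutoff
        )
        pairs.append(RGPair(ga, gb, s_exp[ga], s_exp[gb], r, eligible))
    pairs.sort(key=lambda p: (-p.objective, p.gene_a, p.gene_b))
    eligible_pairs = [p for p in pairs if p.eligible]
    best = eligible_pairs[0] if eligible_pairs else pairs[0]
    return best, eligible_pairs
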
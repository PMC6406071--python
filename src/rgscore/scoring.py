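"""Parametric scoring of reference-gene suitability.

Every scoring component maps a per-gene variable ``x`` (a fold change, a
relative standard deviation, a correlation coefficient, an annotation
count, ...) onto the 0-100 scale with one common sigma-like function

    S = 100 / (1 + Sq * (max(x - IV, 0) / (IP - IV))**CS)

parameterised by an ideal value ``IV`` (everything at or below it scores
100), an inflection point ``IP`` (with ``Sq`` = 1 the score there is
exactly 50), a curve slope ``CS``, and a squeeze factor ``Sq``.  The
expression components are aggregated into a weighted geometric mean
``S_exp``; annotation-derived "anti-scorings" (mutation-rate percentile,
transcript-isoform count, pseudogene count) then multiplicatively reduce
it to the final suitability score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import default_config

__all__ = [
    "ScoringParams",
    "ComponentSpec",
    "ComponentInstance",
    "ComponentValue",
    "GeneScoreCard",
    "PanCancerResult",
    "component_score",
    "build_component_registry",
    "aggregate_expression_score",
    "anti_scores",
    "final_score",
    "pan_cancer_score",
]

#: component ids in canonical (registry) order
EXPRESSION_COMPONENT_IDS = (
    "S_DP", "S_DL", "S_DoO", "S_DoU", "S_DLc",
    "S_EStD", "S_EoH", "S_EoL", "S_EA", "S_Cp", "S_Cr",
)
ANTI_SCORING_IDS = ("S_Mut", "S_Isoforms", "S_Pseudogenes")


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of one scoring component's response curve."""

    IV: float
    IP: float
    CS: float
    Sq: float = 1.0
    CA: float = 0.0
    W: float = 1.0

    def __post_init__(self) -> None:
        if not self.IP > self.IV:
            raise ValueError(f"IP ({self.IP}) must exceed IV ({self.IV})")
        if self.CS <= 0 or self.Sq <= 0 or self.W <= 0 or self.CA < 0:
            raise ValueError(
                f"invalid params: CS={self.CS}, Sq={self.Sq}, W={self.W}, CA={self.CA}"
            )

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "ScoringParams":
        return cls(**{k: float(v) for k, v in m.items()})


@dataclass(frozen=True)
class ComponentSpec:
    """One scoring component: identity, feature kind, curve parameters."""

    id: str
    variable_kind: str
    params: ScoringParams
    n_applied: int = 1


@dataclass(frozen=True)
class ComponentInstance:
    """A single application of a component (e.g. S_EStD on the tumor pool)."""

    spec_id: str
    instance_label: str
    params: ScoringParams


@dataclass(frozen=True)
class ComponentValue:
    """A scored component instance for one gene."""

    spec_id: str
    instance_label: str
    x: float
    score: float


@dataclass
class GeneScoreCard:
    """All suitability scores of one gene in one condition."""

    gene: str
    components: list[ComponentValue]
    s_exp: float
    s_mut: float = 100.0
    s_isoforms: float = 100.0
    s_pseudogenes: float = 100.0
    s_final: float = float("nan")
    advisory: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class PanCancerResult:
    """Cross-condition aggregate suitability of one gene."""

    gene: str
    per_condition: list[tuple[str, float, float]]  # (condition, s_exp, s_mut)
    s_exp_mut_pan: float
    s_final_pan: float
    m: int
    k: float
    ca: float
    flags: list[str] = field(default_factory=list)


def component_score(x: float, params: ScoringParams) -> float:
    """Score a variable with the parametric sigma-like response curve.

    Returns 100 for ``x <= IV``, 100/(1+Sq) at ``x = IP``, and decays
    towards 0 as ``x`` grows.  ``x`` must be finite; a non-finite value
    signals a fault in upstream feature extraction.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite scored variable x={x!r}; upstream feature fault")
    excess = max(x - params.IV, 0.0)
    if excess == 0.0:
        return 100.0
    return 100.0 / (1.0 + params.Sq * (excess / (params.IP - params.IV)) ** params.CS)


def build_component_registry(
    config: Mapping | None = None,
    *,
    strict: bool = True,
) -> list[ComponentInstance]:
    """Expand the component table into the full list of scored instances.

    With the default configuration (six clinical characteristics, three
    expression measures) the registry holds exactly 48 instances:
    S_DP, S_DL, S_DoO, S_DoU, S_DLc and S_EA once each, S_EStD / S_EoH /
    S_EoL once per pool (normal, tumor), and S_Cp / S_Cr once per
    (measure, characteristic) combination, 18 each.

    In strict mode a clinical-characteristic list whose length is not six
    raises ``ValueError``; lenient mode accepts any list (an empty one
    yields a 12-instance registry with no correlation components).
    """
    cfg = dict(default_config()) if config is None else dict(config)
    chars: Sequence[str] = cfg["clinical_characteristics"]
    measures: Sequence[str] = cfg["correlation_measures"]
    if strict and len(chars) != 6:
        raise ValueError(
            f"strict mode requires exactly 6 clinical characteristics, got {len(chars)}"
        )
    params = {
        cid: ScoringParams.from_mapping(cfg["components"][cid]["params"])
        for cid in EXPRESSION_COMPONENT_IDS
    }
    registry: list[ComponentInstance] = []
    for cid in ("S_DP", "S_DL", "S_DoO", "S_DoU", "S_DLc"):
        registry.append(ComponentInstance(cid, cid, params[cid]))
    for cid in ("S_EStD", "S_EoH", "S_EoL"):
        for pool in ("normal", "tumor"):
            registry.append(ComponentInstance(cid, f"{cid}:{pool}", params[cid]))
    registry.append(ComponentInstance("S_EA", "S_EA", params["S_EA"]))
    for cid in ("S_Cp", "S_Cr"):
        for measure in measures:
            for char in chars:
                registry.append(
                    ComponentInstance(cid, f"{cid}:{measure}:{char}", params[cid])
                )
    return registry


def aggregate_expression_score(
    components: Iterable[ComponentValue],
    registry: Sequence[ComponentInstance],
) -> float:
    """Weighted geometric mean of the component scores.

    Each instance contributes ``min(S_i + CA_i, 100)`` raised to its
    weight; the product is taken to the power ``1 / sum(W_i)``.  The
    clamp preserves the theoretical maximum of 100.  Every registry
    instance must be matched by exactly one component value.
    """
    by_label = {c.instance_label: c for c in components}
    log_sum = 0.0
    w_sum = 0.0
    for inst in registry:
        cv = by_label.get(inst.instance_label)
        if cv is None:
            raise ValueError(f"missing component instance {inst.instance_label!r}")
        term = min(cv.score + inst.params.CA, 100.0)
        if term <= 0.0:
            return 0.0
        log_sum += inst.params.W * math.log(term)
        w_sum += inst.params.W
    return math.exp(log_sum / w_sum)


def anti_scores(
    mutation_percentile: float,
    n_isoforms: int,
    n_pseudogenes: int,
    config: Mapping | None = None,
) -> tuple[float, float, float]:
    """Score the three annotation penalties (mutation, isoforms, pseudogenes)."""
    cfg = dict(default_config()) if config is None else dict(config)
    anti = cfg["anti_scorings"]
    if not 0.0 <= mutation_percentile <= 100.0:
        raise ValueError(f"mutation percentile {mutation_percentile} outside [0, 100]")
    if n_isoforms < 0 or n_pseudogenes < 0:
        raise ValueError("annotation counts must be non-negative")
    s_mut = component_score(
        mutation_percentile, ScoringParams.from_mapping(anti["S_Mut"]["params"])
    )
    s_iso = component_score(
        float(n_isoforms), ScoringParams.from_mapping(anti["S_Isoforms"]["params"])
    )
    s_pse = component_score(
        float(n_pseudogenes), ScoringParams.from_mapping(anti["S_Pseudogenes"]["params"])
    )
    return s_mut, s_iso, s_pse


def final_score(
    s_exp: float, s_mut: float, s_isoforms: float, s_pseudogenes: float
) -> float:
    """Combine the expression score with the anti-scorings.

    Each anti-scoring multiplies as a 0-1 fraction so the result stays on
    the 0-100 scale; rankings are unchanged by this rescaling.
    """
    for name, v in (("s_exp", s_exp), ("s_mut", s_mut),
                    ("s_isoforms", s_isoforms), ("s_pseudogenes", s_pseudogenes)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return s_exp * (s_mut / 100.0) * (s_isoforms / 100.0) * (s_pseudogenes / 100.0)


def pan_cancer_score(
    per_condition: Sequence[tuple[str, float, float]],
    s_isoforms: float,
    s_pseudogenes: float,
    *,
    k: float = -0.4,
    ca: float = 12.0,
    gene: str = "",
    flags: Sequence[str] = (),
) -> PanCancerResult:
    """Aggregate per-condition scores into a pan-cancer suitability score.

    The combined per-condition value ``v_j = s_exp_j * s_mut_j / 100`` is
    shifted by the constant add ``ca`` and pooled with a power mean of
    exponent ``k`` (negative ``k`` behaves like a harmonic mean, rewarding
    genes that are consistently good rather than occasionally excellent):

        s_exp_mut_pan = (mean_j (v_j + ca)**k) ** (1/k)

    For identical inputs the aggregate equals ``v + ca``; the offset is
    kept as-is since only the ranking is consumed downstream.  The final
    pan score multiplies by the isoform and pseudogene anti-scorings.
    """
    if len(per_condition) == 0:
        raise ValueError("per_condition must not be empty")
    v = np.array([se * (sm / 100.0) for _, se, sm in per_condition], dtype=float)
    pan = float(np.mean((v + ca) ** k) ** (1.0 / k))
    s_final_pan = pan * (s_isoforms / 100.0) * (s_pseudogenes / 100.0)
    return PanCancerResult(
        gene=gene,
        per_condition=list(per_condition),
        s_exp_mut_pan=pan,
        s_final_pan=s_final_pan,
        m=len(per_condition),
        k=k,
        ca=ca,
        flags=list(flags),
    )
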
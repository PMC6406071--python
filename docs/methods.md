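# Methods

## Model

`rgscore` treats reference-gene (RG) suitability as a multi-component
scoring problem rather than a hypothesis test. Every per-gene feature
*x* that argues against a gene's use as a qPCR reference — a tumor/normal
fold change, within-pool variability, correlation with clinical course,
an annotation count — is mapped to the 0–100 scale by one parametric
curve

    S = 100 / (1 + Sq · (max(x − IV, 0) / (IP − IV))^CS)

This is a reversed sigmoid with a flat saturation region: any `x ≤ IV`
("ideal value") scores exactly 100, the score is `100/(1+Sq)` at the
inflection point `IP` (50 for the usual `Sq = 1`), and the curve slope
`CS` controls how sharply the score collapses beyond `IP`. The parameter
sets shipped in `src/rgscore/data/registry.yaml` encode judgments about
what is tolerable per feature; for example the pooled fold-change
component `S_DP` uses `IV = 0.05, IP = 0.25` — mRNA changes below ~3.5%
are ignored, a ~19% change already halves the component.

Eleven expression components expand to 48 scored instances per gene
(stability components once per pool, correlation components once per
{tumor CPM, normal CPM, paired log2FC} × {pathologic T, N, M, stage,
neoplasm status, treatment success}). Aggregation is a weighted geometric
mean of `min(S_i + CA_i, 100)` with exponents `W_i`:

    S_exp = (Π min(S_i + CA_i, 100)^{W_i})^{1/Σ W_i}

The constant summands `CA_i` keep a single zeroed minor component from
annihilating the product; `S_DP`, `S_DL` and `S_EA` deliberately carry
`CA = 0` so that a gross tumor/normal difference or a too-low expression
level *does* zero the gene. The clamp at 100 preserves the theoretical
maximum of 100; it only matters when a `CA_i` would push a
near-saturated component above it.

### Anti-scorings and the final score

Mutation-rate percentile (midrank percentile of the gene's somatic
mutation count across all genes in the condition), transcript-isoform
count and pseudogene count are scored with the same curve
(`S_Mut`: IV 75, IP 95, CS 4; `S_Isoforms`: IV 1, IP 3, CS 2, Sq 0.4;
`S_Pseudogenes`: IV 0, IP 2, CS 2, Sq 0.4) and multiply the expression
score as 0–1 fractions:

    S_final = S_exp · (S_Mut/100) · (S_Isoforms/100) · (S_Pseudogenes/100)

Dividing every factor after the first by 100 keeps all composite scores
on the 0–100 scale; rankings are invariant to this normalization.

### Pan-cancer aggregation

Per-condition combined values `v_j = S_exp,j · S_Mut,j / 100` are pooled
with a power mean of exponent `k = −0.4` after a constant add `CA = 12`:

    S_pan = (mean_j (v_j + CA)^k)^{1/k}

A negative exponent behaves like a harmonic mean: one bad condition
drags the aggregate down much more than one excellent condition lifts
it, which is the right shape for a "universal" reference gene. The
formula carries a `+CA` offset (identical inputs return `v + CA`); the
offset is kept as printed since only the ranking is consumed, and the
report records `k`, `CA` and `M` alongside the values. Genes missing
from some conditions are aggregated over the conditions they have, with
`M` set to that count and a `partial:` flag (the CLI defaults to the
intersection of gene universes instead).

### Advisory columns

GO keyword penalties (six cancer-process categories worth 5+4+3+2+2+2 =
18 points, matched case-insensitively as substrings of GO term names;
fewer than 3 terms → flat 10 points without depth normalization;
otherwise normalized by `n_terms^0.3`) and publication counts over a
local abstract corpus (word-boundary alias matching in title+abstract;
cancer keywords matched in titles only, with `*suffix` wildcards) are
reported but never multiplied into `S_final` — they exist for manual
exclusion of cancer-involved genes.

## Normalization

TMM scaling factors are re-implemented following the published
trimmed-mean-of-M-values procedure: reference sample = the one whose
upper-quartile count proportion is closest to the panel mean; per-sample
log2 ratios against the reference are trimmed 30% on each side by M and
5% by A; surviving M values are averaged with inverse delta-method
variance weights; factors are rescaled to geometric mean 1. CPM divides
by library size × factor. The implementation reproduces Bioconductor
edgeR's `calcNormFactors(method="TMM")` to ~1e-9 on the fixed matrices
frozen in the tests, which serve as the independent oracle. All-zero
genes are excluded from factor estimation but retained as zero CPM rows.

## Numerical conventions

- **Percentile trimming.** A value with 1-based sorted position `i` out
  of `n` survives the lo–hi trim iff `lo/100 ≤ (i − 0.5)/n < hi/100`
  (upper bound inclusive when `hi = 100`). Deciles use the same rule; if
  a decile window captures no value (possible for `n < 6`), the single
  value whose fractional rank is nearest the window midpoint is used.
  The test oracle is an independent sort-and-slice implementation of the
  same convention.
- **Pseudocount.** ε = 0.25 CPM is added inside every log2 ratio. It is
  small relative to the 2-CPM expression floor, so it only matters for
  genes that are already being pushed to score 0.
- **Expression floor.** Genes with trimmed-mean tumor CPM < 2 keep their
  output row but receive an `S_EA` sentinel mapping to score 0 (with
  `W = 6` this effectively removes them from contention) — rows are
  therefore stable across runs and conditions.
- **Clinical encodings.** Pathologic T/N/M keep their numeric part
  (TX/NX/MX/Tis → missing); stage I–IV → 1–4 with sub-letters stripped;
  neoplasm status tumor free/with tumor → 0/1; treatment success ordered
  complete remission (0) → progressive disease (3). Spearman p-values
  use the two-sided t approximation; combinations with fewer than 3
  informative patients or a constant variable are scored maximally
  stable (r = 0, p = 1) and flagged. The 10–90 band restriction of each
  expression measure breaks CPM ties by sample id so results are
  invariant to input column order.
- **Degenerate inputs.** Non-finite feature values reaching
  `component_score` raise; the model layer converts only the documented
  sentinels (low expression) to score 0 with a flag. Datasets without
  tumor–normal pairs fall back to the pooled fold change for the paired
  components and neutral correlations for the paired measure, with a
  warning.
- Closed-form expectations in tests are asserted at relative tolerance
  1e-9; the aggregation oracle (sympy at 30 digits) at 1e-10.

## Pair selection

Co-expression is the Spearman correlation of two genes' CPM over tumor
samples (the larger pool); a constant vector yields r = 0 (no evidence).
Eligible pairs need both `S_exp > 65` and `|r_s| < 0.5`; among them the
pair maximizing the geometric mean of the two scores wins, with
lexicographic tie-breaks. The 0.5 cutoff and the geometric-mean
objective are package choices (config-exposed); selection is verified
against exhaustive pair enumeration in tests.

## Synthetic data

The generator emulates the structure of TCGA-like inputs, not their
content: negative-binomial (gamma–Poisson) counts around per-gene CPM
targets, log-normal library sizes (mean 2×10⁶, σ = 0.3), paired samples
sharing patient ids, and ordinal clinical characteristics driven by a
per-patient latent severity variable that also shifts the tumor
expression of "clinically associated" genes (a Gaussian-copula-style
coupling on ranks). The default panel cycles through realistic failure
modes — stable genes with annotation handicaps, 1–2-fold shifted genes
(alternating direction so the panel has no net compositional drift,
as in real libraries where stage-associated genes move both ways),
over-dispersed genes, outlier-prone genes, clinically associated genes,
low-expression genes — plus a single designed clean gene (`RG_IDEAL`).
Because a 50-gene panel is a far larger DE fraction than a genome-wide
matrix, balanced shift directions matter: one-sided shifts of a sixth of
the panel would bias any scale normalization, which is a property of the
small test-bed, not of the method.

What passing tests show: the pipeline recovers designed rankings under
count noise, paired structure and clinical coupling at desk scale
(50 genes, 60 tumor / 30 normal / 30 pairs, 20 seeds). What they do not
show: behavior under batch effects, tumor purity gradients, subtype
heterogeneity, or genome-scale composition — none of which the
generator attempts to mimic.

## Problem sizes

Default test and reproduction runs use 12–50-gene panels with 10–60
samples per pool and up to 20 seeds; one full 50-gene condition scores
in well under a second, so the entire ranking-recovery study runs in a
few seconds on one CPU.

## Known limitations

- TMM on very small panels (tens of genes) is sensitive to asymmetric
  differential expression; with genome-scale matrices this vanishes.
- The Spearman p-value t approximation is inaccurate below ~10
  observations; such combinations are usually caught by the ≥3-patient
  guard but intermediate sizes are approximate.
- The GO penalty matches directly assigned term names only — no
  ontology-graph propagation — so sparsely annotated genes lean on the
  flat insufficient-annotation penalty.
- The pan-cancer `+CA` offset means pan scores are not directly
  comparable to per-condition `S_final` values; compare ranks, not
  magnitudes.
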
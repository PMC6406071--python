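# rgscore

Scoring of candidate **reference genes (RGs) for qPCR normalization** from
bulk RNA-seq read counts of tumor and matched normal samples.

qPCR quantification is only as reliable as the reference gene it is
normalized against, and in cancer studies the usual suspects (*GAPDH*,
*ACTB*, ...) are often anything but stable. Given a per-condition (e.g. per
cancer type) gene × sample count matrix, a sample sheet with tumor/normal
labels and patient ids, and a clinical table, `rgscore` ranks every gene by
a multi-component expression-stability score, penalizes genes that are
inconvenient in practice (high mutation rate, many transcript isoforms,
pseudogenes), aggregates scores across conditions into a pan-cancer
ranking, and proposes an optimal pair of non-co-expressed reference genes
per condition.

## The scoring system

Counts are TMM-normalized and rescaled to counts per million (CPM). Every
per-gene feature *x* — a trimmed fold change, a relative standard
deviation, a correlation — is mapped onto 0–100 by one parametric
sigma-like curve

```
S = 100 / (1 + Sq · (max(x − IV, 0) / (IP − IV))^CS)
```

where `IV` is the *ideal value* (everything at or below it scores 100),
`IP` the *inflection point* (score 50 when `Sq = 1`), `CS` the curve slope
and `Sq` a squeeze factor. Eleven expression components expand to **48
scored instances** per gene:

| component | feature | instances |
|---|---|---|
| S_DP, S_DL | pooled / paired trimmed \|log2 FC\| (10–90th pct) | 1 + 1 |
| S_DoO, S_DoU | top / bottom decile of paired log2 FC | 1 + 1 |
| S_DLc | mean trimmed \|log2 FC\| per pair | 1 |
| S_EStD | trimmed SD(CPM)/mean(CPM) per pool | 2 |
| S_EoH, S_EoL | high / low expression outlier contrast per pool | 2 + 2 |
| S_EA | 1/log2(trimmed mean tumor CPM) | 1 |
| S_Cp, S_Cr | Spearman p / \|r_s\| vs 6 clinical characteristics × 3 measures | 18 + 18 |

The expression score is a weighted geometric mean,
`S_exp = (Π (S_i + CA_i)^{W_i})^{1/ΣW_i}`, with constant summands `CA_i`
softening zeros and weights `W_i` from the shipped registry
(`src/rgscore/data/registry.yaml`). Three *anti-scorings* — mutation-rate
percentile, transcript-isoform count, pseudogene count — multiply in as
0–1 fractions: `S_final = S_exp · S_mut/100 · S_iso/100 · S_pseudo/100`.
Cross-condition suitability uses a negative-exponent power mean
(`k = −0.4`, constant add 12), which behaves like a harmonic mean and
rewards genes that are consistently good in every condition. GO keyword
penalties (six cancer-process categories, max 18 points) and publication
counts over a local abstract corpus are advisory columns only.

## Worked example

```python
import rgscore as rg

spec = rg.SyntheticSpec(profiles=rg.make_default_panel(24), n_tumor=20,
                        n_normal=12, n_pairs=12, seed=7, condition="DEMO")
data = rg.generate_dataset(spec)
model = rg.StabilityModel(data.to_expression_dataset(),
                          annotations=data.annotations,
                          mutation_counts=data.mutation_counts,
                          corpus=data.corpus, condition="DEMO")
results = model.fit()
print(results.summary())
```

prints

```
Reference-gene expression stability scoring
==============================================
condition: DEMO
genes: 24   tumor: 20   normal: 12   pairs: 12
component instances: 48

Top 5 genes by S_exp:
    gene    s_exp    s_mut  s_isoforms  s_pseudogenes  s_final
RG_IDEAL     98.0    100.0       100.0          100.0     98.0
    G019     95.4     56.4        38.5           71.4     14.8
    G013     95.4     36.7        71.4           71.4     17.9
    G001     95.4    100.0        71.4           71.4     48.6
    G022     90.3    100.0       100.0           90.9     82.1

Best pair: G019 + RG_IDEAL (S_exp 95.4/98.0, r_s=0.44, eligible)
```

`RG_IDEAL` — the panel's designed clean gene (stable, highly expressed,
one isoform, no pseudogenes, low mutation rate) — keeps its expression
score through the anti-scorings, while equally stable genes with
annotation handicaps (e.g. `G019`: mutation percentile penalty, four
isoforms, pseudogenes) drop sharply in `S_final`. The suggested pair
combines two high-`S_exp` genes whose CPM profiles are not co-expressed
(|r_s| below the 0.5 cutoff).

The same flows are available from the shell: `rgscore generate`,
`rgscore score`, `rgscore pairs` and `rgscore pan-cancer` (see
`rgscore --help`); `results.frame` / the written TSVs carry the full
per-component breakdown.

## Layout

- `src/rgscore/scoring.py` — parametric curve, 48-instance registry, S_exp
  aggregation, anti-scorings, pan-cancer power mean
- `src/rgscore/features.py` — TMM/CPM, trimmed statistics, fold changes,
  pool stability, clinical correlations
- `src/rgscore/annotations.py` — GO penalty, publication counts, mutation
  percentile
- `src/rgscore/pairs.py` — co-expression and optimal pair selection
- `src/rgscore/synthetic.py` — TCGA-like synthetic fixture generator
- `src/rgscore/model.py` — `StabilityModel`/`StabilityResults`,
  `PanCancerModel`/`PanCancerResults`
- `src/rgscore/cli.py` — command-line interface
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and limitations
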
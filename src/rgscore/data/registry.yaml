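# Default scoring-component registry and keyword lists.
#
# Each expression component maps a per-gene feature x onto a 0-100 score via
#   S = 100 / (1 + Sq * (max(x - IV, 0) / (IP - IV))**CS)
# IV: ideal value (saturation bound), IP: inflection point, CS: curve slope,
# Sq: squeeze, CA: constant summand used during aggregation, W: weight in the
# weighted geometric mean.

components:
  S_DP:
    description: "Tumor-normal expression difference, pooled samples: |log2FC_P| on 10-90 trimmed pool means"
    params: {IV: 0.05, IP: 0.25, CS: 2.5, Sq: 1.0, CA: 0.0, W: 4.0}
  S_DL:
    description: "Tumor-normal expression difference, paired samples: |mean of 10-90 trimmed per-pair log2FC_L|"
    params: {IV: 0.05, IP: 0.25, CS: 2.5, Sq: 1.0, CA: 0.0, W: 4.0}
  S_DoO:
    description: "Paired-difference outliers, overexpression: |mean of top decile of log2FC_L|"
    params: {IV: 0.1, IP: 0.7, CS: 2.5, Sq: 1.0, CA: 10.0, W: 1.0}
  S_DoU:
    description: "Paired-difference outliers, underexpression: |mean of bottom decile of log2FC_L|"
    params: {IV: 0.1, IP: 0.7, CS: 2.5, Sq: 1.0, CA: 10.0, W: 1.0}
  S_DLc:
    description: "Cumulative paired difference: mean of 10-90 trimmed |log2FC_L|"
    params: {IV: 0.1, IP: 0.5, CS: 2.5, Sq: 1.0, CA: 5.0, W: 2.0}
  S_EStD:
    description: "Within-pool stability: trimmed StDev(CPM)/trimmed Average(CPM), one instance per pool"
    params: {IV: 0.1, IP: 0.3, CS: 2.0, Sq: 1.0, CA: 5.0, W: 1.5}
  S_EoH:
    description: "Within-pool high-expression outliers: log2(top-decile mean CPM / trimmed mean CPM)"
    params: {IV: 0.1, IP: 0.7, CS: 2.5, Sq: 1.0, CA: 5.0, W: 0.75}
  S_EoL:
    description: "Within-pool low-expression outliers: log2(trimmed mean CPM / bottom-decile mean CPM)"
    params: {IV: 0.1, IP: 0.7, CS: 2.5, Sq: 1.0, CA: 5.0, W: 0.75}
  S_EA:
    description: "Average expression level: 1/log2(trimmed mean CPM of the tumor pool)"
    params: {IV: 0.07, IP: 0.15, CS: 3.0, Sq: 1.0, CA: 0.0, W: 6.0}
  S_Cp:
    description: "Clinical correlation p-values: -log2(p), 3 expression measures x 6 characteristics"
    params: {IV: 2.0, IP: 4.0, CS: 3.0, Sq: 0.3, CA: 5.0, W: 0.3}
  S_Cr:
    description: "Clinical correlation coefficients: |Spearman r_s|, 3 expression measures x 6 characteristics"
    params: {IV: 0.1, IP: 0.25, CS: 2.5, Sq: 0.3, CA: 5.0, W: 0.2}

anti_scorings:
  S_Mut:
    description: "Percentile of somatic mutation rate across genes"
    params: {IV: 75.0, IP: 95.0, CS: 4.0, Sq: 1.0, CA: 0.0, W: 1.0}
  S_Isoforms:
    description: "Number of annotated transcript isoforms"
    params: {IV: 1.0, IP: 3.0, CS: 2.0, Sq: 0.4, CA: 0.0, W: 1.0}
  S_Pseudogenes:
    description: "Number of pseudogenes"
    params: {IV: 0.0, IP: 2.0, CS: 2.0, Sq: 0.4, CA: 0.0, W: 1.0}

# Expression measures and clinical characteristics crossed to form the 18
# correlation instances (3 x 6) of S_Cp and S_Cr each.
correlation_measures: [tumor_cpm, normal_cpm, paired_log2fc]
clinical_characteristics:
  - pathologic_t
  - pathologic_n
  - pathologic_m
  - pathologic_stage
  - neoplasm_cancer_status
  - treatment_success

pan_cancer: {k: -0.4, CA: 12.0}

thresholds:
  pseudocount_cpm: 0.25     # added inside every log2 ratio
  min_tumor_cpm: 2.0        # trimmed-mean tumor CPM floor; below -> S_EA sentinel
  score_threshold: 65.0     # pair eligibility on S^Exp
  r_cutoff: 0.5             # pair co-expression cutoff on |r_s|
  top_k: 5

tmm: {logratio_trim: 0.3, abundance_trim: 0.05}

go_penalty:
  insufficient_terms: 3
  insufficient_points: 10
  normalization_power: 0.3
  categories:
    cell_cycle:
      points: 5
      keywords: [cell cycle, cell division, cell growth, cell proliferation,
                 apoptosis, apoptotic process, cell death, MAPK cascade,
                 tumor, oncogenic, apoptotic]
    differentiation:
      points: 4
      keywords: [cell differentiation, epithelial to mesenchymal transition,
                 mesenchymal to epithelial transition, stem cell, fetal,
                 embryonic, embryonal, embryo, gastrulation, tissue development,
                 cellular developmental process, organ development]
    stress_response:
      points: 3
      keywords: [response to stress, DNA damage, DNA repair]
    immune_response:
      points: 2
      keywords: [inflammation, inflammatory, immune response,
                 T cell activation, macrophage activation, antigen]
    angiogenesis:
      points: 2
      keywords: [angiogenesis]
    intercellular_interactions:
      points: 2
      keywords: [cell communication, cell-cell signaling, cell adhesion,
                 cell motility, cell migration]

# Title keywords marking a publication as cancer-related; entries starting
# with '*' match any word with that suffix. The first six are the core list;
# the remainder are a documented extension of the open-ended tail.
cancer_keywords:
  core: [cancer, tumor, "*carcinoma", sarcoma, glioma, glioblastoma]
  extended: [leukemia, lymphoma, melanoma, neoplasm, oncogene, metastasis]
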
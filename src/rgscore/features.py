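"""Per-gene expression features feeding the stability scoring components.

Raw read counts are TMM-normalized and rescaled to counts per million
(CPM).  From the CPM matrix, the sample sheet and the clinical table this
module derives, per gene:

* pooled and paired tumor/normal log2 fold changes on percentile-trimmed
  means, plus decile (outlier) summaries of the paired fold changes;
* within-pool stability: the trimmed relative standard deviation and the
  high/low expression-outlier contrasts, separately for the normal and
  tumor pools;
* the average-expression term ``1/log2(trimmed mean tumor CPM)``;
* Spearman correlations of three expression measures (tumor CPM, normal
  CPM, paired log2 fold change) with six ordinal clinical
  characteristics — 18 (r_s, p) pairs.

Percentile trimming uses the fractional-rank convention: a value with
sorted position ``i`` (1-based) out of ``n`` survives the lo-hi trim iff
``lo/100 <= (i - 0.5)/n < hi/100`` (the upper bound is inclusive for
hi = 100).  If a decile window captures no value, the single value whose
fractional rank is nearest the window midpoint is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import default_config

__all__ = [
    "ExpressionDataset",
    "GeneExpressionFeatures",
    "tmm_normalize",
    "trimmed_stat",
    "pooled_log2fc",
    "paired_log2fc",
    "pool_stability",
    "clinical_correlations",
    "encode_clinical",
    "extract_features",
]

logger = logging.getLogger(__name__)

CLINICAL_CHARACTERISTICS = (
    "pathologic_t",
    "pathologic_n",
    "pathologic_m",
    "pathologic_stage",
    "neoplasm_cancer_status",
    "treatment_success",
)
CORRELATION_MEASURES = ("tumor_cpm", "normal_cpm", "paired_log2fc")

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}
_STATUS = {"tumor free": 0.0, "with tumor": 1.0}
_TREATMENT = {
    "complete remission": 0.0,
    "complete remission/response": 0.0,
    "partial remission": 1.0,
    "partial remission/response": 1.0,
    "stable disease": 2.0,
    "progressive disease": 3.0,
}


# ---------------------------------------------------------------------------
# normalization

def tmm_normalize(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scaling factors and the normalized CPM matrix.

    The trimmed-mean-of-M-values procedure: pick the reference sample
    whose upper-quartile count proportion is closest to the mean upper
    quartile; for every other sample compute per-gene log ratios (M) and
    average log abundances (A) against the reference, discard genes with
    a zero in either sample, trim the most extreme ``logratio_trim``
    fraction by M and ``abundance_trim`` fraction by A on each side, and
    average the surviving M values weighted by inverse asymptotic
    (delta-method) variances.  Factors are rescaled to geometric mean 1.

    All-zero genes are excluded from factor estimation but retained (as
    zeros) in the CPM matrix.  CPM divides each column by its effective
    library size (library size times factor) and multiplies by 1e6.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")

    nonzero = mat[mat.sum(axis=1) > 0]
    p = nonzero / lib
    f75 = np.quantile(p, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(mat.shape[1])
    ref = nonzero[:, ref_idx]
    n_ref = lib[ref_idx]
    for k in range(mat.shape[1]):
        if k == ref_idx:
            continue
        factors[k] = _tmm_pair(
            nonzero[:, k], ref, lib[k], n_ref, logratio_trim, abundance_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))

    factors = pd.Series(factors, index=counts.columns, name="tmm_factor")
    cpm = counts / (lib * factors.to_numpy()) * 1e6
    return factors, cpm


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abundance_trim) -> float:
    """TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(log_r)) < 1e-6:  # identical proportions
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * abundance_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(log_r)
    rank_s = stats.rankdata(abs_e)
    kept = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not kept.any() or var[kept].min() <= 0:
        return 1.0
    f = np.sum(log_r[kept] / var[kept]) / np.sum(1.0 / var[kept])
    return float(2.0 ** f) if math.isfinite(f) else 1.0


# ---------------------------------------------------------------------------
# trimmed statistics

def _trim_select(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Sorted values surviving the lo-hi percentile trim (may fall back to one)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    frac = (np.arange(1, n + 1) - 0.5) / n
    mask = (frac >= lo / 100.0) & (frac < hi / 100.0 if hi < 100 else frac <= 1.0)
    if not mask.any():
        mid = (lo + hi) / 200.0
        return v[[int(np.argmin(np.abs(frac - mid)))]]
    return v[mask]


def trimmed_stat(
    values: Sequence[float],
    lo_percentile: float,
    hi_percentile: float,
    stat: str = "mean",
) -> float:
    """Mean or standard deviation over a percentile-trimmed value set."""
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    if not 0 <= lo_percentile < hi_percentile <= 100:
        raise ValueError(f"bad percentile bounds ({lo_percentile}, {hi_percentile})")
    kept = _trim_select(np.asarray(values, dtype=float), lo_percentile, hi_percentile)
    if stat == "mean":
        return float(kept.mean())
    if stat == "stdev":
        if kept.size < 2:
            raise ValueError("fewer than 2 surviving values for stdev")
        return float(kept.std(ddof=1))
    raise ValueError(f"unknown stat {stat!r}")


# ---------------------------------------------------------------------------
# dataset container

@dataclass
class ExpressionDataset:
    """Counts, CPM, sample metadata and clinical table for one condition."""

    counts: pd.DataFrame
    cpm: pd.DataFrame
    samples: pd.DataFrame        # index sample_id; columns patient_id, tissue
    pairs: list[tuple[str, str]]  # (tumor sample, normal sample), same patient
    clinical: pd.DataFrame       # index patient_id; six characteristic columns
    tmm_factors: pd.Series | None = None

    @classmethod
    def from_tables(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        clinical: pd.DataFrame,
        config: Mapping | None = None,
    ) -> "ExpressionDataset":
        """Build a dataset: run TMM/CPM and derive tumor-normal pairs.

        ``samples`` needs columns ``patient_id`` and ``tissue``
        (tumor|normal) indexed by sample id; pairs are every patient with
        exactly one tumor and one normal sample.
        """
        cfg = dict(default_config()) if config is None else dict(config)
        missing = set(samples.index) - set(counts.columns)
        if missing:
            raise ValueError(f"sample sheet entries without count columns: {sorted(missing)}")
        counts = counts[samples.index.tolist()]
        tmm_cfg = cfg.get("tmm", {})
        factors, cpm = tmm_normalize(
            counts,
            logratio_trim=tmm_cfg.get("logratio_trim", 0.3),
            abundance_trim=tmm_cfg.get("abundance_trim", 0.05),
        )
        bad = samples.loc[~samples["tissue"].isin(["tumor", "normal"])]
        if len(bad):
            raise ValueError(f"unknown tissue labels: {bad['tissue'].unique().tolist()}")
        pairs = []
        for patient, grp in samples.groupby("patient_id"):
            t = grp.index[grp["tissue"] == "tumor"].tolist()
            n = grp.index[grp["tissue"] == "normal"].tolist()
            if len(t) >= 1 and len(n) >= 1:
                pairs.append((t[0], n[0]))
        pairs.sort()
        return cls(counts=counts, cpm=cpm, samples=samples, pairs=pairs,
                   clinical=clinical, tmm_factors=factors)

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples.index[self.samples["tissue"] == "tumor"].tolist()

    @property
    def normal_samples(self) -> list[str]:
        return self.samples.index[self.samples["tissue"] == "normal"].tolist()


# ---------------------------------------------------------------------------
# fold changes

def pooled_log2fc(
    cpm: pd.DataFrame,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    eps: float = 0.25,
) -> pd.Series:
    """log2 ratio of 10-90 trimmed-mean CPM, tumor pool over normal pool."""
    if len(tumor_samples) == 0 or len(normal_samples) == 0:
        raise ValueError("both pools must be non-empty")
    t = _rowwise_trimmed_mean(cpm[list(tumor_samples)].to_numpy(), 10, 90)
    n = _rowwise_trimmed_mean(cpm[list(normal_samples)].to_numpy(), 10, 90)
    if eps == 0 and ((t == 0) | (n == 0)).any():
        raise ValueError("zero trimmed-mean CPM with eps=0; use a pseudocount")
    return pd.Series(np.log2((t + eps) / (n + eps)), index=cpm.index, name="log2fc_p")


def paired_log2fc(
    cpm: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    eps: float = 0.25,
) -> pd.DataFrame:
    """Per-pair log2(tumor CPM / normal CPM); one column per pair."""
    if len(pairs) == 0:
        raise ValueError("at least one tumor-normal pair required")
    cols = {}
    for t, n in pairs:
        if t not in cpm.columns or n not in cpm.columns:
            raise ValueError(f"pair ({t!r}, {n!r}) references a missing sample")
        cols[t] = np.log2((cpm[t].to_numpy() + eps) / (cpm[n].to_numpy() + eps))
    return pd.DataFrame(cols, index=cpm.index)


def _rowwise_trimmed_mean(mat: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trimmed mean per row under the fractional-rank convention."""
    n = mat.shape[1]
    frac = (np.arange(1, n + 1) - 0.5) / n
    mask = (frac >= lo / 100.0) & (frac < hi / 100.0 if hi < 100 else frac <= 1.0)
    srt = np.sort(mat, axis=1)
    if not mask.any():
        mid = (lo + hi) / 200.0
        return srt[:, int(np.argmin(np.abs(frac - mid)))]
    return srt[:, mask].mean(axis=1)


def _rowwise_trimmed_std(mat: np.ndarray, lo: float, hi: float) -> np.ndarray:
    n = mat.shape[1]
    frac = (np.arange(1, n + 1) - 0.5) / n
    mask = (frac >= lo / 100.0) & (frac < hi / 100.0 if hi < 100 else frac <= 1.0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 surviving values for stdev")
    return np.sort(mat, axis=1)[:, mask].std(axis=1, ddof=1)


# ---------------------------------------------------------------------------
# pool stability

def pool_stability(
    cpm_pool: pd.DataFrame,
    eps: float = 0.25,
    min_cpm: float = 2.0,
) -> pd.DataFrame:
    """Within-pool stability features, one row per gene.

    Columns: ``relsd`` (trimmed SD over trimmed mean), ``outlier_hi``
    (log2 of top-decile mean over trimmed mean), ``outlier_lo`` (log2 of
    trimmed mean over bottom-decile mean), ``trimmed_mean`` and
    ``inv_log2_cpm`` (1/log2 of the trimmed mean; +inf sentinel when the
    trimmed mean falls below ``min_cpm``, mapping to score 0 downstream).
    """
    mat = cpm_pool.to_numpy(dtype=float)
    if mat.shape[1] < 10:
        logger.warning(
            "pool of %d samples: decile statistics are unstable below 10", mat.shape[1]
        )
    mean_mid = _rowwise_trimmed_mean(mat, 10, 90)
    mean_top = _rowwise_trimmed_mean(mat, 90, 100)
    mean_bot = _rowwise_trimmed_mean(mat, 0, 10)
    sd_mid = _rowwise_trimmed_std(mat, 10, 90)
    with np.errstate(divide="ignore", invalid="ignore"):
        relsd = np.where(mean_mid > 0, sd_mid / mean_mid, np.inf)
    outlier_hi = np.log2((mean_top + eps) / (mean_mid + eps))
    outlier_lo = np.log2((mean_mid + eps) / (mean_bot + eps))
    inv = np.full(mean_mid.shape, np.inf)
    ok = mean_mid >= min_cpm
    inv[ok] = 1.0 / np.log2(mean_mid[ok])
    return pd.DataFrame(
        {
            "relsd": relsd,
            "outlier_hi": outlier_hi,
            "outlier_lo": outlier_lo,
            "trimmed_mean": mean_mid,
            "inv_log2_cpm": inv,
        },
        index=cpm_pool.index,
    )


# ---------------------------------------------------------------------------
# clinical correlations

def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Ordinal encoding of the six clinical characteristics.

    pathologic T/N/M keep their numeric part (Tis/TX/NX/MX and empty ->
    missing); stage I..IV -> 1..4 with sub-letters stripped; neoplasm
    cancer status tumor free/with tumor -> 0/1; treatment success ordered
    from complete remission (0) to progressive disease (3).
    """
    out = pd.DataFrame(index=clinical.index, dtype=float)
    for col, prefix in (("pathologic_t", "T"), ("pathologic_n", "N"), ("pathologic_m", "M")):
        out[col] = clinical[col].map(lambda v: _tnm_number(v, prefix))
    out["pathologic_stage"] = clinical["pathologic_stage"].map(_stage_number)
    out["neoplasm_cancer_status"] = clinical["neoplasm_cancer_status"].map(
        lambda v: _STATUS.get(str(v).strip().lower(), np.nan)
    )
    out["treatment_success"] = clinical["treatment_success"].map(
        lambda v: _TREATMENT.get(str(v).strip().lower(), np.nan)
    )
    return out


def _tnm_number(value, prefix: str) -> float:
    s = str(value).strip().upper()
    if not s or s in ("NAN", f"{prefix}X", f"{prefix}IS"):
        return np.nan
    if s.startswith(prefix) and len(s) > 1 and s[1].isdigit():
        return float(s[1])
    if s.isdigit():
        return float(s)
    return np.nan


def _stage_number(value) -> float:
    s = str(value).strip().upper()
    if s.startswith("STAGE"):
        s = s[5:].strip()
    s = s.rstrip("ABC")
    return float(_ROMAN.get(s, np.nan))


def clinical_correlations(
    measures: Mapping[str, tuple[pd.Series, pd.Series]],
    clinical_encoded: pd.DataFrame,
    characteristics: Sequence[str] = CLINICAL_CHARACTERISTICS,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Spearman (r_s, p) of each expression measure with each characteristic.

    ``measures`` maps a measure name to ``(values, patient_ids)`` — the
    per-sample (or per-pair) expression values, already restricted to the
    10-90 percentile band, with their patients.  A combination with fewer
    than 3 non-missing patients, or with a constant variable on either
    side, is returned as the maximally stable (0.0, 1.0) and flagged via
    a warning.  p-values use the two-sided t approximation.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for mname, (values, patients) in measures.items():
        clin = clinical_encoded.reindex(pd.Index(patients))
        for char in characteristics:
            y = clin[char].to_numpy(dtype=float)
            x = np.asarray(values, dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or len(set(y[ok])) < 2 or len(set(x[ok])) < 2:
                out[(mname, char)] = (0.0, 1.0)
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            if not math.isfinite(r):
                r, p = 0.0, 1.0
            out[(mname, char)] = (float(r), float(min(max(p, np.nextafter(0, 1)), 1.0)))
    return out


# ---------------------------------------------------------------------------
# per-gene feature bundle

@dataclass
class GeneExpressionFeatures:
    """The per-gene x-values feeding the 48 expression component instances."""

    gene: str
    log2fc_p: float
    avg_log2fc_l_10_90: float
    avg_log2fc_l_90_100: float
    avg_log2fc_l_0_10: float
    avg_abs_log2fc_l_10_90: float
    relsd_normal: float
    relsd_tumor: float
    outlier_hi_normal: float
    outlier_hi_tumor: float
    outlier_lo_normal: float
    outlier_lo_tumor: float
    inv_log2_cpm: float
    correlations: dict[tuple[str, str], tuple[float, float]]
    flags: list[str] = field(default_factory=list)

    def x_values(self) -> dict[str, float]:
        """Map features onto registry instance labels (x per instance)."""
        x = {
            "S_DP": abs(self.log2fc_p),
            "S_DL": abs(self.avg_log2fc_l_10_90),
            "S_DoO": abs(self.avg_log2fc_l_90_100),
            "S_DoU": abs(self.avg_log2fc_l_0_10),
            "S_DLc": self.avg_abs_log2fc_l_10_90,
            "S_EStD:normal": self.relsd_normal,
            "S_EStD:tumor": self.relsd_tumor,
            "S_EoH:normal": abs(self.outlier_hi_normal),
            "S_EoH:tumor": abs(self.outlier_hi_tumor),
            "S_EoL:normal": abs(self.outlier_lo_normal),
            "S_EoL:tumor": abs(self.outlier_lo_tumor),
            "S_EA": self.inv_log2_cpm,
        }
        for (measure, char), (r, p) in self.correlations.items():
            x[f"S_Cp:{measure}:{char}"] = -math.log2(p)
            x[f"S_Cr:{measure}:{char}"] = abs(r)
        return x


def _band_values(row: np.ndarray, ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Values (and their sample/pair ids) inside the 10-90 percentile band."""
    n = row.size
    order = np.lexsort((np.asarray(ids), row))  # ties broken by id: order-invariant
    frac = (np.arange(1, n + 1) - 0.5) / n
    mask = (frac >= 0.10) & (frac < 0.90)
    if not mask.any():
        mask = np.ones(n, dtype=bool)
    idx = order[mask]
    return row[idx], [ids[i] for i in idx]


def extract_features(
    dataset: ExpressionDataset,
    config: Mapping | None = None,
) -> dict[str, GeneExpressionFeatures]:
    """All per-gene expression features for one condition dataset.

    Genes whose trimmed-mean tumor CPM is below the configured floor keep
    their row but get the average-expression sentinel (downstream score
    0), so output rows are stable across runs.  Datasets without
    tumor-normal pairs fall back to pooled fold changes for the paired
    components, with a warning.
    """
    cfg = dict(default_config()) if config is None else dict(config)
    thresholds = cfg["thresholds"]
    eps = float(thresholds["pseudocount_cpm"])
    min_cpm = float(thresholds["min_tumor_cpm"])
    chars = cfg["clinical_characteristics"]

    tumor = dataset.tumor_samples
    normal = dataset.normal_samples
    cpm = dataset.cpm
    genes = cpm.index.tolist()

    fc_p = pooled_log2fc(cpm, tumor, normal, eps=eps)
    stab_n = pool_stability(cpm[normal], eps=eps, min_cpm=min_cpm)
    stab_t = pool_stability(cpm[tumor], eps=eps, min_cpm=min_cpm)

    have_pairs = len(dataset.pairs) > 0
    if have_pairs:
        fc_l = paired_log2fc(cpm, dataset.pairs, eps=eps)
        pair_mat = fc_l.to_numpy()
        pair_patients = [
            str(dataset.samples.loc[t, "patient_id"]) for t, _ in dataset.pairs
        ]
    else:
        logger.warning("dataset has no tumor-normal pairs; paired components "
                       "fall back to pooled fold changes")

    clin_enc = encode_clinical(dataset.clinical)
    tumor_patients = [str(dataset.samples.loc[s, "patient_id"]) for s in tumor]
    normal_patients = [str(dataset.samples.loc[s, "patient_id"]) for s in normal]
    tumor_mat = cpm[tumor].to_numpy()
    normal_mat = cpm[normal].to_numpy()

    out: dict[str, GeneExpressionFeatures] = {}
    for gi, gene in enumerate(genes):
        flags: list[str] = []
        if have_pairs:
            row = pair_mat[gi]
            srt = np.sort(row)
            l_mid = trimmed_stat(srt, 10, 90, "mean")
            l_hi = trimmed_stat(srt, 90, 100, "mean")
            l_lo = trimmed_stat(srt, 0, 10, "mean")
            l_abs = trimmed_stat(np.abs(row), 10, 90, "mean")
        else:
            l_mid = l_hi = l_lo = fc_p.iloc[gi]
            l_abs = abs(fc_p.iloc[gi])
            flags.append("no_pairs_pooled_fallback")

        measures = {
            "tumor_cpm": _band_values(tumor_mat[gi], tumor_patients),
            "normal_cpm": _band_values(normal_mat[gi], normal_patients),
        }
        if have_pairs:
            measures["paired_log2fc"] = _band_values(pair_mat[gi], pair_patients)
        corr = clinical_correlations(
            {k: (v, ids) for k, (v, ids) in measures.items()}, clin_enc, chars
        )
        if not have_pairs:
            for char in chars:
                corr[("paired_log2fc", char)] = (0.0, 1.0)

        inv = float(stab_t.loc[gene, "inv_log2_cpm"])
        if not math.isfinite(inv):
            flags.append("low_expression")

        out[gene] = GeneExpressionFeatures(
            gene=gene,
            log2fc_p=float(fc_p.iloc[gi]),
            avg_log2fc_l_10_90=float(l_mid),
            avg_log2fc_l_90_100=float(l_hi),
            avg_log2fc_l_0_10=float(l_lo),
            avg_abs_log2fc_l_10_90=float(l_abs),
            relsd_normal=float(stab_n.loc[gene, "relsd"]),
            relsd_tumor=float(stab_t.loc[gene, "relsd"]),
            outlier_hi_normal=float(stab_n.loc[gene, "outlier_hi"]),
            outlier_hi_tumor=float(stab_t.loc[gene, "outlier_hi"]),
            outlier_lo_normal=float(stab_n.loc[gene, "outlier_lo"]),
            outlier_lo_tumor=float(stab_t.loc[gene, "outlier_lo"]),
            inv_log2_cpm=inv,
            correlations=corr,
            flags=flags,
        )
    return out
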
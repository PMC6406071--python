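"""Synthetic TCGA-like fixtures for end-to-end testing of the pipeline.

Generates a gene x sample read-count matrix with designated gene
profiles (stable, tumor-shifted, noisy, outlier-prone, clinically
associated, low-expression), matched tumor/normal samples sharing
patient ids, a per-patient clinical table, gene annotations (isoform /
pseudogene / mutation counts, GO terms, aliases) and a small abstract
corpus — everything the scoring pipeline consumes, in the same TSV
dialects, with no download.

Counts are drawn negative-binomially (gamma-Poisson) around per-gene
CPM targets scaled by log-normally varying library sizes.  Clinical
association is induced through a per-patient latent severity variable
shared between the ordinal clinical characteristics and the tumor
expression of associated genes (a Gaussian copula on ranks).  Generation
is fully reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations import GeneAnnotation
from .features import ExpressionDataset

__all__ = ["GeneProfile", "SyntheticSpec", "SyntheticData",
           "make_default_panel", "generate_dataset", "write_dataset"]

NEUTRAL_GO_TERMS = (
    "rRNA processing", "tRNA modification", "ribosome biogenesis",
    "RNA splicing", "translation", "mRNA 3'-end processing",
    "protein folding", "vesicle docking",
)
CANCER_GO_TERMS = (
    "cell cycle", "regulation of cell proliferation", "apoptotic process",
    "cell differentiation", "response to stress", "immune response",
    "angiogenesis", "cell adhesion",
)


@dataclass(frozen=True)
class GeneProfile:
    """Generative parameters of one synthetic gene."""

    name: str
    base_cpm: float = 200.0
    tumor_shift: float = 0.0       # log2 tumor/normal shift
    dispersion: float = 0.005      # NB dispersion (var = mu + phi*mu^2)
    outlier_frac: float = 0.0      # per-sample probability of an outlier
    outlier_mag: float = 3.0       # log2 magnitude of an outlier
    clinical_assoc: float = 0.0    # latent-severity coupling (log2 per SD)
    n_isoforms: int = 1
    n_pseudogenes: int = 0
    mutation_rate: float = 5.0     # Poisson mean of the somatic-mutation count
    cancer_go: bool = False
    label: str = "stable"          # stable | ideal | shifted | noisy | outlier | clinical | low

    def __post_init__(self) -> None:
        if self.label in ("stable", "ideal"):
            assert abs(self.tumor_shift) <= 0.05 and self.clinical_assoc == 0.0


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic condition dataset."""

    profiles: list[GeneProfile]
    n_tumor: int = 60
    n_normal: int = 30
    n_pairs: int = 30
    seed: int = 0
    mean_library_size: float = 2e6
    library_size_sigma: float = 0.3
    condition: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_pairs > min(self.n_tumor, self.n_normal):
            raise ValueError(
                f"n_pairs={self.n_pairs} exceeds min(n_tumor, n_normal)="
                f"{min(self.n_tumor, self.n_normal)}"
            )


@dataclass
class SyntheticData:
    """Everything one scoring run consumes, as in-memory tables."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    clinical: pd.DataFrame
    annotations: dict[str, GeneAnnotation]
    mutation_counts: pd.Series
    corpus: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def to_expression_dataset(self, config=None) -> ExpressionDataset:
        return ExpressionDataset.from_tables(
            self.counts, self.samples, self.clinical, config=config
        )


def make_default_panel(n_genes: int = 50) -> list[GeneProfile]:
    """A deterministic panel with one designed ideal reference gene.

    Gene ``RG_IDEAL`` is the only fully clean profile (stable, highly
    expressed, one isoform, no pseudogenes, near-zero mutations).  The
    rest of the panel cycles through realistic failure modes: stable
    genes with annotation handicaps, 1-2-fold tumor shifts, dispersed or
    outlier-prone genes, clinically associated genes and low-expression
    genes.
    """
    if n_genes < 6:
        raise ValueError("panel needs at least 6 genes")
    profiles = [GeneProfile(
        name="RG_IDEAL", base_cpm=600.0, tumor_shift=0.0, dispersion=0.003,
        mutation_rate=0.5, n_isoforms=1, n_pseudogenes=0, label="ideal",
    )]
    kinds = ("stable_handicap", "shifted", "noisy", "outlier", "clinical", "low")
    for i in range(1, n_genes):
        kind = kinds[(i - 1) % len(kinds)]
        name = f"G{i:03d}"
        if kind == "stable_handicap":
            profiles.append(GeneProfile(
                name=name, base_cpm=300.0 + 40 * (i % 7), dispersion=0.004,
                n_isoforms=2 + i % 4, n_pseudogenes=(i % 3) + 1,
                mutation_rate=20.0 + 5 * (i % 5), label="stable",
            ))
        elif kind == "shifted":
            occ = i // 6  # alternate direction and vary magnitude across occurrences
            shift = (1.0 + 0.5 * (occ % 3)) * (1 if occ % 2 else -1)
            profiles.append(GeneProfile(
                name=name, base_cpm=250.0, tumor_shift=shift,
                dispersion=0.01, mutation_rate=30.0, label="shifted",
            ))
        elif kind == "noisy":
            profiles.append(GeneProfile(
                name=name, base_cpm=220.0, dispersion=0.4,
                mutation_rate=25.0, n_isoforms=3, label="noisy",
            ))
        elif kind == "outlier":
            profiles.append(GeneProfile(
                name=name, base_cpm=260.0, dispersion=0.01,
                outlier_frac=0.06, outlier_mag=3.5,
                mutation_rate=25.0, n_pseudogenes=1, label="outlier",
            ))
        elif kind == "clinical":
            # alternating sign: real stage-associated genes move in both
            # directions, so the panel has no net compositional drift
            profiles.append(GeneProfile(
                name=name, base_cpm=240.0, dispersion=0.01,
                clinical_assoc=0.45 * (1 if (i // 6) % 2 else -1), mutation_rate=25.0,
                cancer_go=True, label="clinical",
            ))
        else:  # low
            profiles.append(GeneProfile(
                name=name, base_cpm=1.0, dispersion=0.05,
                mutation_rate=10.0, label="low",
            ))
    return profiles


def generate_dataset(spec: SyntheticSpec) -> SyntheticData:
    """Draw one complete synthetic condition dataset from a spec."""
    rng = np.random.default_rng(spec.seed)
    genes = [p.name for p in spec.profiles]

    # patients: paired ones carry both a tumor and a normal sample
    n_patients_t = spec.n_tumor
    patients_t = [f"P{i:03d}" for i in range(n_patients_t)]
    tumor_samples = [f"T_{p}" for p in patients_t]
    normal_patients = patients_t[: spec.n_pairs] + [
        f"P{i:03d}" for i in range(n_patients_t, n_patients_t + spec.n_normal - spec.n_pairs)
    ]
    normal_samples = [f"N_{p}" for p in normal_patients]
    all_patients = sorted(set(patients_t) | set(normal_patients))

    samples = pd.DataFrame(
        {
            "patient_id": [s[2:] for s in tumor_samples + normal_samples],
            "tissue": ["tumor"] * len(tumor_samples) + ["normal"] * len(normal_samples),
        },
        index=pd.Index(tumor_samples + normal_samples, name="sample_id"),
    )

    # latent severity per tumor patient drives stage/TNM and associated genes
    severity = {p: rng.normal() for p in patients_t}
    clinical = _clinical_table(all_patients, severity, rng)

    lib = rng.lognormal(
        mean=np.log(spec.mean_library_size), sigma=spec.library_size_sigma,
        size=len(samples),
    )

    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    is_tumor = (samples["tissue"] == "tumor").to_numpy()
    sample_patients = samples["patient_id"].to_numpy()
    for gi, prof in enumerate(spec.profiles):
        log2_mu = np.full(len(samples), np.log2(prof.base_cpm))
        log2_mu[is_tumor] += prof.tumor_shift
        if prof.clinical_assoc:
            z = np.array([severity.get(p, 0.0) for p in sample_patients])
            log2_mu[is_tumor] += prof.clinical_assoc * z[is_tumor]
        if prof.outlier_frac > 0:
            hits = rng.random(len(samples)) < prof.outlier_frac
            log2_mu[hits] += prof.outlier_mag
        mu = (2.0 ** log2_mu) * lib / 1e6
        if prof.dispersion > 0:
            lam = rng.gamma(1.0 / prof.dispersion, prof.dispersion * mu)
        else:
            lam = mu
        counts[gi] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=samples.index)

    annotations: dict[str, GeneAnnotation] = {}
    mut = {}
    for prof in spec.profiles:
        mut_count = int(rng.poisson(prof.mutation_rate))
        terms = list(CANCER_GO_TERMS if prof.cancer_go else NEUTRAL_GO_TERMS[:5])
        annotations[prof.name] = GeneAnnotation(
            gene=prof.name,
            aliases=[prof.name, f"{prof.name}-alias"],
            n_isoforms=prof.n_isoforms,
            n_pseudogenes=prof.n_pseudogenes,
            mutation_count=mut_count,
            go_terms=terms,
        )
        mut[prof.name] = mut_count
    mutation_counts = pd.Series(mut, name="mutation_count")

    corpus = _corpus(genes, rng)

    manifest = {
        "seed": spec.seed,
        "condition": spec.condition,
        "n_genes": len(genes),
        "n_tumor": spec.n_tumor,
        "n_normal": spec.n_normal,
        "n_pairs": spec.n_pairs,
        "profiles": [asdict(p) for p in spec.profiles],
    }
    return SyntheticData(counts_df, samples, clinical, annotations,
                         mutation_counts, corpus, manifest)


def _clinical_table(patients: Sequence[str], severity: dict, rng) -> pd.DataFrame:
    stages = ["Stage I", "Stage II", "Stage III", "Stage IV"]
    rows = {}
    for p in patients:
        z = severity.get(p, rng.normal())
        zn = z + 0.6 * rng.normal()  # noisy copies keep the ordinal structure
        stage = stages[int(np.clip(np.digitize(z, [-0.5, 0.3, 1.0]), 0, 3))]
        t = f"T{int(np.clip(np.digitize(zn, [-0.8, 0.0, 0.9]), 0, 3)) + 1}"
        n = f"N{int(np.clip(np.digitize(z + 0.8 * rng.normal(), [0.2, 1.2]), 0, 2))}"
        m = "M1" if z + rng.normal() > 1.8 else "M0"
        status = "with tumor" if z + 0.8 * rng.normal() > 0.6 else "tumor free"
        treat = ["complete remission", "partial remission",
                 "stable disease", "progressive disease"][
            int(np.clip(np.digitize(z + 0.8 * rng.normal(), [0.2, 1.0, 1.7]), 0, 3))
        ]
        rows[p] = (t, n, m, stage, status, treat)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["pathologic_t", "pathologic_n", "pathologic_m",
                 "pathologic_stage", "neoplasm_cancer_status", "treatment_success"],
    ).rename_axis("patient_id")


def _corpus(genes: Sequence[str], rng) -> pd.DataFrame:
    """A tiny abstract corpus mentioning a subset of the panel genes."""
    records = []
    cancer_titles = (
        "Expression of {g} in breast cancer",
        "{g} drives adenocarcinoma progression",
        "The role of {g} in glioblastoma",
    )
    neutral_titles = (
        "{g} in ribosome assembly",
        "Structural basis of {g} function",
    )
    rid = 1
    for g in genes[: min(len(genes), 12)]:
        n_cancer = int(rng.integers(0, 3))
        n_neutral = int(rng.integers(1, 3))
        for j in range(n_cancer):
            records.append((f"R{rid:04d}", cancer_titles[j % 3].format(g=g),
                            f"We study {g} in tumors."))
            rid += 1
        for j in range(n_neutral):
            records.append((f"R{rid:04d}", neutral_titles[j % 2].format(g=g),
                            f"Biochemistry of {g}."))
            rid += 1
    return pd.DataFrame(records, columns=["id", "title", "abstract"])


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write all tables in the TSV dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "clinical": outdir / "clinical.tsv",
        "mutations": outdir / "mutations.tsv",
        "annotation": outdir / "annotation.tsv",
        "go_terms": outdir / "go_terms.tsv",
        "corpus": outdir / "corpus.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    data.counts.to_csv(paths["counts"], sep="\t")
    data.samples.to_csv(paths["samples"], sep="\t")
    data.clinical.to_csv(paths["clinical"], sep="\t")
    data.mutation_counts.rename_axis("gene").to_csv(paths["mutations"], sep="\t")
    ann_rows = [
        {
            "gene": a.gene,
            "aliases": ";".join(a.aliases),
            "n_isoforms": a.n_isoforms,
            "n_pseudogenes": a.n_pseudogenes,
            "mutation_count": a.mutation_count,
        }
        for a in data.annotations.values()
    ]
    pd.DataFrame(ann_rows).to_csv(paths["annotation"], sep="\t", index=False)
    go_rows = [
        {"gene": a.gene, "go_terms": ";".join(a.go_terms)}
        for a in data.annotations.values()
    ]
    pd.DataFrame(go_rows).to_csv(paths["go_terms"], sep="\t", index=False)
    data.corpus.to_csv(paths["corpus"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(data.manifest, fh, sort_keys=True)
    return paths
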
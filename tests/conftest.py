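import numpy as np
import pandas as pd
import pytest

import rgscore as rg


@pytest.fixture(scope="session")
def small_panel_data():
    """A 24-gene, 20T/12N synthetic condition shared across tests."""
    spec = rg.SyntheticSpec(
        profiles=rg.make_default_panel(24), n_tumor=20, n_normal=12,
        n_pairs=12, seed=7, condition="SYN7",
    )
    return spec, rg.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_results(small_panel_data):
    spec, data = small_panel_data
    model = rg.StabilityModel(
        data.to_expression_dataset(), annotations=data.annotations,
        mutation_counts=data.mutation_counts, corpus=data.corpus,
        condition="SYN7",
    )
    return model.fit()


@pytest.fixture()
def toy_counts():
    """5-gene, 2-sample count matrix with one strongly DE gene."""
    return pd.DataFrame(
        {"A": [100, 200, 300, 400, 1000], "B": [80, 160, 240, 320, 4000]},
        index=pd.Index([f"g{i}" for i in range(1, 6)], name="gene"),
        dtype=float,
    )


def make_dataset(cpm_rows, n_tumor=10, n_normal=10, paired=True, seed=0):
    """ExpressionDataset straight from target CPM rows (counts == CPM)."""
    rng = np.random.default_rng(seed)
    genes = list(cpm_rows)
    tumor = [f"T{i:02d}" for i in range(n_tumor)]
    normal = [f"N{i:02d}" for i in range(n_normal)]
    patients = [f"P{i:02d}" for i in range(max(n_tumor, n_normal))]
    counts = pd.DataFrame(
        {s: [cpm_rows[g][0][i] for g in genes] for i, s in enumerate(tumor)}
        | {s: [cpm_rows[g][1][i] for g in genes] for i, s in enumerate(normal)},
        index=pd.Index(genes, name="gene"),
    )
    samples = pd.DataFrame(
        {
            "patient_id": patients[:n_tumor] + patients[:n_normal],
            "tissue": ["tumor"] * n_tumor + ["normal"] * n_normal,
        },
        index=pd.Index(tumor + normal, name="sample_id"),
    )
    stages = ["Stage I", "Stage II", "Stage III", "Stage IV"]
    clinical = pd.DataFrame(
        {
            "pathologic_t": [f"T{rng.integers(1, 5)}" for _ in patients],
            "pathologic_n": [f"N{rng.integers(0, 3)}" for _ in patients],
            "pathologic_m": [f"M{rng.integers(0, 2)}" for _ in patients],
            "pathologic_stage": [stages[rng.integers(0, 4)] for _ in patients],
            "neoplasm_cancer_status": [
                ["tumor free", "with tumor"][rng.integers(0, 2)] for _ in patients
            ],
            "treatment_success": [
                ["complete remission", "partial remission",
                 "stable disease", "progressive disease"][rng.integers(0, 4)]
                for _ in patients
            ],
        },
        index=pd.Index(patients, name="patient_id"),
    )
    if not paired:
        samples["patient_id"] = [f"Q{i:03d}" for i in range(len(samples))]
        clinical = clinical.copy()
        clinical.index = pd.Index([f"Q{i:03d}" for i in range(len(clinical))],
                                  name="patient_id")
    return rg.ExpressionDataset.from_tables(counts, samples, clinical)
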
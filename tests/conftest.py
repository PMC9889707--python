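import numpy as np
import pandas as pd
import pytest

import carstim as cs
from carstim.gating import is_feature_column


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (8 healthy + 8 patient donors, 6 doses)."""
    return cs.generate_cohort(cs.GenerationConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return cs.gate_table(
        list(default_cohort.samples.values()),
        cs.GatingStrategy(),
        metadata=default_cohort.manifest,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return cs.generate_cohort(
        cs.GenerationConfig(n_healthy=3, n_patient=3, n_events_per_sample=150, seed=11)
    )


@pytest.fixture(scope="session")
def patient_lodo_rows(default_features):
    """Paired (blood, product) -> dose rows for the patient stratum."""
    table = default_features
    fcols = [c for c in table.columns if is_feature_column(c)]
    blood = table[(table.stage == "blood") & (table.status == "patient")].reset_index(
        drop=True
    )
    prods = table[(table.stage == "product") & (table.status == "patient")].reset_index(
        drop=True
    )
    return cs.build_regression_rows(blood, prods, fcols)


def dose_step_table(seed: int = 7):
    """Five balanced dose levels, ten tiny nuisance features, labels a step
    function of dose alone: separable by every classifier family."""
    rng = np.random.default_rng(seed)
    doses = np.repeat([2.0, 5.0, 10.0, 20.0, 30.0], 24)
    n = len(doses)
    table = pd.DataFrame(
        {f"pct_noise_{i:02d}": 0.1 * rng.standard_normal(n) for i in range(10)}
    )
    table["dose_pg_per_cell"] = doses
    table["sample_id"] = [f"s{i}" for i in range(n)]
    labels = np.searchsorted([4, 8, 15, 25], doses)
    return table, labels


def planted_blob_pool(seed: int = 3, n_per_product: int = 300):
    """Nine products drawn from three well-separated marker-space blobs;
    product cytotoxicity is determined by the blob (10 / 50 / 90 %)."""
    rng = np.random.default_rng(seed)
    markers = list(cs.MarkerPanel())
    centers = rng.choice([-4.0, 0.0, 4.0], size=(3, len(markers)))
    cyto = {0: 10.0, 1: 50.0, 2: 90.0}
    frames = []
    for p in range(9):
        blob = p % 3
        x = centers[blob] + rng.standard_normal((n_per_product, len(markers)))
        df = pd.DataFrame(x - x.min() + 1.0, columns=markers)
        df["sample_id"] = f"prod{p}"
        df["cytotoxicity"] = cyto[blob]
        df["true_blob"] = blob
        frames.append(df)
    return pd.concat(frames, ignore_index=True), markers
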
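import numpy as np
import pandas as pd
import pytest

from lncfuse.simulate import SimulationConfig, simulate_cohort
from lncfuse.survival import SurvivalTable


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully featured cohort with planted effects of every kind."""
    cfg = SimulationConfig(
        n_tumor=40,
        n_normal=15,
        n_mrna=300,
        n_lnc=80,
        de_fraction=0.15,
        lfc_effect=2.0,
        n_coreg_pairs=12,
        complementary_fraction=0.5,
        signature_size=3,
        beta_true=(1.0, -1.0, 1.0),
        censor_rate=0.3,
        seed=42,
    )
    return simulate_cohort(cfg)


def cohort_logcpm(cohort, tumor_only=True) -> pd.DataFrame:
    """Plain log2-CPM of the cohort counts (features x samples)."""
    sheet = cohort.sample_sheet
    cols = sheet.index[sheet["group"] == "tumor"] if tumor_only else sheet.index
    counts = cohort.counts.loc[:, cols]
    lib = counts.sum(axis=0)
    return np.log2((counts + 0.5) / lib * 1e6)


def cohort_survival_table(cohort, features=None) -> SurvivalTable:
    """SurvivalTable over tumor samples with log2-CPM expression."""
    sheet = cohort.sample_sheet
    tumor = sheet.index[sheet["group"] == "tumor"]
    expr = cohort_logcpm(cohort)
    if features is None:
        features = [f for f in cohort.counts.index if f.startswith("LNC")]
    return SurvivalTable(
        expression=expr.loc[features, tumor].T,
        os_days=sheet.loc[tumor, "os_days"],
        event=sheet.loc[tumor, "event"].astype(int),
    )


@pytest.fixture(scope="session")
def small_survival(small_cohort):
    return cohort_survival_table(small_cohort)
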
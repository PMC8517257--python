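import numpy as np
import pandas as pd
import pytest

from statin_pgx.phenotyping import derive_phenotypes
from statin_pgx.synthetic_ehr import SimConfig, VariantSimSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized event-level cohort under study-default settings."""
    return simulate_cohort(SimConfig(n_patients=4000, seed=42))


@pytest.fixture(scope="session")
def default_phenotypes(default_cohort):
    c = default_cohort
    return derive_phenotypes(c.prescriptions, c.labs, c.demographics)


@pytest.fixture(scope="session")
def two_variant_config():
    """Light two-variant architecture matching the study's positive pair:
    ABCB1-like recessive at MAF 0.48 and LILRB5-like dominant at MAF 0.40."""
    return SimConfig(
        n_patients=4000,
        seed=0,
        variant_specs=[
            VariantSimSpec("rs1045642", 0.48, "recessive", 0.09),
            VariantSimSpec("rs12975366", 0.40, "dominant", 0.04),
        ],
        interaction_effect_mmol_per_l=0.01,
    )


def make_labs(patient_id, dated_values, base="2010-06-01"):
    """Lab table from (offset_days, non_hdl) pairs relative to `base`;
    HDL fixed at 1.0 so total = non_hdl + 1."""
    base = pd.Timestamp(base)
    rows = [{"patient_id": patient_id,
             "date": base + pd.Timedelta(days=off),
             "total_cholesterol": val + 1.0,
             "hdl_cholesterol": 1.0}
            for off, val in dated_values]
    return pd.DataFrame(rows)


def make_rx(patient_id, scripts, base="2010-06-01"):
    """Prescription table from (offset_days, statin, strength, quantity,
    directions) tuples relative to `base`."""
    base = pd.Timestamp(base)
    rows = [{"patient_id": patient_id,
             "dispense_date": base + pd.Timedelta(days=off),
             "statin_type": statin, "strength_mg": strength,
             "quantity": quantity, "directions": directions}
            for off, statin, strength, quantity, directions in scripts]
    return pd.DataFrame(rows)
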
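import pandas as pd
import pytest

import mwascreen as mw


@pytest.fixture(scope="session")
def vocab():
    return mw.load_vocabulary(mw.data_path("toy_vocabulary.csv"))


@pytest.fixture(scope="session")
def drug_map():
    return mw.DrugMap.read_csv(mw.data_path("drug_map.csv"))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully populated simulated cohort (shared, read-only)."""
    cfg = mw.default_config(n_patients=1500, seed=20260924)
    return mw.simulate(cfg)


@pytest.fixture()
def tiny_tables():
    """Hand-written four-table fixture: two patients, two deliveries."""
    patients = pd.DataFrame(
        {"patient_id": ["P1", "P2"], "birth_date": ["1985-03-15", "1990-07-01"]}
    )
    deliveries = pd.DataFrame(
        {
            "patient_id": ["P1", "P2"],
            "delivery_id": ["D1", "D2"],
            "delivery_date": ["2015-06-01", "2016-02-10"],
        }
    )
    diagnoses = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2"],
            "date": ["2015-06-01", "2015-02-21", "2016-02-10"],
            "code": ["O82", "O14.1", "644.21"],
        }
    )
    orders = pd.DataFrame(
        {
            "patient_id": ["P1", "P1", "P2"],
            "order_date": ["2015-03-01", "2015-05-31", "2016-02-10"],
            "drug_name": ["Tamiflu", "oseltamivir", "heparin"],
        }
    )
    return patients, deliveries, orders, diagnoses
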
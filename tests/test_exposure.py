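import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mwascreen as mw
from mwascreen.exposure import (
    apply_min_patient_filter,
    build_exposures,
    in_exposure_window,
)


def _dt(s):
    return pd.Timestamp(s)


class TestWindow:
    def test_boundaries_against_inequality(self):
        """Brute-force every offset 0..400 against the stated rule:
        in-window iff delivery-280 <= order <= delivery-1."""
        delivery = _dt("2015-06-01")
        for offset in range(0, 401):
            expected = 1 <= offset <= 280
            assert in_exposure_window(delivery - pd.Timedelta(days=offset), delivery) == expected, offset

    def test_order_on_delivery_day_excluded(self):
        assert not in_exposure_window(_dt("2015-06-01"), _dt("2015-06-01"))

    @settings(deadline=None, max_examples=60)
    @given(
        offset=st.integers(min_value=-30, max_value=400),
        shift=st.integers(min_value=-2000, max_value=2000),
    )
    def test_translation_invariance(self, offset, shift):
        d = _dt("2014-01-15")
        base = in_exposure_window(d - pd.Timedelta(days=offset), d)
        moved = in_exposure_window(
            d - pd.Timedelta(days=offset) + pd.Timedelta(days=shift),
            d + pd.Timedelta(days=shift),
        )
        assert base == moved


def _cohort(rows):
    return pd.DataFrame(rows, columns=["patient_id", "delivery_id", "delivery_date"])


def _orders(rows):
    return pd.DataFrame(rows, columns=["patient_id", "order_date", "drug_name"])


class TestBuild:
    def test_brand_and_generic_merge_to_one_variable(self, drug_map):
        cohort = _cohort([("P1", "D1", "2015-06-01")])
        orders = _orders(
            [("P1", "2015-03-01", "Tamiflu"), ("P1", "2015-04-01", "oseltamivir")]
        )
        m = build_exposures(orders, cohort, drug_map)
        assert m.data.loc["D1", "oseltamivir"] == 1
        assert m.data.loc["D1"].sum() == 1  # one variable, despite two raw names

    def test_repeat_orders_stay_binary(self, drug_map):
        cohort = _cohort([("P1", "D1", "2015-06-01")])
        orders = _orders([("P1", "2015-03-01", "heparin"), ("P1", "2015-03-08", "heparin")])
        m = build_exposures(orders, cohort, drug_map)
        assert m.data.loc["D1", "heparin"] == 1

    def test_no_in_window_orders_zero_row(self, drug_map):
        cohort = _cohort([("P1", "D1", "2015-06-01")])
        orders = _orders([("P1", "2015-06-01", "heparin"), ("P1", "2013-01-01", "aspirin")])
        m = build_exposures(orders, cohort, drug_map)
        assert m.data.loc["D1"].sum() == 0

    def test_empty_cohort_empty_matrix(self, drug_map):
        m = build_exposures(_orders([]), _cohort([]), drug_map)
        assert m.data.shape[0] == 0

    def test_unmapped_names_excluded_and_logged(self, drug_map, caplog):
        cohort = _cohort([("P1", "D1", "2015-06-01")])
        orders = _orders([("P1", "2015-03-01", "unobtainium")])
        import logging

        with caplog.at_level(logging.WARNING):
            m = build_exposures(orders, cohort, drug_map)
        assert m.data.loc["D1"].sum() == 0
        assert any("unmapped" in r.message for r in caplog.records)

    def test_merging_invariance_under_name_split(self, drug_map):
        """Splitting one ingredient's orders across equivalent brand
        names never changes the matrix."""
        cohort = _cohort([("P1", "D1", "2015-06-01"), ("P2", "D2", "2015-07-01")])
        all_generic = _orders(
            [("P1", "2015-03-01", "ibuprofen"), ("P2", "2015-05-01", "ibuprofen")]
        )
        split = _orders(
            [("P1", "2015-03-01", "Motrin"), ("P2", "2015-05-01", "Advil")]
        )
        a = build_exposures(all_generic, cohort, drug_map)
        b = build_exposures(split, cohort, drug_map)
        assert a.data.equals(b.data)


def _matrix_with_patient_counts(counts: dict[str, int], drug_map):
    """Orders giving each variable exactly ``counts[v]`` exposed patients."""
    raw_for = {}
    for raw, var in drug_map.entries.items():
        raw_for.setdefault(var, raw)
    cohort_rows, order_rows = [], []
    pid = 0
    for var, n in counts.items():
        for _ in range(n):
            p, d = f"P{pid}", f"D{pid}"
            pid += 1
            cohort_rows.append((p, d, "2015-06-01"))
            order_rows.append((p, "2015-03-01", raw_for[var]))
    return build_exposures(_orders(order_rows), _cohort(cohort_rows), drug_map)


class TestMinPatientFilter:
    def test_boundary_nine_dropped_ten_retained(self, drug_map):
        m = _matrix_with_patient_counts({"heparin": 9, "aspirin": 10}, drug_map)
        kept = apply_min_patient_filter(m)
        assert "heparin" not in kept.variables
        assert "aspirin" in kept.variables

    def test_counts_distinct_patients_not_deliveries(self, drug_map):
        # one patient, two deliveries, both exposed: patient count is 1
        cohort = _cohort([("P1", "D1", "2014-06-01"), ("P1", "D2", "2016-06-01")])
        orders = _orders([("P1", "2014-03-01", "heparin"), ("P1", "2016-03-01", "heparin")])
        m = build_exposures(orders, cohort, drug_map)
        assert m.patient_counts["heparin"] == 1
        assert m.delivery_counts["heparin"] == 2
        assert "heparin" not in apply_min_patient_filter(m, threshold=2).variables
        assert "heparin" in apply_min_patient_filter(m, threshold=2, count_deliveries=True).variables

    def test_filter_monotone_in_threshold(self, drug_map):
        m = _matrix_with_patient_counts({"heparin": 3, "aspirin": 7, "ibuprofen": 12}, drug_map)
        previous = None
        for thr in (12, 8, 4, 1):
            kept = set(apply_min_patient_filter(m, threshold=thr).variables)
            if previous is not None:
                assert previous <= kept
            previous = kept

    def test_full_map_merges_49_names_to_31_variables_all_retained(self, drug_map):
        assert len(drug_map.entries) == 49
        assert len(drug_map.variables) == 31
        m = _matrix_with_patient_counts({v: 10 for v in drug_map.variables}, drug_map)
        assert len(apply_min_patient_filter(m).variables) == 31
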
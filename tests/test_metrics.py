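"""Confusion-matrix accuracy assessment: printed reference tables, a
brute-force oracle over random matrices, and the algebraic identities
linking OA, UA/PA and Kappa."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse import evaluate, segmentation_rates
from canopyfuse.datasets import SEGMENTATION_COUNTS, reference_confusion_matrix
from canopyfuse.metrics import (
    confusion_from_predictions,
    read_confusion_csv,
    render_report,
    round_half_up,
    write_confusion_csv,
)


def brute_force_report(matrix):
    """Cell-by-cell oracle with explicit python loops."""
    m = np.asarray(matrix, float)
    k = m.shape[0]
    total = m.sum()
    diag = sum(m[i, i] for i in range(k))
    oa = 100.0 * diag / total
    rows = [sum(m[i, j] for j in range(k)) for i in range(k)]
    cols = [sum(m[i, j] for i in range(k)) for j in range(k)]
    pe = sum(rows[i] * cols[i] for i in range(k)) / total**2
    kappa = (diag / total - pe) / (1 - pe)
    ua = [100.0 * m[i, i] / rows[i] if rows[i] else np.nan for i in range(k)]
    pa = [100.0 * m[j, j] / cols[j] if cols[j] else np.nan for j in range(k)]
    return oa, kappa, ua, pa


SPECIES = ["JM", "LG", "TA", "QM", "UP"]


class TestReferenceTables:
    """The bundled published tables must reproduce exactly."""

    @pytest.mark.parametrize(
        "source, oa, kappa",
        [("hsi", 86.08, 0.81), ("lidar", 76.42, 0.67), ("fused", 89.20, 0.85)],
    )
    def test_overall_accuracy_and_kappa(self, source, oa, kappa):
        report = evaluate(reference_confusion_matrix(source))
        assert report.oa == oa
        assert report.kappa == kappa

    def test_fused_per_class_cells(self):
        report = evaluate(reference_confusion_matrix("fused"))
        assert report.producer_accuracy == {
            "JM": 81.13, "LG": 98.62, "TA": 87.64, "QM": 82.76, "UP": 72.22}
        assert report.user_accuracy == {
            "JM": 89.58, "LG": 97.28, "TA": 85.71, "QM": 75.00, "UP": 76.47}
        assert report.commission == {
            "JM": 10.42, "LG": 2.72, "TA": 14.29, "QM": 25.00, "UP": 23.53}
        assert report.omission == {
            "JM": 18.87, "LG": 1.38, "TA": 12.36, "QM": 17.24, "UP": 27.78}

    def test_hsi_per_class_cells(self):
        report = evaluate(reference_confusion_matrix("hsi"))
        assert report.producer_accuracy == {
            "JM": 79.25, "LG": 95.86, "TA": 86.52, "QM": 72.41, "UP": 66.67}
        assert report.user_accuracy == {
            "JM": 82.35, "LG": 96.53, "TA": 81.05, "QM": 70.00, "UP": 75.00}

    def test_lidar_per_class_cells(self):
        report = evaluate(reference_confusion_matrix("lidar"))
        assert report.producer_accuracy == {
            "JM": 69.81, "LG": 91.03, "TA": 74.16, "QM": 58.62, "UP": 47.22}
        assert report.user_accuracy == {
            "JM": 77.08, "LG": 91.67, "TA": 64.08, "QM": 58.62, "UP": 60.71}


class TestEvaluate:
    def test_identity_matrix_is_perfect(self):
        m = pd.DataFrame(np.diag([5, 9, 2]), index=list("abc"),
                         columns=list("abc"))
        report = evaluate(m)
        assert report.oa == 100.0 and report.kappa == 1.0
        assert all(v == 100.0 for v in report.producer_accuracy.values())
        assert all(v == 100.0 for v in report.user_accuracy.values())

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 7)
            m = rng.integers(0, 40, (k, k))
            if m.sum() == 0 or (np.diag(m).sum() == m.sum()):
                m[0, 0] += 1
                m[min(1, k - 1), 0] += 1
            labels = [f"c{i}" for i in range(k)]
            df = pd.DataFrame(m, index=labels, columns=labels)
            report = evaluate(df)
            oa, kappa, ua, pa = brute_force_report(m)
            assert report.oa_raw == pytest.approx(oa, abs=1e-10)
            assert report.kappa_raw == pytest.approx(kappa, abs=1e-10)
            for i, lab in enumerate(labels):
                for got, want in (
                    (report.user_accuracy_raw[lab], ua[i]),
                    (report.producer_accuracy_raw[lab], pa[i]),
                ):
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-10)

    def test_kappa_invariant_under_class_permutation(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 30, (5, 5))
        labels = SPECIES
        df = pd.DataFrame(m, index=labels, columns=labels)
        base = evaluate(df)
        perm = rng.permutation(5)
        df2 = pd.DataFrame(m[np.ix_(perm, perm)],
                           index=[labels[i] for i in perm],
                           columns=[labels[i] for i in perm])
        other = evaluate(df2)
        assert other.kappa_raw == pytest.approx(base.kappa_raw, abs=1e-12)
        assert other.oa_raw == pytest.approx(base.oa_raw, abs=1e-12)

    def test_oa_is_row_weighted_mean_of_ua(self):
        rng = np.random.default_rng(2)
        m = rng.integers(1, 30, (4, 4)).astype(float)
        labels = list("wxyz")
        report = evaluate(pd.DataFrame(m, index=labels, columns=labels))
        rows = m.sum(axis=1)
        weighted = sum(
            rows[i] / m.sum() * report.user_accuracy_raw[lab]
            for i, lab in enumerate(labels)
        )
        assert report.oa_raw == pytest.approx(weighted, abs=1e-10)

    def test_commission_omission_complements(self):
        report = evaluate(reference_confusion_matrix("fused"))
        for lab in report.labels:
            assert report.commission[lab] == pytest.approx(
                round_half_up(100 - report.user_accuracy_raw[lab]))
            assert report.omission[lab] == pytest.approx(
                round_half_up(100 - report.producer_accuracy_raw[lab]))

    def test_zero_column_reported_missing(self):
        m = pd.DataFrame([[5, 0, 1], [1, 0, 2], [0, 0, 7]],
                         index=list("abc"), columns=list("abc"))
        report = evaluate(m)
        assert "b" in report.missing_classes
        assert np.isnan(report.producer_accuracy["b"])

    def test_nonsquare_and_negative_rejected(self):
        with pytest.raises(ValueError):
            evaluate(pd.DataFrame(np.ones((2, 3))))
        with pytest.raises(ValueError):
            evaluate(pd.DataFrame([[1, -2], [0, 3]]))


class TestSegmentationRates:
    def test_reference_counts(self):
        r = segmentation_rates(**SEGMENTATION_COUNTS)
        assert r["detection_rate"] == 90.00
        assert r["total_accuracy"] == 84.62

    def test_perfect(self):
        r = segmentation_rates(50, 50, 50)
        assert r["detection_rate"] == 100.0
        assert r["total_accuracy"] == 100.0

    def test_over_detection_allowed_and_flagged(self):
        r = segmentation_rates(100, 110, 90)
        assert r["detection_rate"] == 110.0
        assert r["over_detection"]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            segmentation_rates(0, 1, 1)
        with pytest.raises(ValueError):
            segmentation_rates(10, 5, 6)


class TestRoundingAndIO:
    def test_half_up_rounding(self):
        assert round_half_up(84.615) == 84.62  # banker's would give 84.61
        assert round_half_up(0.845) == 0.85
        assert round_half_up(2.344) == 2.34

    def test_csv_roundtrip(self, tmp_path):
        m = reference_confusion_matrix("fused")
        path = tmp_path / "m.csv"
        write_confusion_csv(m, path)
        back = read_confusion_csv(path)
        assert back.equals(m)

    def test_render_contains_printed_numbers(self):
        text = render_report(reference_confusion_matrix("fused"))
        for token in ("89.20", "0.85", "97.28", "98.62"):
            assert token in text

    def test_confusion_from_predictions_orientation(self):
        y_true = ["a", "a", "b"]
        y_pred = ["a", "b", "b"]
        m = confusion_from_predictions(y_true, y_pred)
        # predicted rows x reference columns
        assert m.loc["b", "a"] == 1
        assert m.loc["a", "b"] == 0
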
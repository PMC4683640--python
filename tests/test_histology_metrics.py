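"""Radius estimation, corrections, section metrics and detection scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repro_pheno.histology import (
    CannotEstimateRadiusError,
    CorrectionSet,
    DuplicateCenterError,
    SectionMetrics,
    TubuleRecord,
    TubuleTruth,
    UnresolvedReferenceError,
    apply_corrections,
    compute_metrics,
    estimate_radii,
    evaluate_detection,
)


def _brute_force_radii(centers):
    out = []
    for i, a in enumerate(centers):
        best = min(
            math.dist(a, b) for j, b in enumerate(centers) if j != i
        )
        out.append(0.5 * best)
    return np.array(out)


class TestRadii:
    def test_symmetric_pair(self):
        radii_px, radii_um = estimate_radii([(0, 0), (0, 100)], um_per_px=0.5)
        np.testing.assert_allclose(radii_px, [50.0, 50.0])
        np.testing.assert_allclose(radii_um, [25.0, 25.0])

    def test_collinear_triplet(self):
        radii_px, _ = estimate_radii([(0, 0), (0, 100), (0, 250)], um_per_px=1.0)
        np.testing.assert_allclose(radii_px, [50.0, 50.0, 75.0])

    def test_single_center_rejected(self):
        with pytest.raises(CannotEstimateRadiusError):
            estimate_radii([(0, 0)], um_per_px=1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=200))
    def test_agrees_with_brute_force_nearest_neighbour(self, seed, n):
        rng = np.random.default_rng(seed)
        centers = [tuple(p) for p in rng.uniform(0, 1000, size=(n, 2))]
        radii_px, _ = estimate_radii(centers, um_per_px=1.0)
        np.testing.assert_allclose(radii_px, _brute_force_radii(centers), rtol=1e-12)


def _record(row, col, **kw):
    defaults = dict(radius_px=10.0, radius_um=10.0)
    defaults.update(kw)
    return TubuleRecord(center_row_px=row, center_col_px=col, **defaults)


class TestCorrections:
    def test_empty_set_is_identity(self):
        recs = [_record(0, 0), _record(0, 100)]
        assert apply_corrections(recs, CorrectionSet(), um_per_px=1.0) == recs

    def test_deletion_recomputes_radii(self):
        recs = [_record(0, 0), _record(0, 100), _record(0, 250)]
        out = apply_corrections(
            recs, CorrectionSet(deletions=((0, 100),)), um_per_px=1.0
        )
        assert len(out) == 2
        # survivors are now each other's nearest neighbours at distance 250
        assert all(r.radius_px == pytest.approx(125.0) for r in out)

    def test_addition_appended_as_corrected(self):
        recs = [_record(0, 0), _record(0, 100)]
        out = apply_corrections(
            recs, CorrectionSet(additions=((50, 50, "tubule"),)), um_per_px=2.0
        )
        assert len(out) == 3
        added = [r for r in out if r.source == "corrected"]
        assert len(added) == 1
        assert added[0].radius_um == pytest.approx(added[0].radius_px * 2.0)

    def test_duplicate_addition_at_existing_auto_center_rejected(self):
        recs = [_record(0, 0), _record(0, 100)]
        with pytest.raises(DuplicateCenterError):
            apply_corrections(
                recs, CorrectionSet(additions=((0, 100, "tubule"),)), um_per_px=1.0
            )

    def test_reapplying_same_corrections_is_idempotent(self):
        recs = [_record(0, 0), _record(0, 100), _record(0, 250)]
        corr = CorrectionSet(
            additions=((80, 80, "tubule"),),
            deletions=((0, 250),),
            relabels=(((0, 0), {"germ_cell_loss": True}),),
        )
        once = apply_corrections(recs, corr, um_per_px=1.0)
        twice = apply_corrections(once, corr, um_per_px=1.0)
        assert once == twice

    def test_relabel_unknown_center_rejected(self):
        recs = [_record(0, 0), _record(0, 100)]
        with pytest.raises(UnresolvedReferenceError):
            apply_corrections(
                recs, CorrectionSet(relabels=(((5, 5), {"sloughing": True}),)),
                um_per_px=1.0,
            )


class TestMetrics:
    def test_epithelium_length_formula(self):
        recs = [
            _record(i, 2 * i, radius_um=50.0, radius_px=50.0) for i in range(100)
        ]
        m = compute_metrics(recs, um_per_px=1.0)
        assert m.epithelium_length_um == pytest.approx(31415.93, abs=0.01)
        assert m.n_tubules == 100

    def test_all_flags_false_all_counts_zero(self):
        recs = [_record(0, 0), _record(0, 100)]
        m = compute_metrics(recs, um_per_px=1.0)
        assert (m.n_vacuole_tubules, m.n_many_vacuole_tubules, m.n_germ_cell_loss,
                m.n_abnormal_germ_cells, m.n_sloughing) == (0, 0, 0, 0, 0)

    def test_vacuole_counts_with_threshold(self):
        recs = [
            _record(0, 0, n_vacuoles=0),
            _record(0, 100, n_vacuoles=2),
            _record(0, 200, n_vacuoles=5),
        ]
        m = compute_metrics(recs, um_per_px=1.0, many_threshold=3)
        assert m.n_vacuole_tubules == 2
        assert m.n_many_vacuole_tubules == 1

    def test_rete_excluded_from_everything(self):
        recs = [
            _record(0, 0),
            _record(0, 100),
            _record(0, 200, kind="rete", radius_um=99.0),
        ]
        m = compute_metrics(recs, um_per_px=1.0)
        assert m.n_tubules == 2
        assert m.mean_radius_um == pytest.approx(10.0)

    def test_counts_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            recs = [
                _record(i, 3 * i, n_vacuoles=int(rng.integers(0, 8)))
                for i in range(int(rng.integers(1, 30)))
            ]
            m = compute_metrics(recs, um_per_px=1.0, many_threshold=3)
            assert m.n_many_vacuole_tubules <= m.n_vacuole_tubules <= m.n_tubules

    def test_zero_tubules_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([_record(0, 0, kind="rete")], um_per_px=1.0)


def _truth(row, col, radius=20.0):
    return TubuleTruth(center_row_px=row, center_col_px=col, radius_um=radius)


class TestDetectionScoring:
    def test_perfect_detection(self):
        truth = [_truth(10, 10), _truth(100, 100)]
        recall, fp = evaluate_detection(truth, [(10, 10), (100, 100)], match_tol_px=5)
        assert (recall, fp) == (1.0, 0.0)

    def test_one_spurious_of_fifty(self):
        truth = [_truth(10 * i, 500) for i in range(50)]
        detected = [(10 * i, 500) for i in range(50)] + [(999, 999)]
        recall, fp = evaluate_detection(truth, detected, match_tol_px=3)
        assert recall == 1.0
        assert fp == pytest.approx(2.0)

    def test_empty_detections(self):
        recall, fp = evaluate_detection([_truth(0, 0)], [], match_tol_px=3)
        assert (recall, fp) == (0.0, 0.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detection([], [(0, 0)], match_tol_px=3)

    def test_matching_is_one_to_one(self):
        # two detections near one truth: only one may match
        truth = [_truth(50, 50), _truth(200, 200)]
        detected = [(50, 51), (51, 50)]
        recall, fp = evaluate_detection(truth, detected, match_tol_px=5)
        assert recall == pytest.approx(0.5)
        assert fp == pytest.approx(50.0)

    def test_default_tolerance_is_half_truth_radius(self):
        truth = [_truth(100, 100, radius=40.0), _truth(300, 300, radius=40.0)]
        # offset 15 px < 20 px = half radius
        recall, _ = evaluate_detection(truth, [(115, 100), (300, 285)], um_per_px=1.0)
        assert recall == 1.0


def test_section_metrics_invariant_guard():
    m = SectionMetrics(
        n_tubules=5, mean_radius_um=10.0, epithelium_length_um=5 * 10 * 2 * math.pi,
        n_vacuole_tubules=2, n_many_vacuole_tubules=1,
        n_germ_cell_loss=0, n_abnormal_germ_cells=0, n_sloughing=0,
    )
    assert m.n_many_vacuole_tubules <= m.n_vacuole_tubules <= m.n_tubules
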
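import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoiex.iextreme import (
    UNCLASSIFIED,
    InformationExtremeClassifier,
    TrainingError,
    binarize,
    build_tolerances,
    hamming,
    kullback_criterion,
    membership,
    optimize_radius,
    reference_vector,
)


def _independent_criterion(k1, k2, nmin, r):
    """Separately coded arithmetic oracle for the information measure."""
    eps = 10.0 ** (-r)
    s = k1 + k2
    val = (1.0 / nmin) * abs(nmin - s) * math.log2((2.0 * nmin + eps - s) / (s + eps))
    return max(val, 0.0)


class TestTolerancesAndBits:
    def test_zero_delta_collapses_to_base(self):
        tol = build_tolerances(np.array([1.0, 2.0]), np.array([0.5, 0.5]), 0.0)
        np.testing.assert_array_equal(binarize(np.array([1.0, 2.0]), tol), [1, 1])
        np.testing.assert_array_equal(binarize(np.array([1.001, 2.0]), tol), [0, 1])

    def test_bounds_symmetric_about_base(self):
        base = np.array([0.3, -1.0, 2.0])
        tol = build_tolerances(base, np.array([1.0, 2.0, 0.5]), 0.4)
        np.testing.assert_allclose(tol.upper[0] - base, base - tol.lower[0])

    def test_value_just_above_upper_binarizes_to_zero(self):
        tol = build_tolerances(np.array([0.0]), np.array([1.0]), 0.5)
        assert binarize(np.array([0.5]), tol)[0] == 1
        assert binarize(np.array([0.5 + 1e-9]), tol)[0] == 0

    def test_bit_count_matches_columns_and_levels(self):
        base = np.zeros(22)
        tol = build_tolerances(base, np.ones(22), 0.5)
        assert binarize(np.zeros(22), tol).size == 22
        tol3 = build_tolerances(base, np.ones(22), 0.5, bits_per_feature=3)
        assert binarize(np.zeros(22), tol3).size == 66

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            build_tolerances(np.array([0.0]), np.array([0.0]), 0.5)


class TestReferenceAndHamming:
    def test_majority_and_tie_rules(self):
        bits = np.array([[1, 1, 1, 0], [1, 0, 0, 0], [1, 1, 0, 1]])
        np.testing.assert_array_equal(reference_vector(bits), [1, 1, 0, 0])
        np.testing.assert_array_equal(reference_vector(np.array([[1, 0], [0, 1]])), [1, 1])

    def test_hamming_reference_points(self):
        assert hamming(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1])) == 2
        a = np.ones(21, dtype=int)
        assert hamming(a, a) == 0
        assert hamming(a, 1 - a) == 21

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40), st.data())
    @settings(deadline=None, derandomize=True)
    def test_hamming_symmetry(self, bits_a, data):
        bits_b = data.draw(st.lists(st.integers(0, 1), min_size=len(bits_a), max_size=len(bits_a)))
        a, b = np.array(bits_a), np.array(bits_b)
        assert hamming(a, b) == hamming(b, a)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hamming(np.zeros(3), np.zeros(4))


class TestKullbackCriterion:
    def test_error_free_container_has_unit_normalized_value(self):
        _, e_norm = kullback_criterion(0, 0, 50, r=2)
        assert e_norm == pytest.approx(1.0)

    def test_zero_at_half_total_errors(self):
        e, _ = kullback_criterion(25, 25, 50, r=2)
        assert e == pytest.approx(0.0)

    def test_worked_value_matches_independent_arithmetic(self):
        e, e_norm = kullback_criterion(5, 5, 50, r=2)
        assert e == pytest.approx(2.5349, abs=1e-4)
        assert e_norm == pytest.approx(0.1908, abs=1e-4)
        assert e == pytest.approx(_independent_criterion(5, 5, 50, 2))

    @given(st.integers(2, 60), st.data())
    @settings(deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, nmin, data):
        k1 = data.draw(st.integers(0, nmin))
        k2 = data.draw(st.integers(0, nmin - k1) if k1 < nmin else st.just(0))
        e, e_norm = kullback_criterion(k1, k2, nmin, r=2)
        assert 0.0 <= e_norm <= 1.0
        assert (e_norm == 1.0) == (k1 == 0 and k2 == 0)
        e_swap, _ = kullback_criterion(k2, k1, nmin, r=2)
        assert e == pytest.approx(e_swap)

    def test_rejects_out_of_range_counts(self):
        with pytest.raises(ValueError):
            kullback_criterion(51, 0, 50)


def _oracle_optimize(own, other, ref, nmin, r, ref_other=None):
    """Independent exhaustive search with plain loops."""
    n = len(ref)
    best_d, best_e = None, -1.0
    for d in range(n + 1):
        k1 = sum(1 for row in own if sum(x != y for x, y in zip(row, ref)) > d)
        k2 = sum(1 for row in other if sum(x != y for x, y in zip(row, ref)) <= d)
        if not (k1 / nmin < 0.5 and k2 / nmin < 0.5):
            continue
        if ref_other is not None and d >= sum(x != y for x, y in zip(ref, ref_other)):
            continue
        e = _independent_criterion(k1, k2, nmin, r) / _independent_criterion(0, 0, nmin, r)
        if e > best_e:
            best_d, best_e = d, e
    return best_d, best_e


class TestOptimizeRadius:
    def test_separated_classes_reach_unit_criterion(self, rng):
        ref = np.zeros(21, dtype=np.uint8)
        own = np.array([ref.copy() for _ in range(20)])
        for row in own:
            row[rng.choice(21, size=rng.integers(0, 3), replace=False)] = 1
        other = np.ones((20, 21), dtype=np.uint8)
        for row in other:
            row[rng.choice(21, size=rng.integers(0, 3), replace=False)] = 0
        res = optimize_radius(own, other, ref, nmin=20)
        assert res.d_star is not None and 2 <= res.d_star <= 9
        assert res.e_at_optimum == pytest.approx(1.0)

    def test_identical_classes_are_inseparable(self):
        bits = np.tile(np.array([1, 0, 1, 0, 1], dtype=np.uint8), (10, 1))
        res = optimize_radius(bits, bits, reference_vector(bits), nmin=10)
        assert res.d_star is None

    def test_trace_monotonicity(self, rng):
        own = rng.integers(0, 2, size=(15, 21)).astype(np.uint8)
        other = rng.integers(0, 2, size=(15, 21)).astype(np.uint8)
        res = optimize_radius(own, other, reference_vector(own), nmin=15)
        assert (np.diff(res.trace["K1"]) <= 0).all()
        assert (np.diff(res.trace["K2"]) >= 0).all()

    def test_matches_independent_exhaustive_oracle(self, rng):
        for _ in range(30):
            n_own = int(rng.integers(10, 51))
            n_other = int(rng.integers(10, 51))
            p = rng.uniform(0.2, 0.8)
            own = (rng.random((n_own, 21)) < p).astype(np.uint8)
            other = (rng.random((n_other, 21)) < 1 - p).astype(np.uint8)
            ref = reference_vector(own)
            ref_o = reference_vector(other)
            nmin = min(n_own, n_other)
            res = optimize_radius(own, other, ref, nmin, r=2, ref_other=ref_o)
            d_exp, e_exp = _oracle_optimize(own.tolist(), other.tolist(), ref.tolist(), nmin, 2, ref_o.tolist())
            assert res.d_star == d_exp
            if d_exp is not None:
                assert res.e_at_optimum == pytest.approx(e_exp)


class TestMembershipAndClassify:
    def test_membership_identities(self):
        ref = np.array([1, 0, 1, 0, 1, 0], dtype=np.uint8)
        assert membership(ref, ref, radius=3) == pytest.approx(1.0)
        x = ref.copy()
        x[:3] = 1 - x[:3]
        assert membership(x, ref, radius=3) == pytest.approx(0.0)
        x = ref.copy()
        x[:6] = 1 - x[:6]
        assert membership(x, ref, radius=3) == pytest.approx(-1.0)

    def test_zero_radius_container(self):
        ref = np.array([1, 1, 0], dtype=np.uint8)
        assert membership(ref, ref, radius=0) == 1.0
        assert membership(1 - ref, ref, radius=0) == -np.inf


def _gap_probe(clf):
    """Feature row landing in Hamming space strictly between the two fitted
    containers: beyond each class radius but short of the rival reference."""
    import numpy as _np

    c0, c1 = clf.classes_
    ref0, ref1 = clf.references_[c0], clf.references_[c1]
    differ = _np.flatnonzero(ref0 != ref1)
    k = clf.radii_[c1] + 1  # flips from ref1 toward ref0
    assert clf.radii_[c0] + clf.radii_[c1] < differ.size, "no gap between containers"
    assert k <= differ.size - clf.radii_[c0] - 1
    bits = ref1.copy()
    bits[differ[:k]] = ref0[differ[:k]]
    base = clf.tolerance_.base
    width = clf.delta_opt_ * clf.tolerance_.delta_h
    return _np.where(bits == 1, base, base + 10.0 * _np.maximum(width, 1.0))[None, :]


def _separated_table(rng, n_per_class=30, n_feat=8, gap=6.0):
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_feat))
    b = rng.normal(gap, 1.0, size=(n_per_class, n_feat))
    X = np.vstack([a, b])
    y = np.array(["normal"] * n_per_class + ["malignant"] * n_per_class)
    return X, y


class TestClassifier:
    def test_separated_classes_train_to_unit_criterion(self, rng):
        X, y = _separated_table(rng)
        clf = InformationExtremeClassifier().fit(X, y)
        assert np.mean(list(clf.e_values_.values())) == pytest.approx(1.0)
        assert clf.delta_opt_ in np.round(np.arange(0.01, 0.991, 0.02), 4)

    def test_training_is_deterministic(self, rng):
        X, y = _separated_table(rng)
        m1 = InformationExtremeClassifier().fit(X, y).to_model(feature_names=None)
        m2 = InformationExtremeClassifier().fit(X, y).to_model(feature_names=None)
        assert m1 == m2

    def test_reference_vectors_classify_to_their_class(self, rng):
        X, y = _separated_table(rng)
        clf = InformationExtremeClassifier().fit(X, y)
        assert clf.predict(X[y == "malignant"]).tolist().count("malignant") >= 28

    def test_vector_in_the_gap_between_containers_is_unclassified(self, rng):
        X, y = _separated_table(rng)
        clf = InformationExtremeClassifier().fit(X, y)
        probe = _gap_probe(clf)
        assert clf.decision_function(probe).max() <= 0
        assert clf.predict(probe)[0] == UNCLASSIFIED

    def test_membership_positive_inside_own_container(self, rng):
        X, y = _separated_table(rng)
        clf = InformationExtremeClassifier().fit(X, y)
        mu = clf.decision_function(X)
        from cytoiex.iextreme import binarize as _bin

        bits = _bin(X, clf.tolerance_)
        for j, c in enumerate(clf.classes_):
            ref, rad = clf.references_[c], clf.radii_[c]
            inside = np.count_nonzero(bits != ref[None, :], axis=1) <= rad
            if rad > 0:
                assert np.all(mu[inside, j] >= 0)

    def test_inseparable_training_fails_loudly(self, rng):
        X = rng.normal(size=(40, 5))
        X = np.vstack([X, X])
        y = np.array(["normal"] * 40 + ["malignant"] * 40)
        with pytest.raises(TrainingError):
            InformationExtremeClassifier().fit(X, y)

    def test_model_roundtrip_preserves_predictions(self, rng):
        X, y = _separated_table(rng)
        clf = InformationExtremeClassifier().fit(X, y)
        clone = InformationExtremeClassifier.from_model(clf.to_model())
        Xq = rng.normal(3.0, 2.0, size=(25, X.shape[1]))
        np.testing.assert_array_equal(clf.predict(Xq), clone.predict(Xq))

    def test_sklearn_param_interface(self):
        clf = InformationExtremeClassifier(r=3)
        assert clf.get_params()["r"] == 3
        clf.set_params(r=2, bits_per_feature=2)
        assert clf.get_params()["bits_per_feature"] == 2
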
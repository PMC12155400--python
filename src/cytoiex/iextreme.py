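"""Information-extreme learning of hyperspherical class containers.

The classifier maps each normalized feature vector into a binary Hamming
space through a system of symmetric tolerance fields centered on the base
class's feature means: a feature binarizes to 1 when its value falls inside
``[base_i - delta*delta_H_i, base_i + delta*delta_H_i]``.  Each recognition
class is represented by a container: a reference bit vector (the bitwise
majority of its training realizations) plus an integer Hamming radius.  The
radius is chosen by exhaustively sweeping all radii and maximizing a modified
Kullback information criterion

    E = (1/n_min) * |n_min - (K1 + K2)|
        * log2((2*n_min + 10**-r - (K1 + K2)) / (K1 + K2 + 10**-r))

where K1 counts own-class vectors falling outside the container (first-kind
errors) and K2 counts rival-class vectors falling inside it (false alarms),
restricted to the working domain where both error rates stay below 0.5.  An
outer grid search over the tolerance width ``delta`` maximizes the class-mean
normalized criterion.  Classification uses the membership function
``mu = 1 - d(ref, x)/radius``: a vector belongs to the class of largest
positive membership, or is explicitly "unclassified" when every membership is
non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

UNCLASSIFIED = "unclassified"

SCHEMA_VERSION = 1


class TrainingError(RuntimeError):
    """Raised when no tolerance width yields a non-empty working domain."""


@dataclass
class ToleranceSystem:
    """Symmetric per-feature tolerance bounds in normalized feature space.

    With ``bits_per_feature = b > 1`` each feature owns ``b`` concentric
    sub-fields of widths ``delta*j/b`` (j = 1..b), giving a coarse unary
    code of how close the value sits to the base; ``b = 1`` is the standard
    single-interval encoding.
    """

    base: np.ndarray
    delta_h: np.ndarray
    delta: float
    bits_per_feature: int = 1

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        self.delta_h = np.asarray(self.delta_h, dtype=float)
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if np.any(self.delta_h <= 0):
            raise ValueError("delta_H must be positive for every feature")
        widths = self.delta * self.delta_h[None, :] * (
            np.arange(1, self.bits_per_feature + 1)[:, None] / self.bits_per_feature
        )
        self.lower = self.base[None, :] - widths  # (b, N)
        self.upper = self.base[None, :] + widths


def build_tolerances(
    base: np.ndarray, delta_h: np.ndarray, delta: float, bits_per_feature: int = 1
) -> ToleranceSystem:
    """Construct the control tolerance system for a given width parameter."""
    return ToleranceSystem(base=base, delta_h=delta_h, delta=delta, bits_per_feature=bits_per_feature)


def binarize(rows: np.ndarray, tol: ToleranceSystem) -> np.ndarray:
    """Map feature rows to bit vectors: bit = 1 iff the value lies inside its
    tolerance sub-field.  Accepts a single row or a matrix; bit order is
    feature-major (all sub-fields of feature 0 first)."""
    rows = np.asarray(rows, dtype=float)
    single = rows.ndim == 1
    if single:
        rows = rows[None, :]
    if rows.shape[1] != tol.base.size:
        raise ValueError(f"expected {tol.base.size} features, got {rows.shape[1]}")
    # (n, N, b) -> (n, N*b)
    inside = (rows[:, :, None] >= tol.lower.T[None, :, :]) & (
        rows[:, :, None] <= tol.upper.T[None, :, :]
    )
    bits = inside.reshape(rows.shape[0], -1).astype(np.uint8)
    return bits[0] if single else bits


def reference_vector(class_bits: np.ndarray) -> np.ndarray:
    """Bitwise majority vote over class realizations; ties (0.5) round to 1."""
    class_bits = np.atleast_2d(np.asarray(class_bits))
    if class_bits.shape[0] < 1:
        raise ValueError("need at least one realization")
    return (class_bits.mean(axis=0) >= 0.5).astype(np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bits between two equal-length bit vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return int(np.count_nonzero(a != b))


def kullback_criterion(k1: float, k2: float, nmin: int, r: int = 2) -> tuple[float, float]:
    """Modified Kullback information measure and its normalized form.

    ``k1``/``k2`` are first-kind-error and false-alarm counts out of the
    representative sample size ``nmin``; ``10**-r`` regularizes the logarithm.
    The normalized value divides by the error-free maximum (k1 = k2 = 0), so
    it equals 1 exactly when the container makes no errors.
    """
    if not (0 <= k1 <= nmin and 0 <= k2 <= nmin):
        raise ValueError("counts must lie in [0, nmin]")
    if r < 1 or int(r) != r:
        raise ValueError("r must be a positive integer")
    e = _criterion_raw(k1, k2, nmin, r)
    e_max = _criterion_raw(0, 0, nmin, r)
    return e, e / e_max


def _criterion_raw(k1: float, k2: float, nmin: int, r: int) -> float:
    # floored at 0: beyond nmin total errors the container carries no information
    eps = 10.0 ** (-r)
    s = k1 + k2
    return max((1.0 / nmin) * abs(nmin - s) * np.log2((2.0 * nmin + eps - s) / (s + eps)), 0.0)


@dataclass
class RadiusResult:
    """Outcome of a container-radius sweep for one class.

    ``d_star`` is None when the working domain is empty (the classes are not
    separable at the current tolerance width).  ``trace`` records, per radius,
    the error counts, raw and normalized criterion, and working-domain flag —
    the curve whose maximum picks the container radius.
    """

    d_star: int | None
    e_at_optimum: float
    trace: pd.DataFrame


def optimize_radius(
    own_bits: np.ndarray,
    other_bits: np.ndarray,
    ref: np.ndarray,
    nmin: int,
    r: int = 2,
    ref_other: np.ndarray | None = None,
    criterion=None,
) -> RadiusResult:
    """Exhaustive sweep of container radii maximizing the criterion.

    At radius d: K1 = own vectors at Hamming distance > d from the reference,
    K2 = rival vectors at distance <= d.  The working domain requires both
    K1/nmin < 0.5 and K2/nmin < 0.5, and (when the rival reference is given)
    d below the inter-reference distance so a container cannot swallow the
    rival center.  Ties break toward the smaller radius (tighter container).

    ``criterion`` may supply an alternate information measure with the
    signature ``f(k1, k2, nmin, r) -> float``; the default is the modified
    Kullback measure.
    """
    crit = criterion if criterion is not None else _criterion_raw
    own_bits = np.atleast_2d(own_bits)
    other_bits = np.atleast_2d(other_bits)
    ref = np.asarray(ref)
    n = ref.size
    d_own = np.count_nonzero(own_bits != ref[None, :], axis=1)
    d_other = np.count_nonzero(other_bits != ref[None, :], axis=1)
    d_between = hamming(ref, ref_other) if ref_other is not None else None
    records = []
    best_d, best_e = None, -np.inf
    for d in range(n + 1):
        k1 = int(np.count_nonzero(d_own > d))
        k2 = int(np.count_nonzero(d_other <= d))
        s = k1 + k2
        if s < 2 * nmin:
            e = crit(k1, k2, nmin, r)
            e_norm = e / crit(0, 0, nmin, r)
        else:
            e, e_norm = 0.0, 0.0
        in_domain = (k1 / nmin < 0.5) and (k2 / nmin < 0.5)
        admissible = in_domain and (d_between is None or d < d_between)
        records.append(
            {"d": d, "K1": k1, "K2": k2, "E": e, "E_normalized": e_norm, "in_working_domain": in_domain}
        )
        if admissible and e_norm > best_e:
            best_d, best_e = d, e_norm
    trace = pd.DataFrame(records)
    if best_d is None:
        return RadiusResult(d_star=None, e_at_optimum=0.0, trace=trace)
    return RadiusResult(d_star=best_d, e_at_optimum=float(best_e), trace=trace)


def membership(x_bits: np.ndarray, ref: np.ndarray, radius: int) -> float:
    """Container membership ``mu = 1 - d(ref, x)/radius``.

    Positive inside the container, 0 on its surface, negative outside.  A
    zero-radius container admits only its own reference vector.
    """
    d = hamming(ref, x_bits)
    if radius == 0:
        return 1.0 if d == 0 else -np.inf
    return 1.0 - d / radius


class InformationExtremeClassifier(ClassifierMixin, BaseEstimator):
    """Two-class (or one-vs-rest multiclass) container classifier.

    Parameters
    ----------
    r : int, default 2
        Regularizer exponent of the criterion (``10**-r``).
    delta_grid : array-like or None
        Tolerance widths to sweep; default 0.01..0.99 in steps of 0.02.
    base_class : str or None
        Class whose feature means center the tolerance fields; defaults to
        ``"normal"`` when present, otherwise the first class.
    positive_class : str or None
        Class favored on exact membership ties (recall-prioritizing);
        defaults to ``"malignant"`` when present, otherwise the last class.
    bits_per_feature : int, default 1
        Bits of the per-feature unary tolerance code.

    Attributes
    ----------
    classes_ : ndarray of class labels seen in fit.
    delta_opt_ : float — selected tolerance width.
    tolerance_ : ToleranceSystem at ``delta_opt_``.
    references_ : dict label -> reference bit vector.
    radii_ : dict label -> container radius.
    e_values_ : dict label -> normalized criterion at the optimum.
    traces_ : dict label -> per-radius criterion trace (DataFrame).
    delta_scores_ : DataFrame of the outer tolerance sweep.
    """

    def __init__(
        self,
        r: int = 2,
        delta_grid=None,
        base_class: str | None = None,
        positive_class: str | None = None,
        bits_per_feature: int = 1,
    ):
        self.r = r
        self.delta_grid = delta_grid
        self.base_class = base_class
        self.positive_class = positive_class
        self.bits_per_feature = bits_per_feature

    def _grid(self) -> np.ndarray:
        if self.delta_grid is not None:
            return np.asarray(self.delta_grid, dtype=float)
        return np.round(np.arange(0.01, 0.991, 0.02), 4)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 realizations")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.nmin_ = int(counts.min())
        base_label = self.base_class
        if base_label is None:
            base_label = "normal" if "normal" in classes else classes[0]
        if base_label not in classes:
            raise ValueError(f"base_class {base_label!r} not among classes")
        self._base_label_ = base_label
        pos = self.positive_class
        if pos is None:
            pos = "malignant" if "malignant" in classes else classes[-1]
        self._positive_label_ = pos

        base = X[y == base_label].mean(axis=0)
        delta_h = np.maximum(X.max(axis=0) - X.min(axis=0), 1e-9)
        masks = {c: y == c for c in classes}

        best = None  # (score, delta, tol, refs, results)
        score_rows = []
        for delta in self._grid():
            tol = build_tolerances(base, delta_h, float(delta), self.bits_per_feature)
            bits = binarize(X, tol)
            refs = {c: reference_vector(bits[masks[c]]) for c in classes}
            results = {}
            scores = []
            for c in classes:
                others = np.concatenate([bits[masks[o]] for o in classes if o != c])
                rival = self._nearest_rival(refs, c)
                res = optimize_radius(
                    bits[masks[c]], others, refs[c], self.nmin_, self.r, ref_other=rival
                )
                results[c] = res
                scores.append(res.e_at_optimum if res.d_star is not None else 0.0)
            score = float(np.mean(scores))
            score_rows.append({"delta": float(delta), "score": score})
            if best is None or score > best[0]:
                best = (score, float(delta), tol, refs, results)
        self.delta_scores_ = pd.DataFrame(score_rows)
        score, delta, tol, refs, results = best
        if score == 0.0 and all(res.d_star is None for res in results.values()):
            raise TrainingError(
                "classes not separable at any tolerance width; "
                f"swept deltas {self._grid()[0]}..{self._grid()[-1]}"
            )
        self.delta_opt_ = delta
        self.tolerance_ = tol
        self.references_ = refs
        self.radii_ = {c: (results[c].d_star if results[c].d_star is not None else 0) for c in refs}
        self.e_values_ = {c: results[c].e_at_optimum for c in refs}
        self.traces_ = {c: results[c].trace for c in refs}
        return self

    @staticmethod
    def _nearest_rival(refs: dict, c) -> np.ndarray:
        others = [v for k, v in refs.items() if k != c]
        own = refs[c]
        dists = [hamming(own, o) for o in others]
        return others[int(np.argmin(dists))]

    def decision_function(self, X) -> np.ndarray:
        """Membership matrix mu (n_samples, n_classes) in classes_ order."""
        check_is_fitted(self, "references_")
        X = np.asarray(X, dtype=float)
        bits = binarize(np.atleast_2d(X), self.tolerance_)
        mu = np.empty((bits.shape[0], self.classes_.size))
        for j, c in enumerate(self.classes_):
            ref = self.references_[c]
            radius = self.radii_[c]
            d = np.count_nonzero(bits != ref[None, :], axis=1)
            if radius == 0:
                mu[:, j] = np.where(d == 0, 1.0, -np.inf)
            else:
                mu[:, j] = 1.0 - d / radius
        return mu

    def predict(self, X) -> np.ndarray:
        """Class of largest positive membership; ``"unclassified"`` when every
        membership is non-positive; exact positive ties go to the positive
        (recall-prioritized) class."""
        mu = self.decision_function(X)
        out = np.empty(mu.shape[0], dtype=object)
        for i in range(mu.shape[0]):
            row = mu[i]
            best = row.max()
            if best <= 0:
                out[i] = UNCLASSIFIED
                continue
            tied = self.classes_[row == best]
            out[i] = self._positive_label_ if self._positive_label_ in tied else tied[0]
        return out

    # -- serialization ------------------------------------------------------

    def to_model(self, feature_names=None, normalization: dict | None = None) -> dict:
        """JSON-serializable snapshot of the trained decision rules."""
        check_is_fitted(self, "references_")
        return {
            "schema_version": SCHEMA_VERSION,
            "feature_names": list(feature_names) if feature_names is not None else None,
            "classes": [str(c) for c in self.classes_],
            "base_class": str(self._base_label_),
            "positive_class": str(self._positive_label_),
            "r": self.r,
            "bits_per_feature": self.bits_per_feature,
            "nmin": self.nmin_,
            "delta": self.delta_opt_,
            "base": [float(v) for v in self.tolerance_.base],
            "delta_h": [float(v) for v in self.tolerance_.delta_h],
            "references": {str(c): "".join(map(str, self.references_[c])) for c in self.classes_},
            "radii": {str(c): int(self.radii_[c]) for c in self.classes_},
            "e_values": {str(c): float(self.e_values_[c]) for c in self.classes_},
            "traces": {str(c): self.traces_[c].to_dict(orient="list") for c in self.classes_},
            "normalization": normalization,
        }

    @classmethod
    def from_model(cls, model: dict) -> "InformationExtremeClassifier":
        if model.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {model.get('schema_version')!r} != {SCHEMA_VERSION}"
            )
        obj = cls(
            r=model["r"],
            base_class=model["base_class"],
            positive_class=model["positive_class"],
            bits_per_feature=model["bits_per_feature"],
        )
        obj.classes_ = np.asarray(model["classes"], dtype=object)
        obj.nmin_ = model["nmin"]
        obj._base_label_ = model["base_class"]
        obj._positive_label_ = model["positive_class"]
        obj.delta_opt_ = model["delta"]
        obj.tolerance_ = build_tolerances(
            np.asarray(model["base"]), np.asarray(model["delta_h"]), model["delta"],
            model["bits_per_feature"],
        )
        obj.references_ = {
            c: np.frombuffer(model["references"][c].encode(), dtype=np.uint8) - ord("0")
            for c in model["references"]
        }
        obj.radii_ = {c: int(v) for c, v in model["radii"].items()}
        obj.e_values_ = {c: float(v) for c, v in model["e_values"].items()}
        obj.traces_ = {c: pd.DataFrame(t) for c, t in model["traces"].items()}
        obj.n_features_in_ = len(model["base"])
        return obj


def train(
    table: pd.DataFrame,
    label_col: str = "class",
    feature_cols: list[str] | None = None,
    **params,
) -> tuple[InformationExtremeClassifier, dict]:
    """Fit a classifier from a labeled feature table; returns (clf, model dict)."""
    if feature_cols is None:
        feature_cols = [
            c for c in table.columns
            if c not in (label_col, "cell_id") and not c.startswith("aux_")
        ]
    clf = InformationExtremeClassifier(**params)
    clf.fit(table[feature_cols].to_numpy(dtype=float), table[label_col].to_numpy())
    return clf, clf.to_model(feature_names=feature_cols)


def classify(x: np.ndarray, model: dict | InformationExtremeClassifier) -> str:
    """Classify a single normalized feature vector with a trained model."""
    clf = model if isinstance(model, InformationExtremeClassifier) else (
        InformationExtremeClassifier.from_model(model)
    )
    return str(clf.predict(np.atleast_2d(np.asarray(x, dtype=float)))[0])
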
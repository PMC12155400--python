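"""Nuclear shape and texture descriptors for segmented cells.

Each segmented nucleus is reduced to a fixed-order vector of morphometric
descriptors: a geometric block derived from the binary mask (area, perimeter,
equivalent-ellipse statistics, convexity, circularity ``4*pi*A/P**2``) and a
textural block derived from the gray-level content under the mask (first-order
statistics, absorbance, gray-level co-occurrence measures, and histogram
modality counts).  Two auxiliary quantities used throughout cytopathology are
also provided: the Shannon chromatin entropy ``H = -sum(p_i * log2(p_i))`` of
the 256-level nuclear histogram, and the nucleus-to-cytoplasm ratio
``N/C = A_nucleus / (A_cell - A_nucleus)``.

Feature columns are emitted in :data:`FEATURE_COLUMNS` order; the canonical
feature count is 21 (the two axis lengths share one descriptor slot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton, regionprops
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

SHAPE_COLUMNS = (
    "area",
    "eccentricity",
    "solidity",
    "extent",
    "orientation",
    "major_axis",
    "minor_axis",
    "elongation",
    "perimeter",
    "convex_area",
    "circularity",
)
TEXTURE_COLUMNS = (
    "mean_intensity",
    "absorbance",
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
    "std_dev",
    "hist_peaks",
    "hist_valleys",
)
#: Column order of the per-cell feature table (22 values for 21 descriptors:
#: major and minor axis length share one descriptor slot).
FEATURE_COLUMNS = SHAPE_COLUMNS + TEXTURE_COLUMNS

_GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
_HIST_BINS = 32
_PEAK_PROMINENCE_FRACTION = 0.05


class FeatureError(ValueError):
    """Raised when a mask or gray patch cannot yield valid descriptors."""


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise FeatureError("mask must be a 2-D binary raster")
    if not mask.any():
        raise FeatureError("empty mask")
    return mask


def mask_area(mask: np.ndarray) -> int:
    """Nuclear area ``A``: the number of pixels in the mask."""
    return int(_check_mask(mask).sum())


def mask_circularity(mask: np.ndarray) -> float:
    """Circularity ``4*pi*A/P**2`` with a Crofton (4-direction) perimeter."""
    mask = _check_mask(mask)
    p = perimeter_crofton(mask, directions=4)
    return float(4.0 * np.pi * mask.sum() / p**2)


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Geometric descriptor block of a single-component binary mask.

    Area is the raw pixel count; the perimeter uses the Crofton 4-direction
    estimator (near-unbiased on rasterized disks); eccentricity, orientation
    and axis lengths come from the second-moment equivalent ellipse; extent is
    relative to the axis-aligned bounding box; solidity is area over
    convex-hull area.

    Raises
    ------
    FeatureError
        If the mask is empty or has more than one connected component.
    """
    mask = _check_mask(mask)
    n_comp = sk_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise FeatureError(f"mask must be a single component, found {n_comp}")
    (props,) = regionprops(mask.astype(np.uint8))
    p = perimeter_crofton(mask, directions=4)
    area = float(props.area)
    minor = float(props.axis_minor_length)
    major = float(props.axis_major_length)
    return {
        "area": area,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "orientation": float(np.degrees(props.orientation)),
        "major_axis": major,
        "minor_axis": minor,
        "elongation": major / minor if minor > 0 else np.inf,
        "perimeter": float(p),
        "convex_area": float(props.area_convex),
        "circularity": 4.0 * np.pi * area / p**2,
    }


def _glcm_mask_restricted(quantized: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric, per-angle normalized GLCM restricted to in-mask pixel pairs.

    Out-of-mask pixels are coded as a sentinel level and the sentinel row and
    column are dropped before normalization, so only pairs with both pixels
    inside the mask contribute.  Returns an array (levels, levels, 1, n_angles).
    """
    coded = np.where(mask, quantized, _GLCM_LEVELS).astype(np.uint8)
    glcm = graycomatrix(
        coded,
        distances=[1],
        angles=list(_GLCM_ANGLES),
        levels=_GLCM_LEVELS + 1,
        symmetric=True,
        normed=False,
    ).astype(float)
    glcm = glcm[:_GLCM_LEVELS, :_GLCM_LEVELS, :, :]
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    with np.errstate(invalid="ignore"):
        glcm = np.where(sums > 0, glcm / np.where(sums > 0, sums, 1.0), 0.0)
    return glcm


def _histogram_modality(values: np.ndarray, n_pixels: int) -> tuple[int, int]:
    """Peak/valley counts of the smoothed 32-bin intensity histogram.

    The histogram is smoothed by a 3-bin moving average; peaks are local maxima
    with prominence at least 5% of the pixel count; valleys are local minima
    strictly between consecutive peaks.
    """
    hist, _ = np.histogram(values, bins=_HIST_BINS, range=(0, 256))
    smooth = np.convolve(np.pad(hist.astype(float), 1, mode="edge"), np.ones(3) / 3, mode="valid")
    padded = np.concatenate([[0.0], smooth, [0.0]])
    prominence = _PEAK_PROMINENCE_FRACTION * n_pixels
    peaks, _ = signal.find_peaks(padded, prominence=prominence)
    peaks = peaks - 1
    if len(peaks) < 2:
        return len(peaks), 0
    minima, _ = signal.find_peaks(-smooth)
    n_valleys = 0
    for lo, hi in zip(peaks[:-1], peaks[1:]):
        n_valleys += int(np.sum((minima > lo) & (minima < hi)) > 0)
    return len(peaks), n_valleys


def texture_features(mask: np.ndarray, gray: np.ndarray) -> dict[str, float]:
    """Textural descriptor block over the masked gray-level patch.

    GLCM measures use 32 gray levels, distance 1, the four standard angles
    averaged, with co-occurring pairs restricted to mask-interior pixels.
    Absorbance converts 8-bit intensity to mean optical density via
    ``-log10((I+1)/256)``.  A constant patch yields the degenerate limits
    (contrast 0, homogeneity/ASM/energy/correlation 1, one histogram peak).
    """
    mask = _check_mask(mask)
    gray = np.asarray(gray)
    if gray.shape != mask.shape:
        raise FeatureError("gray raster shape must match mask shape")
    if mask.sum() < 2:
        raise FeatureError("texture requires at least 2 mask pixels")
    values = gray[mask].astype(float)
    quantized = (np.clip(gray, 0, 255).astype(np.uint16) // (256 // _GLCM_LEVELS)).astype(np.uint8)
    glcm = _glcm_mask_restricted(quantized, mask)
    have_pairs = glcm.sum(axis=(0, 1))[0] > 0
    out: dict[str, float] = {
        "mean_intensity": float(values.mean()),
        "absorbance": float(np.mean(-np.log10((values + 1.0) / 256.0))),
        "std_dev": float(values.std()),
    }
    if have_pairs.any():
        sel = glcm[:, :, :, have_pairs]
        for prop, name in [
            ("contrast", "contrast"),
            ("dissimilarity", "dissimilarity"),
            ("homogeneity", "homogeneity"),
            ("ASM", "asm"),
            ("correlation", "correlation"),
        ]:
            out[name] = float(graycoprops(sel, prop).mean())
    else:  # isolated pixels only: fall back to the uniform limits
        out.update(contrast=0.0, dissimilarity=0.0, homogeneity=1.0, asm=1.0, correlation=1.0)
    out["energy"] = float(np.sqrt(out["asm"]))
    n_peaks, n_valleys = _histogram_modality(values, int(mask.sum()))
    out["hist_peaks"] = float(n_peaks)
    out["hist_valleys"] = float(n_valleys)
    return {name: out[name] for name in TEXTURE_COLUMNS}


def chromatin_entropy(mask: np.ndarray, gray: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-level histogram under the mask."""
    mask = _check_mask(mask)
    values = np.clip(np.asarray(gray)[mask], 0, 255).astype(np.int64)
    p = np.bincount(values, minlength=256) / values.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nc_ratio(nucleus_area: float, cell_area: float) -> float:
    """Nucleus-to-cytoplasm ratio ``A_nucleus / (A_cell - A_nucleus)``."""
    if nucleus_area <= 0:
        raise FeatureError("nucleus area must be positive")
    if cell_area <= nucleus_area:
        raise FeatureError("cytoplasm area nonpositive: cell_area must exceed nucleus_area")
    return float(nucleus_area / (cell_area - nucleus_area))


def gray_from_hematoxylin(hema: np.ndarray) -> np.ndarray:
    """Reconstruct an 8-bit intensity image from a hematoxylin OD channel.

    Inverts the optical-density convention ``od = -log10((I+1)/256)`` so that
    texture descriptors defined on intensities apply to the stain channel.
    """
    intensity = 256.0 * np.power(10.0, -np.asarray(hema, dtype=float)) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def extract_features(
    masks: "list[np.ndarray]",
    gray: np.ndarray,
    labels: "list[str] | None" = None,
    cell_masks: "list[np.ndarray] | None" = None,
) -> pd.DataFrame:
    """Build the per-cell feature table for a list of nucleus masks.

    Returns a DataFrame with a ``cell_id`` column, the 22 core feature columns
    in :data:`FEATURE_COLUMNS` order, auxiliary ``aux_entropy`` (and
    ``aux_nc_ratio`` when cell masks are supplied), and a ``class`` column when
    labels are supplied.
    """
    rows = []
    for i, mask in enumerate(masks):
        row: dict[str, object] = {"cell_id": i}
        row.update(shape_features(mask))
        row.update(texture_features(mask, gray))
        row["aux_entropy"] = chromatin_entropy(mask, gray)
        if cell_masks is not None:
            row["aux_nc_ratio"] = nc_ratio(float(mask.sum()), float(np.asarray(cell_masks[i]).sum()))
        if labels is not None:
            row["class"] = labels[i]
        rows.append(row)
    columns = ["cell_id", *FEATURE_COLUMNS, "aux_entropy"]
    if cell_masks is not None:
        columns.append("aux_nc_ratio")
    if labels is not None:
        columns.append("class")
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Per-feature normalization (normality-test driven)
# ---------------------------------------------------------------------------


class ShapiroNormalizer(TransformerMixin, BaseEstimator):
    """Per-feature normalization chosen by a Shapiro-Wilk normality test.

    Columns whose training distribution is compatible with normality
    (Shapiro-Wilk p >= ``alpha``) are z-scored with the training mean and
    standard deviation; the rest are rank-transformed to (rank - 0.5)/n in
    [0, 1], with new values mapped by interpolation into the stored sorted
    training sample.  Constant columns are mapped to 0 and flagged.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level of the normality test.

    Attributes
    ----------
    kinds_ : list of {"zscore", "rank", "constant"}
        Transform chosen per column.
    means_, sds_ : ndarray
        Training statistics for z-scored columns (NaN elsewhere).
    references_ : list of ndarray or None
        Sorted training sample for rank-transformed columns.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y=None):
        X = self._validate(X, reset=True)
        if X.shape[0] < 8:
            raise ValueError("normalization requires at least 8 rows")
        self.kinds_: list[str] = []
        self.means_ = np.full(X.shape[1], np.nan)
        self.sds_ = np.full(X.shape[1], np.nan)
        self.references_: list[np.ndarray | None] = []
        self.shapiro_p_ = np.full(X.shape[1], np.nan)
        for i in range(X.shape[1]):
            col = X[:, i]
            if np.ptp(col) == 0:
                self.kinds_.append("constant")
                self.references_.append(None)
                continue
            p = float(stats.shapiro(col).pvalue)
            self.shapiro_p_[i] = p
            if p >= self.alpha:
                self.kinds_.append("zscore")
                self.means_[i] = col.mean()
                self.sds_[i] = col.std(ddof=1)
                self.references_.append(None)
            else:
                self.kinds_.append("rank")
                self.references_.append(np.sort(col))
        return self

    def transform(self, X):
        check_is_fitted(self, "kinds_")
        X = self._validate(X, reset=False)
        out = np.empty_like(X, dtype=float)
        for i, kind in enumerate(self.kinds_):
            col = X[:, i]
            if kind == "constant":
                out[:, i] = 0.0
            elif kind == "zscore":
                out[:, i] = (col - self.means_[i]) / self.sds_[i]
            else:
                ref = self.references_[i]
                n = ref.size
                out[:, i] = np.interp(col, ref, (np.arange(n) + 0.5) / n)
        return out

    def _validate(self, X, reset: bool):
        if isinstance(X, pd.DataFrame):
            if reset:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature array")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X

    def to_dict(self) -> dict:
        check_is_fitted(self, "kinds_")
        return {
            "alpha": self.alpha,
            "kinds": list(self.kinds_),
            "means": [None if np.isnan(v) else float(v) for v in self.means_],
            "sds": [None if np.isnan(v) else float(v) for v in self.sds_],
            "references": [None if r is None else [float(v) for v in r] for r in self.references_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapiroNormalizer":
        obj = cls(alpha=d["alpha"])
        obj.kinds_ = list(d["kinds"])
        obj.means_ = np.array([np.nan if v is None else v for v in d["means"]], dtype=float)
        obj.sds_ = np.array([np.nan if v is None else v for v in d["sds"]], dtype=float)
        obj.references_ = [None if r is None else np.asarray(r, dtype=float) for r in d["references"]]
        obj.shapiro_p_ = np.full(len(obj.kinds_), np.nan)
        obj.n_features_in_ = len(obj.kinds_)
        return obj


@dataclass
class NormalizationModel:
    """Fitted normalization bundled with the feature columns it applies to."""

    normalizer: ShapiroNormalizer
    columns: tuple[str, ...] = field(default_factory=tuple)


def fit_normalization(table: pd.DataFrame, alpha: float = 0.05) -> NormalizationModel:
    """Fit the per-feature normalization on the core feature columns."""
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    norm = ShapiroNormalizer(alpha=alpha).fit(table[cols])
    return NormalizationModel(normalizer=norm, columns=tuple(cols))


def apply_normalization(model: NormalizationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with the core feature columns normalized."""
    out = table.copy()
    out[list(model.columns)] = model.normalizer.transform(table[list(model.columns)])
    return out
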
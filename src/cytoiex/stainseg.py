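"""Hematoxylin isolation and nucleus segmentation for H&E images.

The recipe: convert RGB to optical density, unmix into stain channels with the
standard H&E color-deconvolution basis, flag hyperchromatic pixels by a global
mean + 2*sigma threshold on the hematoxylin channel, clean the mask
morphologically, keep connected components of at least 500 px^2 that do not
touch the image border, split clustered nuclei with a seeded watershed on the
distance transform, and retain only masks passing solidity >= 0.6 and
eccentricity <= 0.98 quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_local
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, h_maxima
from skimage.segmentation import morphological_chan_vese, watershed

from .synthgen import STAIN_D, STAIN_E, STAIN_H

_STAIN_MATRIX = np.stack([STAIN_H, STAIN_E, STAIN_D])  # rows = stains
_UNMIX = np.linalg.inv(_STAIN_MATRIX)


class SegmentationError(ValueError):
    pass


@dataclass
class StainImage:
    """RGB raster plus derived optical-density and per-stain channels."""

    rgb: np.ndarray
    od: np.ndarray
    hema: np.ndarray
    eosin: np.ndarray


@dataclass
class RoiSet:
    """Labeled candidate regions of interest after cleanup and filtering."""

    label_raster: np.ndarray
    components: pd.DataFrame  # columns: id, area, bbox, touches_border


@dataclass
class NucleusMask:
    """One segmented nucleus with its quality statistics."""

    mask: np.ndarray
    solidity: float
    eccentricity: float
    source_roi: int


@dataclass
class SegmentationParams:
    """Tunable knobs of the nucleus-splitting stage.

    Defaults suit nuclei of roughly 40-80 px diameter: a 51 px local-mean
    threshold window with a +0.02 OD strictness offset, watershed seeds at
    distance-transform maxima at least 10 px apart, and the standard quality
    gates.  Active-contour refinement is available but off by default.
    """

    window: int = 51
    offset: float = -0.02
    smooth_sigma: float = 2.0  # Gaussian presmooth of the stain channel
    min_seed_distance: int = 10
    seed_prominence: float = 5.0  # EDT height a seed must stand out by (px)
    solidity_min: float = 0.6
    ecc_max: float = 0.98
    active_contours: bool = False
    ac_iterations: int = 10
    min_nucleus_area: int = 100  # sub-fragment guard after watershed


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density ``-log10((I+1)/256)`` of an 8-bit image."""
    return -np.log10((np.asarray(rgb, dtype=float) + 1.0) / 256.0)


def deconvolve(rgb: np.ndarray) -> StainImage:
    """Unmix an RGB image into hematoxylin/eosin optical-density channels.

    Projects the pixelwise OD onto the inverse of the fixed stain matrix;
    negative stain amounts (unmixing noise) are clipped to zero.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise SegmentationError("expected an (h, w, 3) RGB image")
    od = optical_density(rgb)
    stains = od @ _UNMIX
    stains = np.clip(stains, 0.0, None)
    return StainImage(rgb=rgb, od=od, hema=stains[..., 0], eosin=stains[..., 1])


def detect_hyperchromatic(hema: np.ndarray, tissue_mask: np.ndarray | None = None) -> np.ndarray:
    """Flag pixels with hematoxylin OD above mean + 2*sigma.

    Statistics are taken over the whole image by default, or over
    ``tissue_mask`` when given (e.g. to exclude empty background).
    """
    hema = np.asarray(hema, dtype=float)
    if hema.size == 0:
        raise SegmentationError("empty raster")
    sample = hema[tissue_mask] if tissue_mask is not None else hema
    threshold = sample.mean() + 2.0 * sample.std()
    return hema > threshold


def tissue_mask_from_od(od: np.ndarray, min_od_sum: float = 0.15) -> np.ndarray:
    """Pixels with total absorbance above a floor, i.e. stained tissue."""
    return od.sum(axis=-1) >= min_od_sum


def clean_and_filter(binary: np.ndarray, min_area: int = 500) -> RoiSet:
    """Morphological cleanup and component filtering of a hyperchromasia mask.

    Opening then closing with a radius-2 disk, 8-connected labeling, then
    removal of components below ``min_area`` px^2 (area >= min_area is kept)
    or touching any image border.  Retained components are relabeled 1..k.
    """
    binary = np.asarray(binary, dtype=bool)
    selem = disk(2)
    # erosions treat the outside as foreground so border-touching objects are
    # not artificially retreated from the border they must be excluded for
    opened = ndi.binary_dilation(ndi.binary_erosion(binary, selem, border_value=1), selem)
    cleaned = ndi.binary_erosion(ndi.binary_dilation(opened, selem), selem, border_value=1)
    labeled = sk_label(cleaned, connectivity=2)
    h, w = labeled.shape
    out = np.zeros_like(labeled)
    rows = []
    next_id = 0
    for props in regionprops(labeled):
        r0, c0, r1, c1 = props.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if props.area < min_area or touches:
            continue
        next_id += 1
        out[labeled == props.label] = next_id
        rows.append(
            {"id": next_id, "area": int(props.area), "bbox": (r0, c0, r1, c1), "touches_border": False}
        )
    components = pd.DataFrame(rows, columns=["id", "area", "bbox", "touches_border"])
    return RoiSet(label_raster=out, components=components)


def _split_roi(roi_mask: np.ndarray, hema: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Adaptive threshold + seeded watershed inside one ROI; returns labels.

    The stain channel is Gaussian-presmoothed before thresholding: chromatin
    texture is high-frequency relative to the nucleus scale and would
    otherwise fragment the adaptive-threshold mask.
    """
    smoothed = gaussian(hema, sigma=params.smooth_sigma, preserve_range=True)
    adaptive = smoothed > threshold_local(smoothed, block_size=params.window, offset=params.offset)
    binary = ndi.binary_fill_holes(adaptive & roi_mask)
    if not binary.any():
        return np.zeros_like(roi_mask, dtype=int)
    distance = ndi.distance_transform_edt(binary)
    # seeds: EDT maxima standing out by >= seed_prominence, with maxima closer
    # than min_seed_distance merged into one seed (lobulated contours produce
    # shallow secondary maxima that must not split a single nucleus)
    smooth_dist = ndi.gaussian_filter(distance, 1.0)
    seeds = h_maxima(smooth_dist, params.seed_prominence)
    seeds = ndi.binary_dilation(seeds, structure=disk(max(params.min_seed_distance // 2, 1)))
    markers, n_markers = ndi.label(seeds & binary)
    if n_markers == 0:
        markers = np.zeros_like(distance, dtype=int)
        markers[np.unravel_index(np.argmax(distance), distance.shape)] = 1
    return watershed(-distance, markers, mask=binary)


def segment_nuclei(
    roi: RoiSet, hema: np.ndarray, params: SegmentationParams | None = None
) -> list[NucleusMask]:
    """Split each candidate ROI into individual nuclei and quality-filter them.

    Within each ROI: local-mean adaptive thresholding of the hematoxylin
    channel, Euclidean-distance-transform maxima as watershed seeds, watershed
    on the negated distance transform, optional morphological active-contour
    refinement, then rejection of masks failing the solidity/eccentricity
    gates.  An ROI may legitimately yield zero nuclei.
    """
    params = params or SegmentationParams()
    hema = np.asarray(hema, dtype=float)
    results: list[NucleusMask] = []
    for comp in roi.components.itertuples():
        r0, c0, r1, c1 = comp.bbox
        pad = 5
        rs, cs = max(r0 - pad, 0), max(c0 - pad, 0)
        re, ce = min(r1 + pad, hema.shape[0]), min(c1 + pad, hema.shape[1])
        roi_mask = roi.label_raster[rs:re, cs:ce] == comp.id
        crop = hema[rs:re, cs:ce]
        segments = _split_roi(roi_mask, crop, params)
        for props in regionprops(segments):
            if props.area < params.min_nucleus_area:
                continue
            local = segments == props.label
            if params.active_contours:
                local = morphological_chan_vese(
                    crop, num_iter=params.ac_iterations, init_level_set=local
                ).astype(bool)
                comps = sk_label(local, connectivity=2)
                if comps.max() == 0:
                    continue
                sizes = np.bincount(comps.ravel())[1:]
                local = comps == (1 + int(np.argmax(sizes)))
                (props,) = regionprops(local.astype(np.uint8))
            solidity = float(props.solidity)
            ecc = float(props.eccentricity)
            if solidity < params.solidity_min or ecc > params.ecc_max:
                continue
            full = np.zeros(hema.shape, dtype=bool)
            full[rs:re, cs:ce] = local
            results.append(
                NucleusMask(mask=full, solidity=solidity, eccentricity=ecc, source_roi=comp.id)
            )
    return results


def lesion_fraction(masks: list[NucleusMask] | list[np.ndarray], image_shape: tuple[int, int]) -> float:
    """Fraction of the image covered by the union of the given masks."""
    union = np.zeros(image_shape, dtype=bool)
    for m in masks:
        arr = m.mask if isinstance(m, NucleusMask) else np.asarray(m, dtype=bool)
        union |= arr
    return float(union.sum() / (image_shape[0] * image_shape[1]))


def segment_image(
    rgb: np.ndarray,
    min_area: int = 500,
    params: SegmentationParams | None = None,
    tissue_only: bool = False,
) -> tuple[StainImage, RoiSet, list[NucleusMask]]:
    """Full recipe: deconvolve, threshold, clean, split, filter."""
    stain = deconvolve(rgb)
    tmask = tissue_mask_from_od(stain.od) if tissue_only else None
    hyper = detect_hyperchromatic(stain.hema, tissue_mask=tmask)
    roi = clean_and_filter(hyper, min_area=min_area)
    nuclei = segment_nuclei(roi, stain.hema, params)
    return stain, roi, nuclei
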
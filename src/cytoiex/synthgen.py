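"""Synthetic two-class nucleus scenes with calibrated morphometry.

Generates H&E-like test images for the classification pipeline: each nucleus
is a star-convex radial-harmonic shape with a controllable measured
circularity, filled with an i.i.d. gray-level texture whose marginal
distribution has an exactly specified Shannon entropy, and rendered by
Beer-Lambert mixing along a hematoxylin stain vector over an eosin-stained
cytoplasm ellipse on a near-white background.  Ground-truth nucleus masks,
cell masks, per-nucleus textures and class labels accompany every scene, so
segmentation, feature extraction and classification can all be validated
against a known answer.

Class presets encode the two cytological populations the pipeline is meant to
separate: hyperchromatic malignant-type nuclei (large, lobulated, texturally
heterogeneous, high N/C ratio) and normal nuclei (smaller, round, homogeneous).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import mask_circularity

# Unit optical-density stain vectors (hematoxylin, eosin, residual) from the
# standard published H&E color-deconvolution basis.
STAIN_H = np.array([0.65, 0.70, 0.29])
STAIN_H = STAIN_H / np.linalg.norm(STAIN_H)
STAIN_E = np.array([0.07, 0.99, 0.11])
STAIN_E = STAIN_E / np.linalg.norm(STAIN_E)
STAIN_D = np.array([0.27, 0.57, 0.78])
STAIN_D = STAIN_D / np.linalg.norm(STAIN_D)

_HARMONICS = np.arange(2, 7)  # radial harmonic orders of the contour family
_MAX_AMPLITUDE = 0.97  # contour radius stays positive for amplitude < 1
_PLACEMENT_ATTEMPTS = 1000
_EOSIN_OD = 0.25
_BACKGROUND_NOISE_SD = 2.0


class SynthesisError(ValueError):
    """Raised for unreachable targets or impossible placements."""


@dataclass(frozen=True)
class ClassPreset:
    """Target statistics of one nucleus population.

    Means and dispersions are in measurement units: area in px^2, circularity
    and N/C ratio dimensionless, chromatin entropy in bits, stain depth in
    optical density.
    """

    name: str
    area_mean: float
    area_sd: float
    circ_mean: float
    circ_sd: float
    entropy_mean: float
    entropy_sd: float
    nc_mean: float
    nc_sd: float
    stain_depth: float

    def __post_init__(self):
        if self.area_mean <= 0:
            raise ValueError("area_mean must be positive")
        if not 0 < self.circ_mean <= 1:
            raise ValueError("circ_mean must be in (0, 1]")
        if not 0 <= self.entropy_mean <= 8:
            raise ValueError("entropy_mean must be in [0, 8]")
        if self.nc_mean <= 0:
            raise ValueError("nc_mean must be positive")
        if min(self.area_sd, self.circ_sd, self.entropy_sd, self.nc_sd) < 0:
            raise ValueError("dispersions must be non-negative")
        if self.stain_depth <= 0:
            raise ValueError("stain_depth must be positive")


#: Hyperchromatic malignant-type nuclei: large, lobulated, heterogeneous chromatin.
PATHOLOGICAL = ClassPreset(
    name="pathological",
    area_mean=3737.5,
    area_sd=280.0,
    circ_mean=0.6750,
    circ_sd=0.04,
    entropy_mean=4.3875,
    entropy_sd=0.23,
    nc_mean=0.7075,
    nc_sd=0.05,
    stain_depth=1.0,
)

#: Normal nuclei: small, round, homogeneous chromatin, lower N/C ratio.
NORMAL = ClassPreset(
    name="normal",
    area_mean=2093.3,
    area_sd=60.0,
    circ_mean=0.8933,
    circ_sd=0.02,
    entropy_mean=2.8567,
    entropy_sd=0.06,
    nc_mean=0.4833,
    nc_sd=0.03,
    stain_depth=0.7,
)

PRESETS = {"pathological": PATHOLOGICAL, "normal": NORMAL}


@dataclass(frozen=True)
class NucleusSpec:
    """Instance-level sample of a class preset plus placement bookkeeping."""

    class_label: str
    target_area: float
    target_circularity: float
    target_entropy: float
    target_nc_ratio: float
    center: tuple[int, int]
    orientation: float
    seed: int


@dataclass
class SyntheticScene:
    """A rendered scene plus its ground truth.

    ``nucleus_masks`` are pairwise disjoint; each is contained in its
    ``cell_masks`` entry (nucleus plus cytoplasm).  ``textures`` holds the
    per-nucleus synthesized gray patch (canvas-sized, zero outside the mask).
    """

    image: np.ndarray
    nucleus_masks: list[np.ndarray]
    cell_masks: list[np.ndarray]
    labels: list[str]
    specs: list[NucleusSpec]
    textures: list[np.ndarray]


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size):
    """Normal(mean, sd) truncated to [lo, hi] by rejection; sd=0 degenerates."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    out = np.empty(size, dtype=float)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def sample_targets(preset: ClassPreset, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-nucleus target values: truncated normal at +/-4 sd around the
    preset means, intersected with the validity range of each quantity."""
    area = _truncated_normal(
        rng, preset.area_mean, preset.area_sd,
        max(100.0, preset.area_mean - 4 * preset.area_sd),
        preset.area_mean + 4 * preset.area_sd, n,
    )
    circ = _truncated_normal(
        rng, preset.circ_mean, preset.circ_sd,
        max(0.3, preset.circ_mean - 4 * preset.circ_sd),
        min(1.0, preset.circ_mean + 4 * preset.circ_sd), n,
    )
    entropy = _truncated_normal(
        rng, preset.entropy_mean, preset.entropy_sd,
        max(0.0, preset.entropy_mean - 4 * preset.entropy_sd),
        min(8.0, preset.entropy_mean + 4 * preset.entropy_sd), n,
    )
    nc = _truncated_normal(
        rng, preset.nc_mean, preset.nc_sd,
        max(0.05, preset.nc_mean - 4 * preset.nc_sd),
        preset.nc_mean + 4 * preset.nc_sd, n,
    )
    return pd.DataFrame({"area": area, "circularity": circ, "entropy": entropy, "nc_ratio": nc})


def sample_specs(
    preset: ClassPreset, n: int, canvas: tuple[int, int], seed: int
) -> list[NucleusSpec]:
    """Sample ``n`` nucleus specifications with non-overlapping placements.

    Placement uses rejection sampling on cell-level bounding circles with a
    3 px margin; a bounded number of attempts per nucleus turns an overfull
    canvas into an explicit error rather than an endless loop.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    targets = sample_targets(preset, n, rng)
    h, w = canvas
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    specs: list[NucleusSpec] = []
    for i in range(n):
        row = targets.iloc[i]
        cell_area = row["area"] * (1.0 + 1.0 / row["nc_ratio"])
        r_cell = float(np.sqrt(cell_area / np.pi)) * 1.25  # ellipse + contour slack
        if 2 * r_cell + 6 > min(h, w):
            raise SynthesisError("canvas too small for the sampled cell size")
        for attempt in range(_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(r_cell + 3, h - r_cell - 3)
            cx = rng.uniform(r_cell + 3, w - r_cell - 3)
            ok = all(
                np.hypot(cy - py, cx - px) >= r_cell + pr + 3
                for (py, px), pr in zip(centers, radii)
            )
            if ok:
                break
        else:
            raise SynthesisError(
                f"canvas too small: could not place nucleus {i + 1}/{n} "
                f"after {_PLACEMENT_ATTEMPTS} attempts"
            )
        centers.append((cy, cx))
        radii.append(r_cell)
        specs.append(
            NucleusSpec(
                class_label=preset.name,
                target_area=float(row["area"]),
                target_circularity=float(row["circularity"]),
                target_entropy=float(row["entropy"]),
                target_nc_ratio=float(row["nc_ratio"]),
                center=(int(round(cy)), int(round(cx))),
                orientation=float(rng.uniform(0.0, 180.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def _harmonic_profile(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random per-nucleus harmonic weights (summing to 1) and phases."""
    weights = np.abs(rng.normal(size=_HARMONICS.size)) + 0.1
    weights /= weights.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_HARMONICS.size)
    return weights, phases


def _rasterize_contour(
    target_area: float,
    amplitude: float,
    weights: np.ndarray,
    phases: np.ndarray,
    orientation_deg: float,
) -> np.ndarray:
    """Rasterize rho(theta) = R(1 + amplitude*sum_k w_k cos(k theta + phi_k))."""
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    mod = 1.0 + amplitude * np.sum(
        weights[:, None] * np.cos(_HARMONICS[:, None] * (theta[None, :] + np.radians(orientation_deg)) + phases[:, None]),
        axis=0,
    )
    # mean squared modulation sets the enclosed area of the smooth contour
    base_r = np.sqrt(target_area / (np.pi * np.mean(mod**2)))
    rho = base_r * mod
    pad = int(np.ceil(rho.max())) + 3
    # star-convex: pixel inside iff its radius <= rho at its polar angle
    yy, xx = np.mgrid[0:2 * pad, 0:2 * pad]
    dy, dx = yy - pad + 0.0, xx - pad + 0.0
    angle = np.arctan2(dy, dx) % (2.0 * np.pi)
    rho_wrap = np.concatenate([rho, rho[:1]])
    theta_wrap = np.concatenate([theta, [2.0 * np.pi]])
    rho_at = np.interp(angle, theta_wrap, rho_wrap)
    return np.hypot(dy, dx) <= rho_at


def circularity_calibration(
    target_area: float,
    weights: np.ndarray,
    phases: np.ndarray,
    orientation_deg: float = 0.0,
    n_grid: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone amplitude -> measured-circularity curve for one harmonic profile.

    Measures rasterized circularity on an amplitude grid and enforces
    monotone non-increase by running minimum (raster noise smoothing).
    """
    amplitudes = np.linspace(0.0, _MAX_AMPLITUDE, n_grid)
    circs = np.array(
        [
            mask_circularity(_rasterize_contour(target_area, a, weights, phases, orientation_deg))
            for a in amplitudes
        ]
    )
    circs = np.minimum.accumulate(circs)
    return amplitudes, circs


def make_nucleus_mask(
    target_area: float,
    target_circularity: float,
    orientation: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Binary nucleus mask with calibrated measured area and circularity.

    The contour is a star-convex radial-harmonic curve; its amplitude is read
    off a per-profile monotone calibration curve so the *measured* circularity
    (Crofton-perimeter ``4*pi*A/P**2``) lands on target, and the radius is
    rescaled after rasterization until the pixel-count area is within 2% of
    ``target_area``.
    """
    if target_area < 100:
        raise SynthesisError("target_area must be >= 100 px^2")
    if not 0.3 <= target_circularity <= 1.0:
        raise SynthesisError("target_circularity must be in [0.3, 1.0]")
    rng = np.random.default_rng(seed)
    # some harmonic profiles bottom out above a low circularity target;
    # redraw the profile (deterministically) until the target is reachable
    for _ in range(10):
        weights, phases = _harmonic_profile(rng)
        amplitudes, circs = circularity_calibration(target_area, weights, phases, orientation)
        if target_circularity >= circs[-1]:
            break
    else:
        raise SynthesisError(
            f"circularity {target_circularity:.3f} below calibration range "
            f"[{circs[-1]:.3f}, {circs[0]:.3f}]"
        )
    if target_circularity > circs[0]:
        amplitude = 0.0
    else:
        amplitude = float(np.interp(target_circularity, circs[::-1], amplitudes[::-1]))
    area = target_area
    for _ in range(8):
        mask = _rasterize_contour(area, amplitude, weights, phases, orientation)
        measured = mask.sum()
        if abs(measured - target_area) / target_area <= 0.02:
            break
        area *= target_area / measured
    return mask


def _entropy_of(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _concentration_distribution(lam: float) -> np.ndarray:
    """One-parameter family p_i ~ exp(-lam*(255-i)/255), mass at the dark end."""
    i = np.arange(256, dtype=float)
    w = np.exp(-lam * (255.0 - i) / 255.0)
    return w / w.sum()


def entropy_targeted_distribution(target_entropy: float) -> np.ndarray:
    """256-level distribution with exact Shannon entropy ``target_entropy``.

    Binary search on the concentration parameter of a geometric-like family
    whose entropy decreases continuously from 8 bits (uniform) toward 0.
    """
    if not 0.0 <= target_entropy <= 8.0:
        raise SynthesisError("target_entropy must be in [0, 8]")
    if target_entropy == 0.0:
        p = np.zeros(256)
        p[200] = 1.0
        return p
    lo, hi = 0.0, 1.0e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _entropy_of(_concentration_distribution(mid)) > target_entropy:
            lo = mid
        else:
            hi = mid
    return _concentration_distribution(0.5 * (lo + hi))


def synthesize_texture(mask: np.ndarray, target_entropy: float, seed: int = 0) -> np.ndarray:
    """Fill a mask with i.i.d. 8-bit levels of exactly-targeted entropy.

    Returns a canvas-sized uint8 raster, zero outside the mask.  The marginal
    histogram is what the chromatin-entropy descriptor measures, so no spatial
    structure is imposed.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 500:
        raise SynthesisError("mask too small for stable entropy (need >= 500 px)")
    p = entropy_targeted_distribution(target_entropy)
    rng = np.random.default_rng(seed)
    levels = rng.choice(256, size=n, p=p).astype(np.uint8)
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[mask] = levels
    return out


def _ellipse_mask(shape, center, area, axis_ratio, orientation_deg, scale=1.0):
    h, w = shape
    b = np.sqrt(scale * area / (np.pi * axis_ratio))  # minor semi-axis
    a = axis_ratio * b
    r = int(np.ceil(a)) + 2
    cy, cx = int(center[0]), int(center[1])
    rs, re = max(cy - r, 0), min(cy + r + 1, h)
    cs, ce = max(cx - r, 0), min(cx + r + 1, w)
    yy, xx = np.mgrid[rs:re, cs:ce]
    t = np.radians(orientation_deg)
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    out = np.zeros(shape, dtype=bool)
    out[rs:re, cs:ce] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _place(canvas_shape, local_mask, center) -> np.ndarray:
    """Paste a local boolean patch so its centroid lands on ``center``."""
    out = np.zeros(canvas_shape, dtype=bool)
    ph, pw = local_mask.shape
    r0 = int(center[0]) - ph // 2
    c0 = int(center[1]) - pw // 2
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + ph, canvas_shape[0]), min(c0 + pw, canvas_shape[1])
    out[rs:re, cs:ce] = local_mask[rs - r0 : re - r0, cs - c0 : ce - c0]
    return out


def render_scene(
    specs: list[NucleusSpec],
    canvas: tuple[int, int],
    seed: int = 0,
    presets: dict[str, ClassPreset] | None = None,
) -> SyntheticScene:
    """Render specs into an 8-bit RGB image with ground truth.

    Nucleus pixels absorb along the hematoxylin vector with per-pixel optical
    density ``stain_depth * texture/255``; the cytoplasm ellipse (scaled so the
    whole-cell area matches the target N/C ratio) absorbs a flat eosin OD;
    intensities follow Beer-Lambert ``I = 256*10**(-OD) - 1`` with additive
    Gaussian sensor noise (sd 2 levels).
    """
    presets = presets or PRESETS
    h, w = canvas
    rng = np.random.default_rng(seed)
    od = np.zeros((h, w, 3), dtype=float)
    nucleus_masks, cell_masks, textures, labels = [], [], [], []
    for spec in specs:
        preset = presets[spec.class_label]
        local = make_nucleus_mask(
            spec.target_area, spec.target_circularity, spec.orientation, spec.seed
        )
        nucleus = _place((h, w), local, spec.center)
        texture = synthesize_texture(nucleus, spec.target_entropy, spec.seed + 1)
        cell_area_target = nucleus.sum() * (1.0 + 1.0 / spec.target_nc_ratio)
        lo, hi = 0.5, 2.5
        cell = None
        for _ in range(12):  # bisect ellipse scale so union area hits the target
            mid = 0.5 * (lo + hi)
            ell = _ellipse_mask((h, w), spec.center, cell_area_target, 1.3, spec.orientation, mid)
            cell = ell | nucleus
            if cell.sum() < cell_area_target:
                lo = mid
            else:
                hi = mid
        od[nucleus] += (
            preset.stain_depth * (texture[nucleus, None].astype(float) / 255.0) * STAIN_H[None, :]
        )
        od[cell] += _EOSIN_OD * STAIN_E[None, :]
        nucleus_masks.append(nucleus)
        cell_masks.append(cell)
        textures.append(texture)
        labels.append(spec.class_label)
    intensity = 256.0 * np.power(10.0, -od) - 1.0
    intensity += rng.normal(0.0, _BACKGROUND_NOISE_SD, size=intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=image,
        nucleus_masks=nucleus_masks,
        cell_masks=cell_masks,
        labels=labels,
        specs=specs,
        textures=textures,
    )


def generate_scene(
    preset_name: str, n: int, canvas: tuple[int, int], seed: int
) -> SyntheticScene:
    """Convenience wrapper: sample specs and render one scene.

    ``preset_name`` may be ``"pathological"``, ``"normal"`` or ``"mixed"``
    (half each, pathological first).
    """
    if preset_name == "mixed":
        n_path = n // 2 + n % 2
        specs = sample_specs(PATHOLOGICAL, n_path, canvas, seed)
        # reuse occupied placements by sampling normals on a jittered seed until disjoint
        normals = _sample_additional(NORMAL, n - n_path, canvas, seed + 1, specs)
        specs = specs + normals
    else:
        specs = sample_specs(PRESETS[preset_name], n, canvas, seed)
    return render_scene(specs, canvas, seed)


def _sample_additional(preset, n, canvas, seed, existing: list[NucleusSpec]):
    """Sample further specs avoiding cells already placed."""
    rng = np.random.default_rng(seed)
    targets = sample_targets(preset, n, rng)
    h, w = canvas
    occupied = [
        (s.center, np.sqrt(s.target_area * (1 + 1 / s.target_nc_ratio) / np.pi) * 1.25)
        for s in existing
    ]
    specs: list[NucleusSpec] = []
    for i in range(n):
        row = targets.iloc[i]
        r_cell = float(np.sqrt(row["area"] * (1 + 1 / row["nc_ratio"]) / np.pi)) * 1.25
        for attempt in range(_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(r_cell + 3, h - r_cell - 3)
            cx = rng.uniform(r_cell + 3, w - r_cell - 3)
            if all(np.hypot(cy - py, cx - px) >= r_cell + pr + 3 for (py, px), pr in occupied):
                break
        else:
            raise SynthesisError("canvas too small for mixed scene")
        occupied.append(((cy, cx), r_cell))
        specs.append(
            NucleusSpec(
                class_label=preset.name,
                target_area=float(row["area"]),
                target_circularity=float(row["circularity"]),
                target_entropy=float(row["entropy"]),
                target_nc_ratio=float(row["nc_ratio"]),
                center=(int(round(cy)), int(round(cx))),
                orientation=float(rng.uniform(0.0, 180.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------


def label_raster(masks: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """16-bit label image: 0 = background, i = nucleus i (1-based)."""
    out = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        out[m] = i
    return out


def save_scene(scene: SyntheticScene, outdir: str | Path, stem: str = "scene") -> dict:
    """Write image (PNG), 16-bit label masks (PNG), spec CSV and manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_path = outdir / f"{stem}.png"
    Image.fromarray(scene.image).save(image_path)
    shape = scene.image.shape[:2]
    masks_path = outdir / f"{stem}_masks.png"
    Image.fromarray(label_raster(scene.nucleus_masks, shape)).save(masks_path)
    cells_path = outdir / f"{stem}_cells.png"
    Image.fromarray(label_raster(scene.cell_masks, shape)).save(cells_path)
    rows = []
    for i, spec in enumerate(scene.specs):
        d = asdict(spec)
        d["id"] = i + 1
        rows.append(d)
    csv_path = outdir / f"{stem}_specs.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    manifest = {
        "image": image_path.name,
        "nucleus_masks": masks_path.name,
        "cell_masks": cells_path.name,
        "specs": csv_path.name,
        "n_nuclei": len(scene.specs),
        "canvas": list(shape),
        "labels": scene.labels,
    }
    (outdir / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
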
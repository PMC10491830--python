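"""Synthetic stained-root micrographs with known ground truth.

Emulates brightfield images of root segments stained with a blue dye:
fungal structures (intraradical hyphae, arbuscules, vesicles) render dark
blue, the host root as a lighter translucent band, and the slide background
near white.  Every scene carries exact pixel masks for the root and the
colonized area, so segmentation and index recovery can be benchmarked
without any real micrograph.

Structures
----------
* hyphae  — anti-aliased curvilinear strokes (smoothed random walks);
* arbuscules — dense dendritic blobs grown as dilated branching skeletons
  confined to an elliptical cell-sized patch;
* vesicles — filled ellipses;
* extraradical hyphae (optional) — strokes outside the root band, rendered
  dark but *excluded* from the colonized mask, since only intraradical
  structures count as colonization.

Intensity ordering ``background_level > root_level > fungus_level`` is
guaranteed before noise, so a brightness threshold between fungus and root
levels recovers the colonized area essentially exactly on noise-free
scenes.  Sensor noise and a linear illumination ramp are applied last.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter1d

from .errors import PlacementError, ValidationError
from .raster_io import BinaryMask, RgbImage, write_image, write_mask

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "generate_dataset"]

#: Slightly blue colorization of a grayscale level L.  Chosen so the BT.601
#: luminance of the tinted pixel equals L (0.299*0.985 + 0.587 + 0.114*1.04
#: = 1.000) and no channel clips for L <= 245.
_TINT = (0.985, 1.00, 1.04)

#: How many structure placements generate_scene may attempt beyond the
#: requested inventory before reporting the achieved fraction.
PLACEMENT_BUDGET = 400

#: Declared tolerance on the achieved colonized fraction.
FRACTION_TOL = 0.02


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters for one synthetic micrograph.

    Intensities are mean 8-bit levels before noise; the invariant
    ``background_level > root_level > fungus_level`` mirrors the staining
    contrast (fungal walls take up the dye, plant tissue stays translucent).
    """

    geometry: tuple[int, int] = (192, 256)
    root_width_fraction: float = 0.5
    target_colonization: float = 0.2
    n_arbuscules: int = 3
    n_hyphae: int = 6
    n_vesicles: int = 2
    include_extraradical: bool = False
    background_level: float = 252.0
    root_level: float = 205.0
    fungus_level: float = 70.0
    noise_sd: float = 4.0
    illumination_gradient: float = 0.04
    seed: int = 0

    def __post_init__(self):
        h, w = self.geometry
        if h < 8 or w < 8:
            raise ValidationError("scene geometry must be at least 8x8")
        if not (0.0 < self.root_width_fraction < 1.0):
            raise ValidationError("root_width_fraction must lie in (0, 1)")
        if not (0.0 <= self.target_colonization <= 1.0):
            raise ValidationError("target_colonization must lie in [0, 1]")
        if min(self.n_arbuscules, self.n_hyphae, self.n_vesicles) < 0:
            raise ValidationError("structure counts must be non-negative")
        if not (self.background_level > self.root_level > self.fungus_level):
            raise ValidationError(
                "intensity ordering background_level > root_level > fungus_level required"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.illumination_gradient <= 1.0):
            raise ValidationError("illumination_gradient must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticScene:
    """Generated micrograph plus its ground truth."""

    image: RgbImage
    root_mask: BinaryMask
    colonized_mask: BinaryMask
    true_fraction: float
    params: SceneParams
    budget_exhausted: bool = False


def _root_band(h: int, w: int, width_fraction: float, rng) -> np.ndarray:
    """Smooth horizontal band occupying ``width_fraction`` of image height."""
    half = width_fraction * h / 2.0
    center = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    wiggle = rng.normal(0.0, 1.0, w)
    wiggle = gaussian_filter1d(wiggle, w / 12.0, mode="reflect")
    wiggle *= 0.04 * h / max(np.abs(wiggle).max(), 1e-9)
    rows = np.arange(h)[:, None]
    top = center - half + wiggle[None, :]
    bottom = center + half + wiggle[None, :]
    return (rows >= top) & (rows <= bottom)


def _stroke(h, w, rng, inside: np.ndarray, length: int, thickness: int) -> np.ndarray:
    """Anti-alias-free rasterized smoothed random walk, clipped to bounds."""
    ys, xs = np.nonzero(inside)
    if len(ys) == 0:
        return np.zeros((h, w), bool)
    k = rng.integers(len(ys))
    y, x = float(ys[k]), float(xs[k])
    angle = rng.uniform(0, 2 * np.pi)
    pts = []
    for _ in range(length):
        pts.append((y, x))
        angle += rng.normal(0.0, 0.35)
        y += np.sin(angle)
        x += np.cos(angle)
        if not (0 <= y < h and 0 <= x < w):
            break
    mask = np.zeros((h, w), bool)
    for py, px in pts:
        mask[int(py), int(px)] = True
    if thickness > 1:
        mask = binary_dilation(mask, iterations=thickness - 1)
    return mask


def _arbuscule(h, w, rng, inside: np.ndarray, radius: int) -> np.ndarray:
    """Dendritic blob: branching skeleton grown inside an elliptical patch."""
    ys, xs = np.nonzero(inside)
    if len(ys) == 0:
        return np.zeros((h, w), bool)
    k = rng.integers(len(ys))
    cy, cx = float(ys[k]), float(xs[k])
    ry = radius * rng.uniform(0.7, 1.0)
    rx = radius * rng.uniform(0.7, 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    patch = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    skel = np.zeros((h, w), bool)
    # trunk plus recursive-ish branches: several short walks from the center
    n_branches = rng.integers(5, 9)
    for _ in range(n_branches):
        y, x = cy, cx
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(int(radius * 1.5)):
            iy, ix = int(y), int(x)
            if 0 <= iy < h and 0 <= ix < w:
                skel[iy, ix] = True
            angle += rng.normal(0.0, 0.5)
            y += np.sin(angle)
            x += np.cos(angle)
    skel = binary_dilation(skel, iterations=1)
    return skel & patch


def _vesicle(h, w, rng, inside: np.ndarray, radius: int) -> np.ndarray:
    ys, xs = np.nonzero(inside)
    if len(ys) == 0:
        return np.zeros((h, w), bool)
    k = rng.integers(len(ys))
    cy, cx = float(ys[k]), float(xs[k])
    ry = radius * rng.uniform(0.6, 1.0)
    rx = radius * rng.uniform(0.6, 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one synthetic micrograph with ground-truth masks.

    Deterministic for a given seed.  Structures from the requested
    inventory are placed first; placements then continue (cycling over the
    structure types with nonzero counts) until the colonized fraction of
    the root area is within ``FRACTION_TOL`` of ``target_colonization`` or
    the placement budget runs out, in which case the achieved fraction is
    reported and flagged.  A target > 0 with an all-zero inventory raises
    :class:`PlacementError`.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.geometry
    root = _root_band(h, w, params.root_width_fraction, rng)
    root_area = int(root.sum())
    target = params.target_colonization

    n_structures = params.n_hyphae + params.n_arbuscules + params.n_vesicles
    if target > FRACTION_TOL and n_structures == 0:
        raise PlacementError(target, 0.0, None)

    scale = max(3, int(min(h, w) * 0.04))
    colonized = np.zeros((h, w), bool)

    def place(kind: str, deficit_px: float) -> np.ndarray:
        # size each structure to at most the remaining deficit so the
        # greedy loop converges onto the target instead of oscillating
        if kind == "hypha":
            length = int(np.clip(deficit_px / 3.0, 8, min(h, w) * 0.8))
            return _stroke(h, w, rng, root, length=length, thickness=2) & root
        if kind == "arbuscule":
            r = int(np.clip(np.sqrt(deficit_px / 3.0), 3, scale * 2))
            return _arbuscule(h, w, rng, root, radius=r) & root
        r = int(np.clip(np.sqrt(deficit_px / np.pi), 2, scale))
        return _vesicle(h, w, rng, root, radius=r) & root

    def frac() -> float:
        return colonized.sum() / root_area if root_area else 0.0

    # cycle over structure types in proportion to the requested inventory
    cycle = (["hypha"] * params.n_hyphae + ["arbuscule"] * params.n_arbuscules
             + ["vesicle"] * params.n_vesicles)
    budget_exhausted = False
    if target > 0 and root_area > 0 and cycle:
        attempts = 0
        # stop once comfortably inside the declared tolerance band, but
        # always place at least one structure for a nonzero target
        while target - frac() > FRACTION_TOL / 4 or not colonized.any():
            if attempts >= PLACEMENT_BUDGET:
                budget_exhausted = True
                break
            kind = cycle[attempts % len(cycle)]
            deficit_px = (target - frac()) * root_area
            candidate = colonized | place(kind, deficit_px)
            if candidate.sum() / root_area <= target + FRACTION_TOL:
                colonized = candidate
            attempts += 1

    extraradical = np.zeros((h, w), bool)
    if params.include_extraradical:
        outside = ~root
        for _ in range(max(2, params.n_hyphae // 2)):
            extraradical |= _stroke(h, w, rng, outside,
                                    length=int(min(h, w) * 0.6), thickness=1)
        extraradical &= ~root  # never counted as colonized

    # intensity field, ordered by construction
    levels = np.full((h, w), params.background_level)
    levels[root] = params.root_level
    levels[colonized] = params.fungus_level
    levels[extraradical & ~root] = params.fungus_level

    if params.illumination_gradient > 0:
        ramp = 1.0 + params.illumination_gradient * (
            np.linspace(-0.5, 0.5, w)[None, :]
        )
        levels = levels * ramp
    if params.noise_sd > 0:
        levels = levels + rng.normal(0.0, params.noise_sd, (h, w))
    levels = np.clip(levels, 0, 255)

    rgb = np.clip(np.stack([levels * t for t in _TINT], axis=-1), 0, 255)
    image = RgbImage(np.floor(rgb + 0.5).astype(np.uint8))

    root_mask = BinaryMask(root)
    colonized_mask = BinaryMask(colonized & root)
    true_fraction = colonized_mask.area / root_mask.area if root_mask.area else 0.0
    return SyntheticScene(
        image=image,
        root_mask=root_mask,
        colonized_mask=colonized_mask,
        true_fraction=float(true_fraction),
        params=params,
        budget_exhausted=budget_exhausted,
    )


def generate_dataset(class_targets, base: SceneParams, out_dir=None):
    """Generate a labeled scene collection mirroring a six-class study design.

    Parameters
    ----------
    class_targets : list of (class_id, n, (lo, hi))
        For each visual class, generate ``n`` scenes with target colonized
        fractions drawn uniformly in ``[lo, hi]``.
    base : SceneParams
        Template parameters; per-scene seed and target are derived from
        ``base.seed`` deterministically.
    out_dir : path, optional
        If given, scenes are written as PNGs (image + root/colonized masks)
        with a ``manifest.csv`` (columns file, class, true_fraction, seed).

    Returns
    -------
    (scenes, manifest) : list of SyntheticScene, list of dict rows
    """
    if not class_targets:
        raise ValidationError("class_targets must not be empty")
    for cid, n, (lo, hi) in class_targets:
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError(f"class {cid}: range [{lo}, {hi}] outside [0, 1]")
        if n < 0:
            raise ValidationError(f"class {cid}: negative count")

    rng = np.random.default_rng(base.seed)
    scenes: list[SyntheticScene] = []
    manifest: list[dict] = []
    for cid, n, (lo, hi) in class_targets:
        for i in range(n):
            target = float(rng.uniform(lo, hi))
            seed = int(rng.integers(0, 2**31 - 1))
            params = replace(base, target_colonization=target, seed=seed)
            scene = generate_scene(params)
            fname = f"class{cid}_{i:03d}.png"
            scenes.append(scene)
            manifest.append({
                "file": fname,
                "class": cid,
                "true_fraction": scene.true_fraction,
                "seed": seed,
            })

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for scene, row in zip(scenes, manifest):
            write_image(scene.image, out_dir / row["file"])
            stem = Path(row["file"]).stem
            write_mask(scene.root_mask, out_dir / f"{stem}_root.png")
            write_mask(scene.colonized_mask, out_dir / f"{stem}_colonized.png")
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["file", "class", "true_fraction", "seed"])
            writer.writeheader()
            writer.writerows(manifest)
    return scenes, manifest
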
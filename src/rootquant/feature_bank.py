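"""The 25-component per-pixel feature bank for pixel classification.

Each pixel of a grayscale micrograph is described by a 25-vector built
from four filter families:

* channels 1–5: Gaussian blurs at five scales (local mean intensity);
* channels 6–10: gradient magnitude (Sobel) of the Gaussian blurs at five
  scales (edges of stained structures);
* channels 11–22: Gabor magnitude responses on a 3-frequency x
  4-orientation grid (oriented texture — hyphal filaments);
* channels 23–25: Hessian features at one scale — larger eigenvalue,
  smaller eigenvalue and determinant (ridge/blob geometry, suited to
  thin hyphae and dense arbuscules).

All filters use reflective boundary padding.  Default scales are
octave-spaced to span typical hypha widths at low magnification; every
parameter is configurable and is stored alongside any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import gabor, sobel

from .errors import ValidationError
from .raster_io import GrayImage

__all__ = ["FeatureConfig", "FeatureStack", "compute_feature_stack", "sample_features"]


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the 25-channel bank: 5 + 5 + 3x4 + 3 = 25 exactly."""

    gaussian_sigmas: tuple = (1.0, 2.0, 4.0, 8.0, 16.0)
    sobel_sigmas: tuple = (1.0, 2.0, 4.0, 8.0, 16.0)
    gabor_frequencies: tuple = (0.05, 0.12, 0.25)  # cycles / pixel
    gabor_orientations: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    hessian_sigma: float = 2.0

    def __post_init__(self):
        n = (len(self.gaussian_sigmas) + len(self.sobel_sigmas)
             + len(self.gabor_frequencies) * len(self.gabor_orientations) + 3)
        if n != 25:
            raise ValidationError(
                f"feature configuration yields {n} channels; exactly 25 required"
            )
        for name in ("gaussian_sigmas", "sobel_sigmas", "gabor_frequencies"):
            vals = getattr(self, name)
            if any(v <= 0 for v in vals):
                raise ValidationError(f"{name} must be positive")
            if list(vals) != sorted(set(vals)):
                raise ValidationError(f"{name} must be strictly increasing")
        if any(not (0 <= t < np.pi) for t in self.gabor_orientations):
            raise ValidationError("gabor_orientations must lie in [0, pi)")
        if self.hessian_sigma <= 0:
            raise ValidationError("hessian_sigma must be positive")

    @property
    def channel_names(self) -> tuple:
        names = [f"gaussian_s{s:g}" for s in self.gaussian_sigmas]
        names += [f"sobel_of_gaussian_s{s:g}" for s in self.sobel_sigmas]
        names += [
            f"gabor_f{f:g}_t{np.degrees(t):g}"
            for f in self.gabor_frequencies
            for t in self.gabor_orientations
        ]
        s = self.hessian_sigma
        names += [f"hessian_l1_s{s:g}", f"hessian_l2_s{s:g}", f"hessian_det_s{s:g}"]
        return tuple(names)

    def to_dict(self) -> dict:
        return {
            "gaussian_sigmas": list(self.gaussian_sigmas),
            "sobel_sigmas": list(self.sobel_sigmas),
            "gabor_frequencies": list(self.gabor_frequencies),
            "gabor_orientations": list(self.gabor_orientations),
            "hessian_sigma": self.hessian_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            gaussian_sigmas=tuple(d["gaussian_sigmas"]),
            sobel_sigmas=tuple(d["sobel_sigmas"]),
            gabor_frequencies=tuple(d["gabor_frequencies"]),
            gabor_orientations=tuple(d["gabor_orientations"]),
            hessian_sigma=float(d["hessian_sigma"]),
        )


@dataclass(frozen=True)
class FeatureStack:
    """25 x H x W array of per-pixel features with fixed channel order."""

    channels: np.ndarray
    channel_names: tuple
    geometry: tuple

    def __post_init__(self):
        ch = np.asarray(self.channels)
        if ch.ndim != 3 or ch.shape[0] != 25:
            raise ValidationError(f"feature stack must be 25xHxW, got {ch.shape}")
        if len(self.channel_names) != 25 or len(set(self.channel_names)) != 25:
            raise ValidationError("25 unique channel names required")
        if ch.shape[1:] != tuple(self.geometry):
            raise ValidationError("channel geometry does not match declared geometry")
        if not np.all(np.isfinite(ch)):
            raise ValidationError("feature stack contains non-finite values")


def compute_feature_stack(img: GrayImage, cfg: FeatureConfig | None = None) -> FeatureStack:
    """Compute the 25-channel feature stack of a grayscale image."""
    if cfg is None:
        cfg = FeatureConfig()
    px = img.pixels.astype(np.float64)
    channels = []
    for s in cfg.gaussian_sigmas:
        channels.append(gaussian_filter(px, s, mode="reflect"))
    for s in cfg.sobel_sigmas:
        blurred = gaussian_filter(px, s, mode="reflect")
        channels.append(sobel(blurred))
    for f in cfg.gabor_frequencies:
        for t in cfg.gabor_orientations:
            real, imag = gabor(px, frequency=f, theta=t, mode="reflect")
            channels.append(np.hypot(real, imag))
    hrr, hrc, hcc = hessian_matrix(
        px, sigma=cfg.hessian_sigma, mode="reflect", use_gaussian_derivatives=False
    )
    l1, l2 = hessian_matrix_eigvals([hrr, hrc, hcc])  # l1 >= l2 everywhere
    channels.append(l1)
    channels.append(l2)
    channels.append(l1 * l2)  # determinant
    stack = np.stack(channels, axis=0)
    return FeatureStack(stack, cfg.channel_names, img.geometry)


def sample_features(stack: FeatureStack, coordinates) -> np.ndarray:
    """Extract the 25-vectors at (row, col) coordinates, order preserved.

    Returns an (n, 25) array; an empty coordinate list yields shape (0, 25).
    """
    h, w = stack.geometry
    coords = list(coordinates)
    if not coords:
        return np.empty((0, 25))
    rows = np.empty(len(coords), dtype=np.intp)
    cols = np.empty(len(coords), dtype=np.intp)
    for i, (r, c) in enumerate(coords):
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"coordinate ({r}, {c}) out of bounds for {h}x{w}")
        rows[i], cols[i] = r, c
    return stack.channels[:, rows, cols].T.copy()
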
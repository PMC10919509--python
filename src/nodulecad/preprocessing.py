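"""Slice denoising, image-quality metrics and foreground segmentation.

Denoisers
---------
``mean_shift`` — iterated joint spatial/range kernel filtering: every pixel
moves toward the mode of the local kernel density estimated with a Gaussian
spatial kernel of bandwidth ``hs`` and a Gaussian range kernel of bandwidth
``hr``.

``gaussian`` / ``perona_malik`` / ``catte`` — explicit finite-difference
diffusion with reflective (Neumann) boundaries. ``gaussian`` is linear
diffusion; ``perona_malik`` uses conductance g(|∇I|) = 1/(1+(|∇I|/kappa)^2)
on raw differences; ``catte`` evaluates the same conductance on a
Gaussian-presmoothed copy of the image, which makes the edge-stopping
decision robust to noise.

Quality metrics: PSNR (peak 1.0 on the normalized scale), Pratt's figure of
merit on edge maps, and mean SSIM with a uniform window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage.metrics import structural_similarity

from .errors import ValidationError

DENOISE_METHODS = ("gaussian", "perona_malik", "catte", "mean_shift")


@dataclass
class ImageSlice:
    """A 2D grayscale slice with values normalized to [0, 1]."""

    pixels: np.ndarray
    spacing: float | None = None  # mm per pixel, when known
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("ImageSlice requires a 2D array")
        if not np.isfinite(self.pixels).all():
            raise ValidationError("pixel values must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValidationError("pixel values must lie in [0, 1]; normalize first")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize(pixels: np.ndarray, spacing: float | None = None, source_id: str = "") -> ImageSlice:
    """Min-max normalize an arbitrary grayscale array into an ImageSlice."""
    px = np.asarray(pixels, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        px = (px - lo) / (hi - lo)
    else:
        px = np.zeros_like(px)
    return ImageSlice(pixels=px, spacing=spacing, source_id=source_id)


@dataclass(frozen=True)
class DenoiseConfig:
    method: str = "catte"
    hs: float = 2.0       # spatial bandwidth (pixels), mean-shift
    hr: float = 0.1       # range bandwidth (gray units), mean-shift
    iterations: int = 10
    kappa: float = 0.1    # diffusion conductance scale
    dt: float = 0.2       # explicit diffusion step
    presmooth_sigma: float = 1.0  # catte gradient presmoothing

    def __post_init__(self):
        if self.method not in DENOISE_METHODS:
            raise ValidationError(f"unknown denoise method {self.method!r}")
        if self.hs <= 0 or self.hr <= 0:
            raise ValidationError("bandwidths must be > 0")
        if not (0 < self.dt <= 0.25):
            raise ValidationError("dt must satisfy 0 < dt <= 0.25 (2D stability)")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")


_MEAN_SHIFT_TOL = 1e-4


def mean_shift_filter(img: ImageSlice, cfg: DenoiseConfig) -> ImageSlice:
    """Joint spatial/range mean-shift filtering of the intensity image.

    Each pixel's value is repeatedly replaced by the Gaussian-kernel
    weighted mean of its spatial neighbours, with range weights computed
    against the pixel's current value — gradient ascent on the joint
    density, stopping at convergence (max change < 1e-4) or the iteration
    cap.
    """
    if cfg.method != "mean_shift":
        raise ValidationError("cfg.method must be 'mean_shift'")
    radius = max(1, int(math.ceil(2 * cfg.hs)))
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= (2 * cfg.hs) ** 2
    ]
    sw = np.array(
        [math.exp(-(dy * dy + dx * dx) / (2 * cfg.hs**2)) for dy, dx in offsets]
    )
    values = img.pixels.copy()
    padded_ref = np.pad(img.pixels, radius, mode="reflect")
    h, w = values.shape
    for _ in range(cfg.iterations):
        num = np.zeros_like(values)
        den = np.zeros_like(values)
        for (dy, dx), wgt in zip(offsets, sw):
            nb = padded_ref[
                radius + dy : radius + dy + h, radius + dx : radius + dx + w
            ]
            rw = np.exp(-((nb - values) ** 2) / (2 * cfg.hr**2)) * wgt
            num += rw * nb
            den += rw
        new = num / den
        change = float(np.abs(new - values).max())
        values = new
        if change < _MEAN_SHIFT_TOL:
            break
    return ImageSlice(
        pixels=np.clip(values, 0.0, 1.0),
        spacing=img.spacing,
        source_id=img.source_id,
    )


def _neighbor_diffs(u: np.ndarray):
    """One-sided N/S/E/W differences with reflective boundaries."""
    p = np.pad(u, 1, mode="edge")
    dn = p[:-2, 1:-1] - u
    ds = p[2:, 1:-1] - u
    de = p[1:-1, 2:] - u
    dw = p[1:-1, :-2] - u
    return dn, ds, de, dw


def diffuse(img: ImageSlice, cfg: DenoiseConfig) -> ImageSlice:
    """Explicit iterated diffusion: gaussian, perona_malik or catte."""
    if cfg.method not in ("gaussian", "perona_malik", "catte"):
        raise ValidationError(f"diffuse does not handle method {cfg.method!r}")
    u = img.pixels.copy()
    k2 = cfg.kappa**2
    for _ in range(cfg.iterations):
        dn, ds, de, dw = _neighbor_diffs(u)
        if cfg.method == "gaussian":
            cn = cs = ce = cw = 1.0
        else:
            if cfg.method == "catte":
                us = ndi.gaussian_filter(u, cfg.presmooth_sigma, mode="reflect")
                gn, gs, ge, gw = _neighbor_diffs(us)
            else:
                gn, gs, ge, gw = dn, ds, de, dw
            cn = 1.0 / (1.0 + gn**2 / k2)
            cs = 1.0 / (1.0 + gs**2 / k2)
            ce = 1.0 / (1.0 + ge**2 / k2)
            cw = 1.0 / (1.0 + gw**2 / k2)
        u = u + cfg.dt * (cn * dn + cs * ds + ce * de + cw * dw)
    return ImageSlice(
        pixels=np.clip(u, 0.0, 1.0), spacing=img.spacing, source_id=img.source_id
    )


def denoise(img: ImageSlice, cfg: DenoiseConfig) -> ImageSlice:
    """Dispatch to the configured denoiser."""
    if cfg.method == "mean_shift":
        return mean_shift_filter(img, cfg)
    return diffuse(img, cfg)


def psnr(reference: ImageSlice | np.ndarray, test: ImageSlice | np.ndarray) -> float:
    """Peak signal-to-noise ratio, 10*log10(1 / MSE), in dB.

    Identical images yield +inf.
    """
    a = reference.pixels if isinstance(reference, ImageSlice) else np.asarray(reference, float)
    b = test.pixels if isinstance(test, ImageSlice) else np.asarray(test, float)
    if a.shape != b.shape:
        raise ValidationError("psnr requires same-shape images")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def fom(reference_edges: np.ndarray, test_edges: np.ndarray, alpha: float = 1.0 / 9.0) -> float:
    """Pratt's figure of merit between two binary edge maps.

    (1/max(Nr, Nt)) * sum over test edge pixels of 1/(1 + alpha*d^2),
    d = distance to the nearest reference edge pixel.
    """
    ref = np.asarray(reference_edges, bool)
    tst = np.asarray(test_edges, bool)
    if ref.shape != tst.shape:
        raise ValidationError("edge maps must share a shape")
    nr, nt = int(ref.sum()), int(tst.sum())
    if nr == 0:
        raise ValidationError("reference edge map has no edge pixels")
    if nt == 0:
        return 0.0
    dist = ndi.distance_transform_edt(~ref)
    d = dist[tst]
    return float(np.sum(1.0 / (1.0 + alpha * d**2)) / max(nr, nt))


def sobel_edge_map(img: ImageSlice | np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary edge map from thresholded Sobel gradient magnitude.

    Default threshold: half the maximum gradient magnitude.
    """
    px = img.pixels if isinstance(img, ImageSlice) else np.asarray(img, float)
    mag = skfilters.sobel(px)
    if threshold is None:
        threshold = 0.5 * float(mag.max())
    return mag > threshold


def ssim(reference: ImageSlice | np.ndarray, test: ImageSlice | np.ndarray, window: int = 7) -> float:
    """Mean structural similarity with a uniform window.

    Constants C1 = (0.01)^2, C2 = (0.03)^2 on the unit gray scale.
    """
    a = reference.pixels if isinstance(reference, ImageSlice) else np.asarray(reference, float)
    b = test.pixels if isinstance(test, ImageSlice) else np.asarray(test, float)
    if a.shape != b.shape:
        raise ValidationError("ssim requires same-shape images")
    if window > min(a.shape) or window % 2 == 0 or window < 3:
        raise ValidationError("window must be odd, >= 3 and fit inside the image")
    return float(
        structural_similarity(
            a, b, win_size=window, data_range=1.0, gaussian_weights=False
        )
    )


@dataclass(frozen=True)
class SegmentConfig:
    """Adaptive-threshold segmentation parameters.

    ``threshold=None`` selects the threshold with Otsu's criterion on a
    256-bin histogram; a float overrides it. ``closing_radius=0`` disables
    the rolling-ball closing; ``fill_holes=False`` disables cavity filling.
    """

    threshold: float | None = None
    nbins: int = 256
    closing_radius: int = 2
    fill_holes: bool = True


def segment_foreground(img: ImageSlice, cfg: SegmentConfig = SegmentConfig()) -> np.ndarray:
    """Adaptive threshold -> cavity filling -> disk ("rolling ball") closing.

    A degenerate single-level histogram yields an empty mask with a warning
    rather than an exception.
    """
    px = img.pixels
    t = cfg.threshold
    if t is None:
        if np.ptp(px) == 0:
            warnings.warn(
                "degenerate single-level histogram; returning empty mask",
                stacklevel=2,
            )
            return np.zeros(px.shape, dtype=bool)
        t = float(skfilters.threshold_otsu(px, nbins=cfg.nbins))
    mask = px > t
    if cfg.fill_holes:
        mask = ndi.binary_fill_holes(mask)
    if cfg.closing_radius > 0:
        mask = skmorph.closing(mask, skmorph.disk(cfg.closing_radius)).astype(bool)
    return mask
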
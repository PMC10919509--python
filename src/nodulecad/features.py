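"""Hybrid feature extraction for candidate regions.

Three feature families per candidate:

* gray statistics on the masked pixels — mean, variance, histogram energy
  sum(H(k)^2), histogram entropy -sum(H log2 H), and calcification fraction
  (share of masked pixels brighter than a threshold T);
* co-occurrence texture — contrast sum (i-j)^2 S(i,j) and homogeneity
  sum S(i,j)/(1+(i-j)^2) of the gray-level co-occurrence matrix, averaged
  over the four standard angles, at one or more pixel distances;
* shape — the 2D descriptor block shared with the rule cropper, plus an
  optional voxel-based 3D block (volume, surface, sphericity, compactness)
  when a mask stack is available.

The default configuration emits exactly 17 named features: 5 gray + 6
shape + 4 texture (distances 1 and 2) + 2 gradient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters

from .candidate_detection import NoduleCandidate, compute_descriptors
from .errors import ValidationError
from .preprocessing import ImageSlice

GLCM_ANGLES = (0, 45, 90, 135)

# (drow, dcol) unit offsets per angle, for distance d multiply by d
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GrayHistogram:
    """Normalized histogram over L uniform gray bins on [0, 1]."""

    H: np.ndarray
    L: int

    def __post_init__(self):
        h = np.asarray(self.H, float)
        if h.ndim != 1 or h.size != self.L:
            raise ValidationError("histogram length must equal L")
        if (h < 0).any() or abs(h.sum() - 1.0) > 1e-9:
            raise ValidationError("histogram must be non-negative and sum to 1")


@dataclass(frozen=True)
class GLCM:
    """Normalized L x L gray-level co-occurrence matrix at offset (d, theta)."""

    S: np.ndarray
    d: int
    theta: int
    L: int
    symmetric: bool = True

    def __post_init__(self):
        s = np.asarray(self.S, float)
        if s.shape != (self.L, self.L):
            raise ValidationError("GLCM must be L x L")
        if (s < 0).any() or abs(s.sum() - 1.0) > 1e-9:
            raise ValidationError("GLCM entries must be non-negative and sum to 1")
        if self.theta not in GLCM_ANGLES:
            raise ValidationError(f"theta must be one of {GLCM_ANGLES}")


def quantize(values: np.ndarray, L: int) -> np.ndarray:
    """Uniform quantization of [0, 1] values into integer levels 0..L-1."""
    if L < 2:
        raise ValidationError("need at least 2 gray levels")
    return np.minimum((np.asarray(values, float) * L).astype(int), L - 1)


def gray_histogram(intensities: np.ndarray, L: int = 16) -> GrayHistogram:
    """Histogram of masked intensities over L uniform bins."""
    v = np.asarray(intensities, float).ravel()
    if v.size == 0:
        raise ValidationError("empty mask: no pixels to histogram")
    counts = np.bincount(quantize(v, L), minlength=L).astype(float)
    return GrayHistogram(H=counts / counts.sum(), L=L)


def energy(h: GrayHistogram) -> float:
    """Ex = sum_k H(k)^2."""
    return float(np.sum(h.H**2))


def entropy(h: GrayHistogram, base: float = 2.0) -> float:
    """Hx = -sum_k H(k) * log H(k), with 0*log(0) = 0. Default base 2."""
    p = h.H[h.H > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))


def calcification(intensities: np.ndarray, T: float = 0.9) -> float:
    """Fraction of masked pixels with intensity strictly above T."""
    if not (0.0 <= T <= 1.0):
        raise ValidationError("threshold T must lie in [0, 1]")
    v = np.asarray(intensities, float).ravel()
    if v.size == 0:
        raise ValidationError("empty mask")
    return float(np.mean(v > T))


def glcm(
    img: np.ndarray,
    mask: np.ndarray,
    L: int = 16,
    d: int = 1,
    theta: int = 0,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence matrix of quantized levels at offset (d, theta).

    Pairs are counted only when *both* pixels lie inside the mask; pairs
    leaving the mask or the image are skipped. Raises if no valid pair
    admits the offset.
    """
    if theta not in _ANGLE_OFFSETS:
        raise ValidationError(f"theta must be one of {GLCM_ANGLES}")
    if d < 1:
        raise ValidationError("distance d must be >= 1")
    mask = np.asarray(mask, bool)
    levels = quantize(np.asarray(img, float), L)
    dr, dc = (_ANGLE_OFFSETS[theta][0] * d, _ANGLE_OFFSETS[theta][1] * d)
    h, w = mask.shape

    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    i = levels[r0:r1, c0:c1][src]
    j = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][src]
    if i.size == 0:
        raise ValidationError("no co-occurring pixel pair admits this offset")
    counts = np.zeros((L, L), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(S=counts / counts.sum(), d=d, theta=theta, L=L, symmetric=symmetric)


def glcm_contrast(g: GLCM) -> float:
    """SLx = sum_ij (i-j)^2 * S(i,j)."""
    idx = np.arange(g.L)
    return float(np.sum((idx[:, None] - idx[None, :]) ** 2 * g.S))


def glcm_homogeneity(g: GLCM) -> float:
    """SPx = sum_ij S(i,j) / (1 + (i-j)^2); always in (0, 1]."""
    idx = np.arange(g.L)
    return float(np.sum(g.S / (1.0 + (idx[:, None] - idx[None, :]) ** 2)))


def _mean_texture(img, mask, L, d, symmetric) -> tuple[float, float]:
    """Contrast and homogeneity averaged over the four standard angles;
    angles with no admissible pair are skipped."""
    contrasts, homogs = [], []
    for theta in GLCM_ANGLES:
        try:
            g = glcm(img, mask, L=L, d=d, theta=theta, symmetric=symmetric)
        except ValidationError:
            continue
        contrasts.append(glcm_contrast(g))
        homogs.append(glcm_homogeneity(g))
    if not contrasts:
        raise ValidationError(f"no admissible co-occurrence pair at distance {d}")
    return float(np.mean(contrasts)), float(np.mean(homogs))


def shape3d_features(
    stack_mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> dict[str, float]:
    """Voxel-based 3D shape block for a binary mask stack.

    volume = voxel count * voxel volume; surface area by counting exposed
    voxel faces; equivalent diameter (6V/pi)^(1/3); sphericity
    pi^(1/3)(6V)^(2/3)/A; compactness A^3/(36 pi V^2); curvature proxy =
    std of boundary-voxel distance to the centroid.
    """
    m = np.asarray(stack_mask, bool)
    if m.ndim != 3:
        raise ValidationError("stack_mask must be 3D")
    n = int(m.sum())
    if n == 0:
        raise ValidationError("empty 3D mask")
    sz, sy, sx = (float(s) for s in spacing)
    volume = n * sz * sy * sx

    face_areas = (sy * sx, sz * sx, sz * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        p = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(p.astype(np.int8), axis=axis))
        area += fa * float(diff.sum())

    eq_diam = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area
    compactness = area**3 / (36.0 * np.pi * volume**2)

    eroded = ndi.binary_erosion(m)
    boundary = m & ~eroded
    coords = np.argwhere(boundary).astype(float) * np.array([sz, sy, sx])
    centroid = np.argwhere(m).astype(float).mean(axis=0) * np.array([sz, sy, sx])
    dists = np.sqrt(((coords - centroid) ** 2).sum(axis=1))
    curvature_proxy = float(dists.std()) if dists.size else 0.0

    return {
        "volume": float(volume),
        "surface_area": float(area),
        "equivalent_diameter": float(eq_diam),
        "sphericity": float(sphericity),
        "compactness": float(compactness),
        "curvature_proxy": curvature_proxy,
    }


@dataclass(frozen=True)
class FeatureConfig:
    """Feature roster configuration; the default yields 17 features."""

    L: int = 16
    distances: tuple[int, ...] = (1, 2)
    symmetric: bool = True
    calcification_T: float = 0.9
    entropy_base: float = 2.0

    def __post_init__(self):
        if self.L < 2:
            raise ValidationError("L must be >= 2")
        if not (0 <= self.calcification_T <= 1):
            raise ValidationError("calcification_T must lie in [0, 1]")
        if any(d < 1 for d in self.distances):
            raise ValidationError("distances must be >= 1")

    def feature_names(self) -> list[str]:
        names = ["mean", "variance", "energy", "entropy", "calcification"]
        names += [
            "area",
            "perimeter",
            "circularity",
            "flatness",
            "elongation",
            "rectangularity",
        ]
        for d in self.distances:
            names += [f"contrast_d{d}", f"homogeneity_d{d}"]
        names += ["gradient_mean", "gradient_std"]
        return names


@dataclass
class FeatureVector:
    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if len(self.names) != self.values.size:
            raise ValidationError("names/values length mismatch")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def extract_features(
    cand: NoduleCandidate,
    img: ImageSlice,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the ordered hybrid feature vector for one candidate."""
    mask = cand.region_mask
    if mask.shape != img.pixels.shape:
        raise ValidationError("candidate mask and image shapes differ")
    intensities = img.pixels[mask]
    hist = gray_histogram(intensities, L=cfg.L)

    values: list[float] = [
        float(intensities.mean()),
        float(intensities.var()),
        energy(hist),
        entropy(hist, base=cfg.entropy_base),
        calcification(intensities, T=cfg.calcification_T),
    ]

    desc = cand.descriptors
    values += [
        float(cand.area),
        desc.perimeter,
        desc.circularity,
        desc.flatness,
        desc.elongation,
        desc.rectangularity,
    ]

    for d in cfg.distances:
        try:
            con, hom = _mean_texture(img.pixels, mask, cfg.L, d, cfg.symmetric)
        except ValidationError:
            # region too small to admit this offset: maximally uniform
            con, hom = 0.0, 1.0
        values += [con, hom]

    mag = skfilters.sobel(img.pixels)
    grad = mag[mask]
    values += [float(grad.mean()), float(grad.std())]

    return FeatureVector(names=cfg.feature_names(), values=np.array(values))


def feature_matrix(
    cands: list[NoduleCandidate],
    img: ImageSlice,
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Stack candidate feature vectors into an (n, 17) matrix."""
    names = cfg.feature_names()
    if not cands:
        return np.empty((0, len(names))), names
    rows = [extract_features(c, img, cfg).values for c in cands]
    return np.vstack(rows), names
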
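"""Candidate extraction from the foreground mask and rule-based pruning.

Connected components become :class:`NoduleCandidate` objects carrying a
small descriptor block (mean/variance of intensity, circularity, flatness,
elongation, rectangularity). :func:`rule_crop` then drops every candidate
that violates any active per-descriptor bound, recording which rule fired —
obvious non-nodules never reach a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .errors import ValidationError
from .preprocessing import ImageSlice

DESCRIPTOR_NAMES = (
    "mean_intensity",
    "intensity_variance",
    "circularity",
    "flatness",
    "elongation",
    "rectangularity",
)

_EPS_AXIS = 1e-6


@dataclass(frozen=True)
class RuleDescriptors:
    mean_intensity: float
    intensity_variance: float
    circularity: float       # 4*pi*A / P^2
    flatness: float          # minor/major axis ratio, in (0, 1]
    elongation: float        # major/minor axis ratio, >= 1
    rectangularity: float    # A / bbox area
    perimeter: float = 0.0   # contour arc length (reused by features)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


@dataclass
class NoduleCandidate:
    region_mask: np.ndarray               # full-image boolean mask
    bbox: tuple[int, int, int, int]       # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    area: int
    descriptors: RuleDescriptors
    slice_id: str = ""
    region_id: int = 0


def mask_perimeter(mask: np.ndarray) -> float:
    """Perimeter of a binary mask by weighted boundary-pixel counting.

    Boundary steps are weighted by their Euclidean length (sqrt(2) on
    diagonals), which keeps raster bias small enough that disk circularity
    stays near 1 across radii.
    """
    return float(skmeasure.perimeter(np.pad(mask, 1), neighborhood=4))


def compute_descriptors(mask: np.ndarray, intensities: np.ndarray) -> RuleDescriptors:
    """Descriptors for a single region ``mask``; ``intensities`` are the
    pixel values under the mask."""
    area = int(mask.sum())
    if area < 1:
        raise ValidationError("empty region")
    perim = mask_perimeter(mask)
    circularity = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0

    rr, cc = np.nonzero(mask)
    # axis ratios from the second central moments (image-moment ellipse);
    # +1/12 is the variance of a unit pixel, keeps 1-px-thin shapes finite
    mu_rr = rr.var() + 1.0 / 12.0
    mu_cc = cc.var() + 1.0 / 12.0
    mu_rc = ((rr - rr.mean()) * (cc - cc.mean())).mean()
    common = np.sqrt(max((mu_rr - mu_cc) ** 2 + 4 * mu_rc**2, 0.0))
    lam1 = (mu_rr + mu_cc + common) / 2.0
    lam2 = max((mu_rr + mu_cc - common) / 2.0, _EPS_AXIS)
    elongation = float(np.sqrt(lam1 / lam2))
    flatness = 1.0 / elongation

    bbox_area = (rr.max() - rr.min() + 1) * (cc.max() - cc.min() + 1)
    return RuleDescriptors(
        mean_intensity=float(intensities.mean()),
        intensity_variance=float(intensities.var()),
        circularity=float(circularity),
        flatness=flatness,
        elongation=elongation,
        rectangularity=float(area / bbox_area),
        perimeter=perim,
    )


def label_candidates(
    mask: np.ndarray, img: ImageSlice, min_area: int = 10
) -> list[NoduleCandidate]:
    """8-connected components of ``mask`` with area >= ``min_area``."""
    mask = np.asarray(mask, bool)
    if mask.shape != img.pixels.shape:
        raise ValidationError("mask and image shapes differ")
    labelled = skmeasure.label(mask, connectivity=2)
    out: list[NoduleCandidate] = []
    rid = 0
    for region in skmeasure.regionprops(labelled):
        if region.area < min_area:
            continue
        region_mask = labelled == region.label
        r0, c0, r1, c1 = region.bbox
        desc = compute_descriptors(region_mask, img.pixels[region_mask])
        out.append(
            NoduleCandidate(
                region_mask=region_mask,
                bbox=(r0, c0, r1, c1),
                centroid=tuple(map(float, region.centroid)),
                area=int(region.area),
                descriptors=desc,
                slice_id=img.source_id,
                region_id=rid,
            )
        )
        rid += 1
    return out


@dataclass(frozen=True)
class RuleThresholds:
    """Optional (lower, upper) bound per descriptor; a candidate is dropped
    iff ANY active bound is violated."""

    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if name not in DESCRIPTOR_NAMES:
                raise ValidationError(f"unknown descriptor {name!r}")
            if lo is not None and hi is not None and lo > hi:
                raise ValidationError(f"{name}: lower bound exceeds upper bound")

    def violations(self, desc: RuleDescriptors) -> list[str]:
        out = []
        for name, (lo, hi) in self.bounds.items():
            v = getattr(desc, name)
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                out.append(name)
        return out


def default_rule_thresholds(
    background_intensity: float = 0.2, noise_sigma: float = 0.05
) -> RuleThresholds:
    """Defaults tuned so compact bright blobs — including spiculated ones,
    whose circularity drops to ~0.2 and elongation can reach ~5 — pass,
    while elongated or dim streaks are pruned; every bound is overridable."""
    return RuleThresholds(
        bounds={
            "circularity": (0.1, None),
            "elongation": (None, 6.0),
            "rectangularity": (0.12, None),
            "mean_intensity": (background_intensity + 2 * noise_sigma, None),
        }
    )


def rule_crop(
    candidates: list[NoduleCandidate], thresholds: RuleThresholds
) -> tuple[list[NoduleCandidate], list[NoduleCandidate], dict[int, list[str]]]:
    """Partition candidates into (kept, dropped, reasons).

    ``reasons`` maps the index of each dropped candidate *in the input
    list* to the list of violated rule names (always non-empty).
    """
    kept: list[NoduleCandidate] = []
    dropped: list[NoduleCandidate] = []
    reasons: dict[int, list[str]] = {}
    for i, cand in enumerate(candidates):
        viol = thresholds.violations(cand.descriptors)
        if viol:
            dropped.append(cand)
            reasons[i] = viol
        else:
            kept.append(cand)
    return kept, dropped, reasons
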
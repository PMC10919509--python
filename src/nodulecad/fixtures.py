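"""Synthetic phantom slices and labelled feature tables.

Everything downstream (denoising, segmentation, candidate pruning, feature
extraction, classification) is exercised on the phantoms produced here, so
the generator guarantees the statistical structure the pipeline assumes:

* nodules are bright, compact blobs — smooth disks (benign-like) or disks
  with radial sinusoidal perturbation (malignant-like, spiculated);
* vessel distractors are elongated streaks with elongation >= 3 and a
  textured interior, so shape rules and GLCM texture can both reject them;
* additive Gaussian noise with configurable sigma;
* all randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import PlacementError, ValidationError
from .preprocessing import ImageSlice

LABELS = ("benign", "malignant", "non-nodule")

_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Intensities are on the normalized [0, 1] gray scale. ``spiculation``
    switches the nodule margin model from smooth disks to radially
    perturbed disks (irregular, malignant-like margins).
    """

    width: int = 128
    height: int = 128
    n_nodules: int = 3
    n_vessels: int = 5
    nodule_radius_range: tuple[float, float] = (5.0, 10.0)
    nodule_intensity: float = 0.8
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    spiculation: bool = False
    seed: int = 0
    vessel_intensity: float | None = None
    vessel_texture: float = 0.25

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise ValidationError("phantom must be at least 32x32 pixels")
        if self.n_nodules < 0 or self.n_vessels < 0:
            raise ValidationError("object counts must be non-negative")
        rmin, rmax = self.nodule_radius_range
        if not (0 < rmin <= rmax):
            raise ValidationError("nodule_radius_range must satisfy 0 < min <= max")
        # spiculated margins may extend up to 1.3 * r0
        if 2 * rmax * 1.3 >= min(self.width, self.height) - 4:
            raise ValidationError("nodule radii do not fit inside the image")
        for name in ("nodule_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @property
    def fg_vessel(self) -> float:
        return (
            self.nodule_intensity
            if self.vessel_intensity is None
            else self.vessel_intensity
        )


@dataclass
class LabelledSlice:
    """A phantom image plus ground-truth region masks and labels."""

    image: ImageSlice
    truth_masks: list[np.ndarray] = field(default_factory=list)
    truth_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.truth_masks) != len(self.truth_labels):
            raise ValidationError("masks and labels must have the same length")
        h, w = self.image.pixels.shape
        for m in self.truth_masks:
            if m.shape != (h, w):
                raise ValidationError("truth mask shape differs from image shape")
            if not m.any():
                raise ValidationError("truth masks must be non-empty")
        for lab in self.truth_labels:
            if lab not in LABELS:
                raise ValidationError(f"unknown label {lab!r}")


def _disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _spiculated_mask(
    h: int, w: int, cy: float, cx: float, r0: float, rng: np.random.Generator
) -> np.ndarray:
    """Disk with radius r(theta) = r0 * (1 + a*sin(k*theta + phi))."""
    a = rng.uniform(0.1, 0.3)
    k = int(rng.integers(5, 10))
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r_theta = r0 * (1.0 + a * np.sin(k * theta + phi))
    return dy**2 + dx**2 <= r_theta**2


def _segment_mask(
    h: int, w: int, p0: np.ndarray, p1: np.ndarray, half_width: float
) -> np.ndarray:
    """Pixels within half_width of the segment p0-p1 (a thick streak)."""
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    d = p1 - p0
    length2 = float(d @ d)
    t = np.clip((pts - p0) @ d / length2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    dist2 = ((pts - proj) ** 2).sum(axis=1)
    return (dist2 <= half_width**2).reshape(h, w)


def generate_phantom(spec: PhantomSpec) -> LabelledSlice:
    """Render a phantom slice from ``spec``; reproducible from ``spec.seed``.

    Raises :class:`PlacementError` if the requested geometry cannot be
    placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    occupied = np.zeros((h, w), dtype=bool)
    masks: list[np.ndarray] = []
    labels: list[str] = []

    def place(make_mask) -> np.ndarray:
        for _ in range(_MAX_PLACEMENT_TRIES):
            m = make_mask()
            if m.any() and not (ndi.binary_dilation(m, iterations=2) & occupied).any():
                occupied[m] = True
                return m
        raise PlacementError(
            "could not place object without overlap after "
            f"{_MAX_PLACEMENT_TRIES} tries"
        )

    for _ in range(spec.n_nodules):
        r0 = rng.uniform(*spec.nodule_radius_range)
        margin = r0 * (1.3 if spec.spiculation else 1.0) + 2

        def make_nodule():
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if spec.spiculation:
                return _spiculated_mask(h, w, cy, cx, r0, rng)
            return _disk_mask(h, w, cy, cx, r0)

        masks.append(place(make_nodule))
        labels.append("malignant" if spec.spiculation else "benign")

    for _ in range(spec.n_vessels):
        width_px = float(rng.integers(2, 4))
        # lengths from stubby (elongation just above 3) to long streaks
        lo = 3.5 * width_px
        hi = max(lo + 1, 0.4 * min(h, w))
        length = rng.uniform(lo, hi)

        def make_vessel():
            ang = rng.uniform(0, np.pi)
            d = np.array([np.sin(ang), np.cos(ang)]) * length / 2
            c = np.array(
                [rng.uniform(4, h - 4), rng.uniform(4, w - 4)]
            )
            p0, p1 = c - d, c + d
            if not (
                2 <= min(p0[0], p1[0])
                and max(p0[0], p1[0]) < h - 2
                and 2 <= min(p0[1], p1[1])
                and max(p0[1], p1[1]) < w - 2
            ):
                return np.zeros((h, w), dtype=bool)
            return _segment_mask(h, w, p0, p1, width_px / 2)

        masks.append(place(make_vessel))
        labels.append("non-nodule")

    # compose: hard foreground deltas, feathered with a 1-px Gaussian edge
    delta = np.zeros((h, w), dtype=float)
    for m, lab in zip(masks, labels):
        value = spec.fg_vessel if lab == "non-nodule" else spec.nodule_intensity
        delta[m] = value - spec.background_intensity
    img = spec.background_intensity + ndi.gaussian_filter(delta, sigma=1.0)

    # vessel interiors carry unblurred texture so GLCM statistics differ
    # from the near-uniform nodules
    if spec.vessel_texture > 0:
        for m, lab in zip(masks, labels):
            if lab == "non-nodule":
                img[m] += spec.vessel_texture * rng.uniform(-1, 1, int(m.sum())) * (
                    spec.fg_vessel - spec.background_intensity
                )

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    image = ImageSlice(pixels=img, source_id=f"phantom-seed{spec.seed}")
    return LabelledSlice(image=image, truth_masks=masks, truth_labels=labels)


def generate_feature_table(
    n_per_class: int | Sequence[int],
    class_params: Sequence[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a Gaussian-mixture feature table with known class structure.

    Parameters
    ----------
    n_per_class
        Samples per class (scalar, or one count per class).
    class_params
        Sequence of ``(mean, covariance)`` per class; covariances must be
        positive semi-definite.

    Returns
    -------
    X : (n, d) float array
    y : (n,) int array of class indices
    """
    if len(class_params) < 1:
        raise ValidationError("at least one class required")
    counts = (
        [int(n_per_class)] * len(class_params)
        if np.isscalar(n_per_class)
        else [int(n) for n in n_per_class]
    )
    if len(counts) != len(class_params):
        raise ValidationError("n_per_class length must match class_params")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c, ((mean, cov), n) in enumerate(zip(class_params, counts)):
        mean = np.asarray(mean, dtype=float)
        cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if cov.shape[0] != cov.shape[1] or cov.shape[0] != mean.size:
            raise ValidationError("mean/covariance dimensions disagree")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2)
        if eig.min() < -1e-8 * max(1.0, abs(eig.max())):
            raise ValidationError("covariance must be positive semi-definite")
        xs.append(rng.multivariate_normal(mean, cov, size=n, method="svd"))
        ys.append(np.full(n, c, dtype=int))
    return np.concatenate(xs), np.concatenate(ys)


def generate_patch_set(
    n_per_class: int,
    seed: int = 0,
    size: int = 48,
    radius_range: tuple[float, float] = (8.0, 12.0),
) -> list[tuple[ImageSlice, np.ndarray, str]]:
    """Sample small single-region patches for the three-class experiments.

    benign      — near-uniform bright smooth disk
    malignant   — near-uniform bright spiculated disk
    non-nodule  — textured patch whose *mask geometry is a smooth disk*,
                  i.e. it matches benign in shape but not in texture

    Returns a list of ``(image, mask, label)`` triples, ``n_per_class`` of
    each label, shuffled deterministically.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[ImageSlice, np.ndarray, str]] = []
    c = size / 2
    for label in LABELS:
        for _ in range(n_per_class):
            r0 = rng.uniform(*radius_range)
            if label == "malignant":
                mask = _spiculated_mask(size, size, c, c, r0, rng)
            else:
                mask = _disk_mask(size, size, c, c, r0)
            img = np.full((size, size), 0.2)
            img[mask] = 0.8
            img = ndi.gaussian_filter(img, sigma=1.0)
            if label == "non-nodule":
                img[mask] += 0.15 * rng.uniform(-1, 1, int(mask.sum()))
            img += rng.normal(0.0, 0.01, img.shape)
            img = np.clip(img, 0.0, 1.0)
            out.append(
                (ImageSlice(pixels=img, source_id=f"patch-{label}"), mask, label)
            )
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def write_phantom(
    labelled: LabelledSlice,
    out_dir: str | Path,
    slice_id: str = "slice0",
    fmt: str = "png",
) -> Path:
    """Write image (16-bit PNG or DICOM), masks (PNG) and a CSV manifest.

    Returns the manifest path.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = labelled.image.pixels
    if fmt == "png":
        iio.imwrite(out / f"{slice_id}.png", (px * 65535).round().astype(np.uint16))
    elif fmt == "dicom":
        _write_dicom(px, out / f"{slice_id}.dcm")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    rows = []
    for i, (mask, label) in enumerate(
        zip(labelled.truth_masks, labelled.truth_labels)
    ):
        iio.imwrite(
            out / f"{slice_id}_mask{i}.png", (mask.astype(np.uint8) * 255)
        )
        rr, cc = np.nonzero(mask)
        bbox = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
        rows.append([slice_id, i, label, *bbox])
    manifest = out / f"{slice_id}_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_id", "region_id", "label", "row0", "col0", "row1", "col1"])
        writer.writerows(rows)
    return manifest


def _write_dicom(pixels: np.ndarray, path: Path) -> None:
    try:
        import pydicom
        from pydicom.dataset import FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ValidationError(
            "DICOM output requires the optional 'pydicom' dependency"
        ) from exc
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = (pixels * 65535).round().astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)
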
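"""Image readers shared by the CLI: PNG/TIFF always, DICOM when the
optional pydicom dependency is installed."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError
from .preprocessing import ImageSlice, normalize


def load_image(path: str | Path) -> ImageSlice:
    """Read a single-frame grayscale image and normalize it to [0, 1].

    The min/max window used for normalization is recorded in source_id
    metadata as ``name[lo:hi]``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse an RGB(A) read of a gray image
            arr = arr[..., :3].mean(axis=2)
    elif suffix == ".dcm":
        try:
            import pydicom
        except ImportError as exc:
            raise ValidationError(
                "reading DICOM requires the optional 'pydicom' dependency "
                "(pip install nodulecad[dicom])"
            ) from exc
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise ValidationError("only single-frame monochrome DICOM is supported")
    else:
        raise ValidationError(f"unsupported image format {suffix!r}")
    lo, hi = float(arr.min()), float(arr.max())
    return normalize(arr, source_id=f"{path.name}[{lo:g}:{hi:g}]")


def save_image(img: ImageSlice | np.ndarray, path: str | Path) -> None:
    """Write a [0,1] image as 16-bit PNG/TIFF."""
    import imageio.v3 as iio

    px = img.pixels if isinstance(img, ImageSlice) else np.asarray(img, float)
    iio.imwrite(Path(path), (np.clip(px, 0, 1) * 65535).round().astype(np.uint16))
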
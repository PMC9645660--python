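"""Image file I/O: grayscale TIFF/PNG reading, labeled-image and overlay writing.

Labeled images are written as 16-bit TIFF (id 0 = background) so label
round-trips are lossless; overlays draw per-id colored contours on the source
image for visual inspection.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.segmentation import find_boundaries

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.int32, np.float32, np.float64)


def _check_dtype(arr: np.ndarray, path) -> np.ndarray:
    if not any(np.issubdtype(arr.dtype, d) for d in _SUPPORTED_DTYPES):
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")
    return arr


def read_image_stack(path) -> list[np.ndarray]:
    """Read a grayscale image file as a list of 2-D frames.

    Multi-page TIFFs yield one frame per page (in page order); PNG and
    single-page TIFF yield a one-element list.  8- and 16-bit integer and
    floating-point images are supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) png → luminance
            arr = arr[..., :3].mean(axis=-1)
    _check_dtype(np.asarray(arr), path)
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return [arr[i] for i in range(arr.shape[0])]
    raise ValueError(f"cannot interpret image of shape {arr.shape} in {path}")


def read_stack_or_dir(path) -> tuple[list[np.ndarray], list[str]]:
    """Frames from a multi-page TIFF, a single image, or a directory of images
    (lexicographic filename order). Returns (frames, frame_names)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG images in {path}")
        frames, names = [], []
        for f in files:
            fr = read_image_stack(f)
            frames.extend(fr)
            names.extend([f.stem] if len(fr) == 1 else
                         [f"{f.stem}_{i:03d}" for i in range(len(fr))])
        return frames, names
    frames = read_image_stack(path)
    if len(frames) == 1:
        return frames, [path.stem]
    return frames, [f"{path.stem}_{i:03d}" for i in range(len(frames))]


def write_labeled(path, labeled: np.ndarray) -> None:
    """Write a labeled instance image as 16-bit TIFF (lossless integer I/O)."""
    labeled = np.asarray(labeled)
    if labeled.min() < 0 or labeled.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels must fit in uint16")
    tifffile.imwrite(Path(path), labeled.astype(np.uint16), photometric="minisblack")


def read_labeled(path) -> list[np.ndarray]:
    return [np.asarray(f).astype(np.int32) for f in read_image_stack(path)]


def write_probability(path, prob: np.ndarray) -> None:
    """Write a probability map as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(prob, dtype=np.float32))


def _id_color(i: int) -> tuple[int, int, int]:
    """Deterministic, well-spread RGB color for a label id (golden-angle hue)."""
    h = (i * 0.61803398875) % 1.0
    x = 1 - abs((h * 6) % 2 - 1)
    r, g, b = [(1, x, 0), (x, 1, 0), (0, 1, x), (0, x, 1), (x, 0, 1), (1, 0, x)][int(h * 6) % 6]
    return int(255 * r), int(255 * g), int(255 * b)


def write_overlay(path, image: np.ndarray, labeled: np.ndarray) -> None:
    """PNG of the grayscale image with per-id colored instance contours."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    base = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    rgb = np.stack([base] * 3, axis=-1)
    labeled = np.asarray(labeled)
    for lab in np.unique(labeled):
        if lab == 0:
            continue
        contour = find_boundaries(labeled == lab, mode="inner")
        rgb[contour] = np.array(_id_color(int(lab))) / 255.0
    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))
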
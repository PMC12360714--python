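"""Reading and writing of phantom images.

Images are single-channel grayscale rasters of photon counts. They are held
in memory as float64 arrays in the original count scale (no rescaling); the
source bit depth is carried alongside so that saturation can be flagged and
exports re-quantized correctly.
"""

from __future__ import annotations

import os
import warnings

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ImageFormatError

__all__ = ["load_image", "save_image", "bit_depth_max"]


def bit_depth_max(bit_depth: int) -> float:
    """Largest representable count at a given unsigned bit depth."""
    return float(2**bit_depth - 1)


def _depth_from_dtype(dtype: np.dtype) -> int | None:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    if dtype == np.uint32:
        return 32
    return None


def load_image(path: str | os.PathLike, bit_depth_hint: int | None = None) -> tuple[np.ndarray, int | None]:
    """Load a grayscale TIFF/PNG as float64 counts.

    Multi-channel images are accepted only when all channels are identical
    (a grayscale image stored as RGB); otherwise :class:`ImageFormatError`
    is raised. Returns ``(image, bit_depth)`` where ``bit_depth`` comes from
    the file dtype, falling back to ``bit_depth_hint``.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # Accept RGB(A) only if it is grayscale in disguise.
        channels = arr.reshape(arr.shape[0], arr.shape[1], -1)
        rgb = channels[..., : min(3, channels.shape[-1])]
        if not np.all(rgb == rgb[..., :1]):
            raise ImageFormatError(
                f"{path}: multi-channel image with differing channels; "
                "reduce to a single channel before analysis"
            )
        arr = rgb[..., 0]
    elif arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a 2D image, got shape {arr.shape}")
    depth = _depth_from_dtype(arr.dtype)
    if depth is None:
        depth = bit_depth_hint
    return arr.astype(np.float64), depth


def save_image(image: np.ndarray, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Quantize float counts to unsigned integers and write TIFF or PNG.

    Values are clipped to the representable range of ``bit_depth``; clipping
    emits a warning because it means the scene saturated the output format.
    """
    path = os.fspath(path)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    vmax = bit_depth_max(bit_depth)
    arr = np.asarray(image, dtype=np.float64)
    n_clipped = int(np.count_nonzero((arr < 0) | (arr > vmax)))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} pixels clipped to the {bit_depth}-bit range on export",
            stacklevel=2,
        )
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    out = np.clip(np.rint(arr), 0, vmax).astype(dtype)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
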
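"""Image and stack I/O.

Grayscale images are normalised to [0, 1] by their container's nominal
maximum (255 for 8-bit, 65535 for 16-bit) rather than per-image min-max, so
intensities stay comparable across a focal stack — the l1-max and
spatial-frequency comparisons rely on that.  Colour inputs are rejected
unless luminance conversion is requested explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .amd_imaging import AmdImage, TemporalStack
from .exceptions import ValidationError

__all__ = [
    "load_image",
    "save_image",
    "load_stack",
    "save_amd",
]

_LUMA = (0.299, 0.587, 0.114)  # ITU-R BT.601


def _normalise(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValidationError(
            "float image data must already be normalised to [0, 1]"
        )
    return np.clip(arr, 0.0, 1.0)


def _to_gray(arr: np.ndarray, luminance: bool) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if not luminance:
            raise ValidationError(
                "colour input rejected; pass luminance=True (or --luminance) "
                "to convert with BT.601 weights"
            )
        rgb = arr[..., :3].astype(float)
        return np.tensordot(rgb, _LUMA, axes=([-1], [0])).astype(arr.dtype if arr.dtype.kind == "f" else float)
    raise ValidationError(f"unsupported image shape {arr.shape}")


def load_image(path: str | Path, luminance: bool = False) -> np.ndarray:
    """Read a PNG/TIFF grayscale image, normalised to [0, 1] by bit depth."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # convert in the native integer range, then normalise
        dtype = arr.dtype
        gray = _to_gray(arr, luminance)
        arr = gray.astype(dtype) if dtype.kind == "u" else gray
    return _normalise(_to_gray(np.asarray(arr), luminance))


def save_image(path: str | Path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] image as 8- or 16-bit PNG/TIFF (by extension)."""
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        data = np.round(image * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(image * 255.0).astype(np.uint8)
    else:
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def load_stack(path: str | Path, frame_rate: float = 42.0) -> TemporalStack:
    """Read a multi-page TIFF as a temporal stack, normalised by bit depth."""
    frames = tifffile.imread(Path(path))
    if frames.ndim == 2:
        frames = frames[None]
    return TemporalStack(frames=_normalise(frames), frame_rate=frame_rate)


def save_amd(path: str | Path, amd: AmdImage) -> None:
    """Write an AMD angiogram as 16-bit image plus a JSON scale sidecar."""
    path = Path(path)
    peak = float(amd.amd.max())
    scale = 1.0 / peak if peak > 0 else 1.0
    save_image(path, amd.amd * scale, bit_depth=16)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"amd_peak": peak, "stored_value_times": scale, "epsilon": amd.epsilon})
    )
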
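"""File I/O: PFM (portable float map) for lossless radiance/normal/gradient
grids, 8/16-bit PNG for display, and the gauge-data CSV layout."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .probes import GaugeSample

__all__ = [
    "read_pfm",
    "write_pfm",
    "write_png",
    "read_gray_image",
    "read_gauge_csv",
    "write_gauge_csv",
]


def write_pfm(path, data: np.ndarray) -> None:
    """Write a little-endian PFM file (grayscale ``Pf`` or 3-channel ``PF``).

    PFM stores rows bottom-to-top; a negative scale marks little-endian.
    """
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        header = b"Pf"
    elif data.ndim == 3 and data.shape[2] == 3:
        header = b"PF"
    else:
        raise InvalidParameterError("PFM supports HxW or HxWx3 arrays")
    h, w = data.shape[:2]
    with open(path, "wb") as fh:
        fh.write(header + b"\n")
        fh.write(f"{w} {h}\n".encode())
        fh.write(b"-1.0\n")
        fh.write(np.flipud(data).astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    """Read a PFM file written by :func:`write_pfm` (or any standard PFM)."""
    with open(path, "rb") as fh:
        header = fh.readline().strip()
        if header not in (b"Pf", b"PF"):
            raise InvalidParameterError(f"not a PFM file: {path}")
        dims = fh.readline().split()
        w, h = int(dims[0]), int(dims[1])
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        count = w * h * (3 if header == b"PF" else 1)
        data = np.frombuffer(fh.read(count * 4), dtype=dtype, count=count)
    shape = (h, w, 3) if header == b"PF" else (h, w)
    return np.flipud(data.reshape(shape)).astype(np.float64)


def write_png(path, values: np.ndarray, bitdepth: int = 16) -> None:
    """Write values in [0, 1] as an 8- or 16-bit grayscale PNG."""
    import imageio.v3 as iio

    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    if bitdepth == 16:
        iio.imwrite(path, (v * 65535.0 + 0.5).astype(np.uint16))
    elif bitdepth == 8:
        iio.imwrite(path, (v * 255.0 + 0.5).astype(np.uint8))
    else:
        raise InvalidParameterError("bitdepth must be 8 or 16")


def read_gray_image(path) -> np.ndarray:
    """Read an image file as grayscale floats in [0, 1] (PFM or PNG etc.)."""
    path = Path(path)
    if path.suffix.lower() == ".pfm":
        img = read_pfm(path)
        if img.ndim == 3:
            img = img.mean(axis=2)
        return np.clip(img, 0.0, None)
    import imageio.v3 as iio

    raw = iio.imread(path)
    img = np.asarray(raw, dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        img /= np.iinfo(raw.dtype).max
    return img


def write_gauge_csv(path, samples) -> None:
    from .probes import samples_to_frame

    samples_to_frame(samples).to_csv(path, index=False)


def read_gauge_csv(path):
    df = pd.read_csv(path)
    return [GaugeSample(str(r.observer_id), str(r.condition_id), int(r.gauge_index),
                        float(r.slant_deg), float(r.tilt_deg), int(r.trial))
            for r in df.itertuples()]
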
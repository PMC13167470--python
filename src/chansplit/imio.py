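"""TIFF image I/O with explicit axis metadata.

Arrays use axis order (C, [Z,] Y, X) throughout the package; the axis string
is stored in the TIFF so round-trips preserve it.
"""

from __future__ import annotations

import numpy as np
import tifffile

SUPPORTED_DTYPES = ("uint8", "uint16", "float32")


def write_image(path, array: np.ndarray, axes: str = None) -> None:
    arr = np.asarray(array)
    if str(arr.dtype) not in SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported dtype {arr.dtype}; use one of {SUPPORTED_DTYPES}"
        )
    if axes is None:
        axes = {2: "YX", 3: "CYX", 4: "CZYX"}.get(arr.ndim)
    if axes is None or len(axes) != arr.ndim:
        raise ValueError(f"axes {axes!r} do not match array ndim {arr.ndim}")
    tifffile.imwrite(path, arr, photometric="minisblack",
                     metadata={"axes": axes})


def read_image(path):
    """Returns (array, axes). Raises cleanly on malformed files."""
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            axes = None
            if tf.shaped_metadata:
                axes = tf.shaped_metadata[0].get("axes")
            if axes is None:
                axes = tf.series[0].axes
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from None
    if str(arr.dtype) not in SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {arr.dtype} in {path}")
    return arr, axes
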
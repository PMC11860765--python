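"""Image and table I/O: multi-page TIFF with axis sidecars, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

FLOAT_FORMAT = "%.6g"  # all CSV floats at 6 significant digits


def save_image(path, array: np.ndarray, axes: str, **metadata) -> None:
    """Write a TIFF plus a small JSON sidecar declaring the axis order.

    ``axes`` is e.g. 'YX', 'ZYX' or 'CZYX'; extra keyword metadata (voxel
    sizes, channel names) lands in the sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array))
    sidecar = {"axes": axes, "shape": list(np.asarray(array).shape), **metadata}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF and its sidecar (empty dict when the sidecar is absent)."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return arr, meta


def save_table(path, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_flat_config(path) -> dict[str, str]:
    """Parse a flat ``key=value`` config file.

    Blank lines and ``#`` comments are ignored; values keep everything after
    the first ``=``. Keys may be namespaced with dots (``exofish.threshold``).
    """
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
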
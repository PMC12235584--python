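"""File adapters: TIFF stacks, THUNDERSTORM-style localization CSV,
spectral-fit and cluster CSVs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .localization import LOC_COLUMNS

__all__ = [
    "read_stack",
    "write_stack",
    "read_thunderstorm_csv",
    "write_thunderstorm_csv",
]

# internal column -> THUNDERSTORM CSV header
_TS_HEADER = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "photons": "intensity [photon]",
    "background": "offset [photon]",
    "uncertainty_nm": "uncertainty_xy [nm]",
}


def read_stack(path) -> np.ndarray:
    """Read a (multi-page) TIFF as a (T, H, W) float array."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr, float)
    return arr[None] if arr.ndim == 2 else arr


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, np.float32))


def write_thunderstorm_csv(locs: pd.DataFrame, path) -> None:
    out = locs[LOC_COLUMNS].rename(columns=_TS_HEADER)
    out.to_csv(path, index=False)


def read_thunderstorm_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    inv = {v: k for k, v in _TS_HEADER.items()}
    df = df.rename(columns=inv)
    missing = [c for c in ("frame", "x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns {missing}")
    return df
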
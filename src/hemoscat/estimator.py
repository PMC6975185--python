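"""Per-pixel estimation of Cth and b maps from multispectral image stacks.

The measurement chain is: raw intensity images Is(lambda) at the four
imaging bands, divided by a white-reference Iw(lambda) to give diffuse
reflectance R = Is/Iw, converted to absorbance A = -log10 R, then pushed
through the fitted linear regression per pixel.  No transport simulation
is involved at estimation time, so the cost is linear in pixel count.

Invalid pixels (zero reference, nonpositive or >1 reflectance) and
out-of-range estimates (negative Cth, b outside [1, 4]) are flagged in
``valid_mask`` but never silently filled or clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tissue_optics import ISOSBESTIC_WAVELENGTHS
from .trainer import RegressionModel

#: Plausible range for the scattering power of skin; estimates outside are
#: flagged (not clipped).
B_PLAUSIBLE = (1.0, 4.0)


@dataclass(frozen=True)
class ReflectanceStack:
    """Co-registered raw images plus white reference at the four bands.

    ``images`` and ``white_reference`` are float arrays of shape
    (4, H, W); a scalar-per-band white reference may be given as shape
    (4,) or (4, 1, 1).
    """

    images: np.ndarray
    white_reference: np.ndarray
    wavelengths: tuple[float, ...] = ISOSBESTIC_WAVELENGTHS
    timestamp: str = ""
    grid_hash: str = ""  # optional: the model this stack was prepared for

    def __post_init__(self) -> None:
        img = np.asarray(self.images)
        if img.ndim != 3 or img.shape[0] != 4:
            raise ValueError("images must have shape (4, H, W)")
        wr = np.asarray(self.white_reference)
        if wr.shape not in ((4,), (4, 1, 1), img.shape):
            raise ValueError(
                "white_reference must be per-band scalar (4,) or match images"
            )
        if tuple(self.wavelengths) != tuple(ISOSBESTIC_WAVELENGTHS):
            raise ValueError(
                f"wavelengths must be {ISOSBESTIC_WAVELENGTHS} in order"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class ParameterMaps:
    """Per-pixel Cth (vol.%) and b maps with a validity mask."""

    cth_map: np.ndarray
    b_map: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.cth_map.shape == self.b_map.shape == self.valid_mask.shape):
            raise ValueError("maps and mask must share one shape")

    def roi_mean(self, roi: np.ndarray) -> tuple[float, float]:
        """Mean (Cth, b) over valid pixels of a boolean ROI mask."""
        sel = roi & self.valid_mask
        if not np.any(sel):
            return float("nan"), float("nan")
        return float(self.cth_map[sel].mean()), float(self.b_map[sel].mean())


@dataclass
class TimeCourse:
    """Relative-change time courses per ROI.

    delta entries follow dX% = (X - X_baseline)/X_baseline * 100; the
    baseline row is exactly 0.
    """

    times: list
    roi_names: list[str]
    mean_cth: np.ndarray  # (n_times, n_rois)
    mean_b: np.ndarray
    delta_cth_pct: np.ndarray
    delta_b_pct: np.ndarray
    baseline_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            for j, roi in enumerate(self.roi_names):
                rows.append(
                    dict(
                        time=t, roi=roi,
                        mean_cth=self.mean_cth[i, j], mean_b=self.mean_b[i, j],
                        delta_cth_pct=self.delta_cth_pct[i, j],
                        delta_b_pct=self.delta_b_pct[i, j],
                    )
                )
        return pd.DataFrame(rows)


def normalize_reflectance(stack: ReflectanceStack) -> tuple[np.ndarray, np.ndarray]:
    """Diffuse reflectance R = Is/Iw per band, with a validity mask.

    Returns (R, valid) where R has shape (4, H, W) and valid (H, W) is
    False wherever any band has Iw = 0, R <= 0 or R > 1.  Invalid entries
    of R are set to NaN rather than propagating infinities.
    """
    imgs = np.asarray(stack.images, dtype=float)
    wr = np.asarray(stack.white_reference, dtype=float)
    if wr.shape == (4,):
        wr = wr[:, None, None]
    wr = np.broadcast_to(wr, imgs.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(wr != 0.0, imgs / wr, np.nan)
    bad = (wr == 0.0) | ~np.isfinite(R) | (R <= 0.0) | (R > 1.0)
    R = np.where(bad, np.nan, R)
    valid = ~np.any(bad, axis=0)
    return R, valid


def absorbance(R: np.ndarray) -> np.ndarray:
    """A = -log10 R.  R must be positive on valid (non-NaN) entries."""
    R = np.asarray(R, dtype=float)
    finite = np.isfinite(R)
    if np.any(finite & (R <= 0.0)):
        raise ValueError("nonpositive reflectance on a valid pixel")
    with np.errstate(invalid="ignore"):
        return -np.log10(R)


def estimate_maps(stack: ReflectanceStack, model: RegressionModel) -> ParameterMaps:
    """Apply the fitted regression per pixel.

    Raises on a wavelength mismatch between model and stack, and on a
    grid-hash mismatch when the stack declares one.
    """
    if tuple(model.wavelengths) != tuple(stack.wavelengths):
        raise ValueError(
            f"model wavelengths {model.wavelengths} != stack {stack.wavelengths}"
        )
    if stack.grid_hash and model.grid_hash and stack.grid_hash != model.grid_hash:
        raise ValueError(
            "stack was prepared for a different model "
            f"(grid_hash {stack.grid_hash} != {model.grid_hash})"
        )
    R, valid = normalize_reflectance(stack)
    A = absorbance(R)  # (4, H, W), NaN where invalid
    A_flat = np.moveaxis(A, 0, -1)  # (H, W, 4)
    b_map, cth_map = model.predict(np.nan_to_num(A_flat, nan=0.0))
    # re-mask pixels whose absorbances were undefined
    valid = valid & np.all(np.isfinite(A_flat), axis=-1)
    b_map = np.where(valid, b_map, np.nan)
    cth_map = np.where(valid, cth_map, np.nan)
    in_range = valid & (cth_map >= 0.0) & (b_map >= B_PLAUSIBLE[0]) & (b_map <= B_PLAUSIBLE[1])
    return ParameterMaps(cth_map=cth_map, b_map=b_map, valid_mask=in_range)


def relative_change(
    series: Sequence[ParameterMaps],
    rois: Mapping[str, np.ndarray],
    times: Sequence | None = None,
    baseline_index: int = 0,
) -> TimeCourse:
    """ROI-mean time courses of dCth% and db% against a baseline frame."""
    n_t = len(series)
    if not (0 <= baseline_index < n_t):
        raise IndexError("baseline_index out of range")
    roi_names = list(rois)
    mean_cth = np.empty((n_t, len(roi_names)))
    mean_b = np.empty_like(mean_cth)
    for i, maps in enumerate(series):
        for j, name in enumerate(roi_names):
            mean_cth[i, j], mean_b[i, j] = maps.roi_mean(np.asarray(rois[name], bool))
    base_c = mean_cth[baseline_index]
    base_b = mean_b[baseline_index]
    if np.any(~np.isfinite(base_c)) or np.any(base_c == 0.0) or np.any(base_b == 0.0):
        raise ValueError("baseline ROI mean undefined or zero; relative change undefined")
    d_cth = (mean_cth - base_c) / base_c * 100.0
    d_b = (mean_b - base_b) / base_b * 100.0
    d_cth[baseline_index] = 0.0
    d_b[baseline_index] = 0.0
    return TimeCourse(
        times=list(times) if times is not None else list(range(n_t)),
        roi_names=roi_names,
        mean_cth=mean_cth, mean_b=mean_b,
        delta_cth_pct=d_cth, delta_b_pct=d_b,
        baseline_index=baseline_index,
    )


# ---------------------------------------------------------------------------
# File I/O: per-band grayscale TIFF with a YAML sidecar

def save_stack(stack: ReflectanceStack, directory: str | Path, name: str = "stack") -> Path:
    """Write per-band TIFFs plus a sidecar YAML naming bands and references."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"wavelengths": list(stack.wavelengths), "timestamp": stack.timestamp,
            "grid_hash": stack.grid_hash, "bands": [], "white": []}
    wr = np.asarray(stack.white_reference, dtype=float)
    if wr.shape == (4,):
        wr = np.broadcast_to(wr[:, None, None], stack.images.shape)
    for i, lam in enumerate(stack.wavelengths):
        band = f"{name}_{int(lam)}nm.tif"
        white = f"{name}_{int(lam)}nm_white.tif"
        tifffile.imwrite(directory / band, stack.images[i].astype(np.float32))
        tifffile.imwrite(directory / white, wr[i].astype(np.float32))
        meta["bands"].append(band)
        meta["white"].append(white)
    sidecar = directory / f"{name}.yaml"
    sidecar.write_text(yaml.safe_dump(meta))
    return sidecar


def load_stack(sidecar: str | Path) -> ReflectanceStack:
    """Read a stack written by :func:`save_stack` (or hand-assembled)."""
    sidecar = Path(sidecar)
    meta = yaml.safe_load(sidecar.read_text())
    directory = sidecar.parent
    imgs = np.stack([tifffile.imread(directory / b).astype(float) for b in meta["bands"]])
    wr = np.stack([tifffile.imread(directory / w).astype(float) for w in meta["white"]])
    return ReflectanceStack(
        images=imgs, white_reference=wr,
        wavelengths=tuple(float(l) for l in meta["wavelengths"]),
        timestamp=meta.get("timestamp", ""), grid_hash=meta.get("grid_hash", ""),
    )


def save_maps(maps: ParameterMaps, directory: str | Path, name: str = "maps") -> None:
    """Cth/b maps as 32-bit float TIFF plus the validity mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{name}_cth.tif", maps.cth_map.astype(np.float32))
    tifffile.imwrite(directory / f"{name}_b.tif", maps.b_map.astype(np.float32))
    tifffile.imwrite(directory / f"{name}_valid.tif", maps.valid_mask.astype(np.uint8))


def load_maps(directory: str | Path, name: str = "maps") -> ParameterMaps:
    directory = Path(directory)
    return ParameterMaps(
        cth_map=tifffile.imread(directory / f"{name}_cth.tif").astype(float),
        b_map=tifffile.imread(directory / f"{name}_b.tif").astype(float),
        valid_mask=tifffile.imread(directory / f"{name}_valid.tif").astype(bool),
    )


def load_roi_mask(path: str | Path) -> np.ndarray:
    """Single-channel image file -> boolean ROI mask (nonzero = inside)."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0
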
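"""Hyperspectral cube data model, I/O and spectral preprocessing.

A Raman hyperspectral image is a map of spectra: a ``(rows, cols, k)``
intensity array with a calibrated wavenumber axis of length ``k`` (Raman
shift, cm^-1).  Orientation convention used throughout the package:
``(row, col, wavenumber)``, row-major, 0-based, pixel ``(0, 0)`` top-left.

Preprocessing follows the fixed order

    cosmic-ray removal -> background subtraction -> baseline correction
    -> normalization

and every step records what it did in a :class:`PreprocessingReport`.
Negative intensities after background/baseline subtraction are retained
(never clamped) so later peak fits stay unbiased.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import tifffile
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)

__all__ = [
    "WavenumberAxis",
    "HyperspectralCube",
    "Spectrum",
    "CellMask",
    "PreprocessingReport",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "remove_cosmic_rays",
    "subtract_background",
    "correct_baseline",
    "normalize",
    "average_spectrum",
]


class FormatError(ValueError):
    """Raised when a file does not match the declared on-disk layout."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Calibrated Raman-shift axis in cm^-1 (strictly increasing)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavenumber axis must be 1-D with length >= 2")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavenumber axis contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Mean channel spacing in cm^-1."""
        return float(np.mean(np.diff(self.values)))

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def window(self, center: float, halfwidth: float) -> slice:
        """Slice of channels within ``center +/- halfwidth`` cm^-1."""
        lo, hi = center - halfwidth, center + halfwidth
        idx = np.nonzero((self.values >= lo) & (self.values <= hi))[0]
        if idx.size == 0:
            raise ValueError(
                f"window {lo:.1f}-{hi:.1f} cm^-1 is outside the axis range"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class HyperspectralCube:
    """``(h, w, k)`` intensity array with wavenumber axis and pixel size."""

    intensities: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D (h, w, k) array")
        if arr.shape[2] != len(self.axis):
            raise FormatError(
                f"spectral dimension {arr.shape[2]} does not match axis "
                f"length {len(self.axis)}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("spatial dimensions must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.intensities = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    def pixel_spectrum(self, row: int, col: int) -> "Spectrum":
        return Spectrum(self.intensities[row, col].astype(np.float64), self.axis)

    def copy_with(self, intensities: np.ndarray) -> "HyperspectralCube":
        return HyperspectralCube(
            intensities, self.axis, self.pixel_size_um, dict(self.metadata)
        )


@dataclass
class Spectrum:
    """A single spectrum on a wavenumber axis."""

    intensities: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 1 or arr.size != len(self.axis):
            raise ValueError("spectrum length does not match axis length")
        if not np.all(np.isfinite(arr)):
            raise ValueError("spectrum contains non-finite values")
        self.intensities = arr


@dataclass
class CellMask:
    """Boolean pixel map delimiting one cell."""

    pixels: np.ndarray
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def bounding_box(self) -> tuple[slice, slice]:
        rows = np.any(self.pixels, axis=1)
        cols = np.any(self.pixels, axis=0)
        r0, r1 = np.nonzero(rows)[0][[0, -1]]
        c0, c1 = np.nonzero(cols)[0][[0, -1]]
        return slice(int(r0), int(r1) + 1), slice(int(c0), int(c1) + 1)


@dataclass
class PreprocessingReport:
    """Audit trail for a preprocessing step."""

    n_spikes_removed: int = 0
    baseline_method: str = ""
    normalization_mode: str = ""
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_spikes_removed < 0:
            raise ValueError("n_spikes_removed must be >= 0")


# ---------------------------------------------------------------------------
# I/O
#
# HDF5 layout: /intensities (h, w, k float32), /wavenumbers (k float64),
# root attribute pixel_size_um.  TIFF alternative: one page per wavenumber
# plane plus a plain-text sidecar (one cm^-1 value per line).
# ---------------------------------------------------------------------------


def write_cube(cube: HyperspectralCube, path: str | Path,
               format: str = "hdf5") -> None:
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "intensities", data=cube.intensities.astype(np.float32)
            )
            f.create_dataset(
                "wavenumbers", data=cube.axis.values.astype(np.float64)
            )
            f.attrs["pixel_size_um"] = cube.pixel_size_um
            for key, val in cube.metadata.items():
                if isinstance(val, (str, int, float)):
                    f.attrs[f"meta_{key}"] = val
    elif format == "tiff_stack":
        planes = np.moveaxis(cube.intensities.astype(np.float32), 2, 0)
        tifffile.imwrite(path, planes)
        sidecar = path.with_suffix(path.suffix + ".wavenumbers.txt")
        np.savetxt(sidecar, cube.axis.values, fmt="%.6f")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cube(path: str | Path, format: str = "hdf5") -> HyperspectralCube:
    """Read a hyperspectral cube from HDF5 or a TIFF stack + axis sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "intensities" not in f or "wavenumbers" not in f:
                raise FormatError(
                    "HDF5 cube must contain /intensities and /wavenumbers"
                )
            arr = f["intensities"][()]
            axis = WavenumberAxis(f["wavenumbers"][()])
            px = float(f.attrs.get("pixel_size_um", 1.0))
            meta = {
                k[5:]: v for k, v in f.attrs.items() if k.startswith("meta_")
            }
        return HyperspectralCube(arr, axis, px, meta)
    if format == "tiff_stack":
        planes = tifffile.imread(path)
        if planes.ndim != 3:
            raise FormatError("TIFF stack must hold one page per wavenumber")
        sidecar = path.with_suffix(path.suffix + ".wavenumbers.txt")
        if not sidecar.exists():
            raise FormatError(f"missing wavenumber sidecar {sidecar}")
        axis_vals = np.loadtxt(sidecar, dtype=np.float64)
        if axis_vals.size != planes.shape[0]:
            raise FormatError(
                f"sidecar has {axis_vals.size} values but stack has "
                f"{planes.shape[0]} pages"
            )
        return HyperspectralCube(
            np.moveaxis(planes, 0, 2), WavenumberAxis(axis_vals)
        )
    raise ValueError(f"unknown format {format!r}")


def write_mask(mask: CellMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel image (nonzero = inside)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path: str | Path, cell_id: str = "cell") -> CellMask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr[..., 0]
    return CellMask(arr > 0, cell_id)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def remove_cosmic_rays(
    cube: HyperspectralCube, z_threshold: float = 8.0, window: int = 7
) -> tuple[HyperspectralCube, PreprocessingReport]:
    """Replace single-channel cosmic-ray spikes by the local spectral median.

    For every pixel spectrum a running median (width ``window``, reflected
    edge padding) is computed along the spectral axis.  Channels whose
    residual from the running median exceeds ``z_threshold`` robust sigma
    (1.4826 x median absolute residual of that spectrum) AND whose residual
    drops below half its magnitude on both neighbouring channels are
    replaced by the running-median value.  Spikes in CCD Raman spectra are
    essentially single-channel and orders of magnitude above the noise, so
    a spectral-axis median detects them without temporal replicates; the
    narrowness condition protects genuine Raman bands, whose apex residual
    can exceed the threshold on coarse spectral grids but is shared with at
    least one neighbour, from being clipped.  Multi-channel spike clusters
    need a second pass with a wider window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if window >= cube.shape[2]:
        raise ValueError("window must be smaller than the spectral dimension")

    data = cube.intensities.astype(np.float64)
    med = ndimage.median_filter(data, size=(1, 1, window), mode="reflect")
    resid = data - med
    mad = np.median(np.abs(resid), axis=2, keepdims=True)
    scale = np.max(np.abs(data), axis=2, keepdims=True)
    sigma = np.maximum(1.4826 * mad, 1e-12 + 1e-9 * scale)
    abs_r = np.abs(resid)
    outlier = abs_r > z_threshold * sigma
    # narrowness: a cosmic spike is single-channel, so its residual
    # collapses on both sides; a band apex keeps at least one tall neighbour
    padded = np.pad(abs_r, ((0, 0), (0, 0), (1, 1)), mode="reflect")
    neigh_max = np.maximum(padded[:, :, :-2], padded[:, :, 2:])
    spikes = outlier & (neigh_max < 0.5 * abs_r)
    cleaned = np.where(spikes, med, data)
    n = int(spikes.sum())
    report = PreprocessingReport(
        n_spikes_removed=n,
        parameters={"z_threshold": z_threshold, "window": window},
    )
    return cube.copy_with(cleaned), report


def subtract_background(
    cube: HyperspectralCube,
    background: Spectrum | np.ndarray,
) -> HyperspectralCube:
    """Subtract a background spectrum, or the mean spectrum of a blank region.

    ``background`` is either a :class:`Spectrum` (subtracted directly) or a
    2-D boolean region mask over blank pixels whose mean spectrum is used.
    Negative results are retained.
    """
    if isinstance(background, Spectrum):
        bg = background.intensities
    else:
        region = np.asarray(background, dtype=bool)
        if region.shape != cube.spatial_shape:
            raise ValueError("region mask shape does not match cube")
        if not region.any():
            raise ValueError("background region is empty")
        bg = cube.intensities[region].mean(axis=0)
    return cube.copy_with(cube.intensities.astype(np.float64) - bg)


def _modpoly_baseline(y: np.ndarray, x: np.ndarray, degree: int,
                      max_iter: int = 40, tol: float = 1e-6) -> np.ndarray:
    """Modified-polynomial baselines for spectra stacked as rows of ``y``.

    Iteratively fits a polynomial and clips the working spectrum to the fit,
    so peaks are progressively excluded and the fit settles on the slowly
    varying background.  Chebyshev basis on [-1, 1] for conditioning.
    """
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.chebyshev.chebvander(xs, degree)  # (k, degree+1)
    pinv = np.linalg.pinv(V)
    w = y.copy()
    base = pinv.dot(w.T).T.dot(V.T)
    for _ in range(max_iter):
        w_new = np.minimum(w, base)
        base_new = pinv.dot(w_new.T).T.dot(V.T)
        change = np.max(np.abs(base_new - base))
        scale = np.max(np.abs(y)) + 1e-300
        w, base = w_new, base_new
        if change < tol * scale:
            break
    return base


def _als_baseline(y: np.ndarray, lam: float, p: float,
                  n_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline for one spectrum (Eilers-Boelens)."""
    k = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(k - 2, k))
    DTD = lam * (D.T @ D)
    w = np.ones(k)
    z = y
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + DTD).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def correct_baseline(
    cube: HyperspectralCube,
    method: str = "modpoly",
    params: Mapping | None = None,
) -> tuple[HyperspectralCube, PreprocessingReport]:
    """Subtract a per-pixel slowly varying baseline (autofluorescence).

    ``modpoly`` (default): modified polynomial fitting, ``degree`` 1-9
    (default 5).  ``als``: asymmetric least squares with ``lam`` (default
    1e5) and ``p`` (default 0.01).  Sharp Raman peaks are preserved; the
    broad background beneath them is removed.
    """
    params = dict(params or {})
    data = cube.intensities.astype(np.float64)
    h, w, k = data.shape
    flat = data.reshape(-1, k)
    x = cube.axis.values
    if method == "modpoly":
        degree = int(params.pop("degree", 5))
        if not 1 <= degree <= 9:
            raise ValueError("modpoly degree must be in 1..9")
        base = _modpoly_baseline(flat, x, degree)
        used = {"degree": degree}
    elif method == "als":
        lam = float(params.pop("lam", 1e5))
        p = float(params.pop("p", 0.01))
        if lam <= 0 or not 0 < p < 1:
            raise ValueError("als requires lam > 0 and 0 < p < 1")
        base = np.vstack([_als_baseline(row, lam, p) for row in flat])
        used = {"lam": lam, "p": p}
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    corrected = (flat - base).reshape(h, w, k)
    report = PreprocessingReport(baseline_method=method, parameters=used)
    return cube.copy_with(corrected), report


def normalize(
    cube: HyperspectralCube,
    mode: str = "l2",
    reference_band: tuple[float, float] | None = None,
) -> tuple[HyperspectralCube, PreprocessingReport]:
    """Scale every pixel spectrum to unit norm.

    Modes: ``area`` (sum of the positive part), ``l2`` (Euclidean norm,
    default), ``peak`` (maximum inside ``reference_band`` cm^-1).  Pixels
    with zero norm (e.g. blank background) are left unscaled and counted in
    the report; a warning is emitted.
    """
    data = cube.intensities.astype(np.float64)
    if mode == "area":
        norms = np.clip(data, 0.0, None).sum(axis=2)
    elif mode == "l2":
        norms = np.sqrt((data ** 2).sum(axis=2))
    elif mode == "peak":
        if reference_band is None:
            raise ValueError("peak mode requires reference_band=(lo, hi)")
        lo, hi = reference_band
        sl = cube.axis.window((lo + hi) / 2.0, (hi - lo) / 2.0)
        norms = data[:, :, sl].max(axis=2)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    zero = norms <= 0
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} pixel spectra have zero {mode}-norm and were left "
            "unscaled",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    scaled = data / safe[:, :, None]
    report = PreprocessingReport(
        normalization_mode=mode,
        parameters={"reference_band": reference_band, "n_zero_norm": n_zero},
    )
    return cube.copy_with(scaled), report


def average_spectrum(cube: HyperspectralCube, mask: CellMask) -> Spectrum:
    """Arithmetic mean spectrum over the masked pixels (the cell region)."""
    if mask.pixels.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube")
    if mask.area == 0:
        raise ValueError("mask is empty")
    mean = cube.intensities[mask.pixels].mean(axis=0)
    return Spectrum(mean.astype(np.float64), cube.axis)


def preprocess(
    cube: HyperspectralCube,
    *,
    spike_z: float = 8.0,
    spike_window: int = 7,
    background: Spectrum | np.ndarray | None = None,
    baseline_method: str = "modpoly",
    baseline_params: Mapping | None = None,
    norm_mode: str = "l2",
    reference_band: tuple[float, float] | None = None,
) -> tuple[HyperspectralCube, list[PreprocessingReport]]:
    """Run the full fixed-order preprocessing chain, returning all reports."""
    reports: list[PreprocessingReport] = []
    cube, rep = remove_cosmic_rays(cube, spike_z, spike_window)
    reports.append(rep)
    if background is not None:
        cube = subtract_background(cube, background)
        reports.append(PreprocessingReport(parameters={"background": "given"}))
    cube, rep = correct_baseline(cube, baseline_method, baseline_params)
    reports.append(rep)
    cube, rep = normalize(cube, norm_mode, reference_band)
    reports.append(rep)
    return cube, reports
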
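"""Image transforms feeding the descriptor families.

Descriptors are computed not only on the raw compound image but on a fixed
set of transforms of it — the spatial-frequency spectrum (2-D FFT
magnitude), a wavelet detail image, a 2-D Chebyshev coefficient image, and
the two compound transforms (wavelet of Fourier, Chebyshev of Fourier).
All transforms are deterministic functions of the raw image.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt

__all__ = ["TRANSFORM_NAMES", "compute_transforms", "chebyshev_coefficients"]

#: Fixed transform order used by the feature manifest.
TRANSFORM_NAMES = (
    "raw",
    "fourier",
    "wavelet",
    "chebyshev",
    "wavelet_of_fourier",
    "chebyshev_of_fourier",
)

_CHEB_ORDER = 20
_MIN_SIZE = 16


def _pad_min(img: np.ndarray, min_size: int = _MIN_SIZE) -> np.ndarray:
    h, w = img.shape
    ph, pw = max(0, min_size - h), max(0, min_size - w)
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    return img


def _fourier(img: np.ndarray) -> np.ndarray:
    """Log-magnitude of the centred 2-D FFT (phase discarded)."""
    return np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(img))))


def _wavelet_detail(img: np.ndarray) -> np.ndarray:
    """2-level symlet-5 decomposition with the approximation zeroed.

    Reconstructing from detail coefficients only gives an image of local
    high-frequency structure; its absolute value is the detail-energy image.
    """
    max_level = pywt.dwtn_max_level(img.shape, "sym5")
    level = max(1, min(2, max_level))
    with warnings.catch_warnings():
        # tiny padded images trigger a benign boundary-effect warning
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(img, "sym5", level=level, mode="symmetric")
    coeffs[0] = np.zeros_like(coeffs[0])
    rec = pywt.waverec2(coeffs, "sym5", mode="symmetric")
    return np.abs(rec[: img.shape[0], : img.shape[1]])


def chebyshev_coefficients(img: np.ndarray, order: int = _CHEB_ORDER) -> np.ndarray:
    """Least-squares 2-D Chebyshev approximation coefficients (signed).

    Returns the ``(order+1, order+1)`` coefficient matrix of the separable
    Chebyshev expansion of the image over [-1, 1]^2.
    """
    h, w = img.shape
    xs = np.linspace(-1.0, 1.0, h)
    ys = np.linspace(-1.0, 1.0, w)
    Tx = np.polynomial.chebyshev.chebvander(xs, order)
    Ty = np.polynomial.chebyshev.chebvander(ys, order)
    return np.linalg.pinv(Tx) @ img @ np.linalg.pinv(Ty).T


def _chebyshev_image(img: np.ndarray) -> np.ndarray:
    """Coefficient-magnitude image of the 2-D Chebyshev approximation."""
    return np.abs(chebyshev_coefficients(img))


def compute_transforms(image: np.ndarray) -> dict[str, np.ndarray]:
    """All descriptor-input images derived from one raw image.

    The raw image is zero-padded to at least 16x16 first.  Raises on
    non-finite input.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    img = _pad_min(img)
    fourier = _fourier(img)
    return {
        "raw": img,
        "fourier": fourier,
        "wavelet": _wavelet_detail(img),
        "chebyshev": _pad_min(_chebyshev_image(img)),
        "wavelet_of_fourier": _wavelet_detail(fourier),
        "chebyshev_of_fourier": _pad_min(_chebyshev_image(fourier)),
    }
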
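"""The eleven image-descriptor families.

Each family function maps a 2-D float image to a fixed-length vector; name
lists are module-level constants so the manifest can be generated and
frozen.  Families follow the generic content-descriptor bank tradition:
textures (Haralick co-occurrence, Tamura, Gabor), pixel-statistics
(multi-scale histograms, comb moments, edge and object statistics) and
polynomial decompositions (Chebyshev, Chebyshev-Fourier, Zernike, Radon).
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform

__all__ = ["FAMILIES", "FAMILY_SIZES", "FAMILY_TRANSFORMS", "family_names"]

_EPS = 1e-12


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _quantize8(img: np.ndarray) -> np.ndarray:
    """8-bit quantization by min-max over the image (constant -> all zero)."""
    return np.round(_minmax(img) * 255.0).astype(np.uint8)


def _hist(values: np.ndarray, bins: int, range_: tuple[float, float] | None = None) -> np.ndarray:
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        return np.zeros(bins)
    if range_ is None:
        lo, hi = float(v.min()), float(v.max())
        if hi - lo <= 0:
            out = np.zeros(bins)
            out[0] = 1.0
            return out
        range_ = (lo, hi)
    h, _ = np.histogram(v, bins=bins, range=range_)
    return h / max(v.size, 1)


# ---------------------------------------------------------------------------
# Chebyshev statistics (32): histogram of 2-D Chebyshev coefficients
# ---------------------------------------------------------------------------


def chebyshev_statistics(img: np.ndarray) -> np.ndarray:
    from .transforms import chebyshev_coefficients

    coeffs = chebyshev_coefficients(img)
    return _hist(coeffs, 32)


# ---------------------------------------------------------------------------
# Chebyshev-Fourier coefficients (32): radial Chebyshev x angular Fourier
# magnitudes on the inscribed disk, histogrammed
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _polar_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx) / radius
    theta = np.arctan2(yy - cy, xx - cx)
    inside = r <= 1.0
    return r[inside], theta[inside], inside


def chebyshev_fourier(img: np.ndarray) -> np.ndarray:
    r, theta, inside = _polar_grid(img.shape)
    vals = img[inside]
    x = 2.0 * r - 1.0
    n_rad, n_ang = 8, 8
    T = np.polynomial.chebyshev.chebvander(x, n_rad - 1)  # (npx, 8)
    mags = np.empty(n_rad * n_ang)
    npx = max(vals.size, 1)
    for m in range(n_ang):
        e = np.exp(-1j * m * theta)
        coeffs = (T * (vals * e)[:, None]).sum(axis=0) / npx
        mags[m * n_rad : (m + 1) * n_rad] = np.abs(coeffs)
    return _hist(mags, 32)


# ---------------------------------------------------------------------------
# Comb first-four moments (48): per-line moment series in 4 directions,
# each moment series summarized as a 3-bin histogram
# ---------------------------------------------------------------------------


def _line_moments(lines: list[np.ndarray]) -> np.ndarray:
    out = np.zeros((len(lines), 4))
    for i, line in enumerate(lines):
        m = line.mean()
        d = line - m
        s = float(np.sqrt((d ** 2).mean()))
        out[i, 0] = m
        out[i, 1] = s
        if s > _EPS and line.size > 2:
            out[i, 2] = float((d ** 3).mean()) / s ** 3
            out[i, 3] = float((d ** 4).mean()) / s ** 4 - 3.0  # excess
    return out


def comb_moments(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    directions = [
        [img[i, :] for i in range(h)],
        [img[:, j] for j in range(w)],
        [np.diagonal(img, offset=o) for o in range(-h + 2, w - 1)],
        [np.diagonal(np.fliplr(img), offset=o) for o in range(-h + 2, w - 1)],
    ]
    feats = []
    for lines in directions:
        lines = [ln for ln in lines if ln.size >= 2]
        moms = _line_moments(lines)
        for m in range(4):
            feats.append(_hist(moms[:, m], 3))
    return np.concatenate(feats)


# ---------------------------------------------------------------------------
# Edge statistics (28)
# ---------------------------------------------------------------------------


def edge_statistics(img: np.ndarray) -> np.ndarray:
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    feats = np.zeros(28)
    thr = mag.mean()
    edge = mag > thr
    feats[0] = edge.mean()
    feats[1] = mag.mean()
    feats[2] = np.median(mag)
    feats[3] = mag.var()
    feats[4:12] = _hist(mag, 8)
    if edge.any():
        direc = np.arctan2(gy[edge], gx[edge])
        feats[12] = direc.mean()
        feats[13] = np.median(direc)
        feats[14] = direc.var()
        dh = _hist(direc, 8, range_=(-np.pi, np.pi))
        feats[15:23] = dh
        feats[23] = dh.max()  # direction homogeneity
        feats[24:28] = np.abs(dh[:4] - dh[4:])  # opposite-bin differences
    return feats


# ---------------------------------------------------------------------------
# Gabor energies (7)
# ---------------------------------------------------------------------------

_GABOR_FREQS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
_GABOR_SIGMA = 2.5  # fixed envelope so the kernel stays compact at low f


def gabor_energies(img: np.ndarray) -> np.ndarray:
    total = float((img ** 2).mean()) + _EPS
    out = np.empty(len(_GABOR_FREQS))
    for i, f in enumerate(_GABOR_FREQS):
        re, im = filters.gabor(
            img, frequency=f, sigma_x=_GABOR_SIGMA, sigma_y=_GABOR_SIGMA
        )
        out[i] = float(
            (re.astype(np.float64) ** 2 + im.astype(np.float64) ** 2).mean()
        ) / total
    return out


# ---------------------------------------------------------------------------
# Haralick co-occurrence textures (28 = 14 statistics x {mean, range})
# ---------------------------------------------------------------------------

_LEVELS = 256


def _haralick_stats(P: np.ndarray) -> np.ndarray:
    """14 co-occurrence statistics of one normalized GLCM.

    The GLCM of a small image is sparse, so statistics are accumulated over
    its nonzero entries only; the joint entropies of the independence model
    collapse analytically (HXY1 = HXY2 = HX + HY since sum_j P_ij = px_i).
    """
    L = P.shape[0]
    ii, jj = np.nonzero(P)
    vals = P[ii, jj]
    px = np.bincount(ii, weights=vals, minlength=L)
    py = np.bincount(jj, weights=vals, minlength=L)
    levels = np.arange(L)
    mu_x = float((levels * px).sum())
    mu_y = float((levels * py).sum())
    sd_x = float(np.sqrt(((levels - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2 * py).sum()))
    p_sum = np.bincount(ii + jj, weights=vals, minlength=2 * L - 1)
    p_diff = np.bincount(np.abs(ii - jj), weights=vals, minlength=L)
    ks = np.arange(2 * L - 1)
    kd = levels

    diff = (ii - jj).astype(np.float64)
    asm = float((vals ** 2).sum())
    contrast = float((diff ** 2 * vals).sum())
    if sd_x > _EPS and sd_y > _EPS:
        corr = float(((ii * jj * vals).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        corr = 0.0
    variance = float(((ii - mu_x) ** 2 * vals).sum())
    idm = float((vals / (1.0 + diff ** 2)).sum())
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nz = p_sum > 0
    sum_ent = float(-(p_sum[nz] * np.log(p_sum[nz])).sum())
    entropy = float(-(vals * np.log(vals)).sum())
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    nz = p_diff > 0
    diff_ent = float(-(p_diff[nz] * np.log(p_diff[nz])).sum())
    hx = float(-(px[px > 0] * np.log(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    hxy1 = hx + hy
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy1 - entropy)))))
    return np.array([
        asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent,
        entropy, diff_var, diff_ent, imc1, imc2, diff_avg,
    ])


def haralick(img: np.ndarray) -> np.ndarray:
    from skimage.feature import graycomatrix

    q = _quantize8(img)
    glcm = graycomatrix(
        q, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=_LEVELS, symmetric=True, normed=True,
    )
    per_angle = np.stack(
        [_haralick_stats(glcm[:, :, 0, a]) for a in range(4)], axis=0
    )
    return np.concatenate([per_angle.mean(axis=0), np.ptp(per_angle, axis=0)])


# ---------------------------------------------------------------------------
# Multi-scale histograms (24 = 3 + 5 + 7 + 9 bins)
# ---------------------------------------------------------------------------


def multiscale_histograms(img: np.ndarray) -> np.ndarray:
    scaled = _minmax(img)
    return np.concatenate(
        [_hist(scaled, b, range_=(0.0, 1.0)) for b in (3, 5, 7, 9)]
    )


# ---------------------------------------------------------------------------
# Object statistics (34) from Otsu-binarized connected components
# ---------------------------------------------------------------------------


def object_statistics(img: np.ndarray) -> np.ndarray:
    feats = np.zeros(34)
    if np.ptp(img) <= 0:
        return feats
    binary = img > filters.threshold_otsu(img)
    labels = measure.label(binary, connectivity=2)
    regions = measure.regionprops(labels)
    feats[0] = len(regions)
    feats[1] = measure.euler_number(binary, connectivity=2)
    if not regions:
        return feats
    h, w = img.shape
    areas = np.array([r.area for r in regions], dtype=np.float64)
    cents = np.array([r.centroid for r in regions])
    feats[2] = cents[:, 0].mean() / h
    feats[3] = cents[:, 1].mean() / w
    feats[4:9] = [areas.min(), areas.max(), areas.mean(), np.median(areas), areas.var()]
    feats[9:19] = _hist(areas, 10)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    dists = np.hypot(*(cents - center).T) / max(np.hypot(h, w) / 2.0, 1.0)
    feats[19:24] = [dists.min(), dists.max(), dists.mean(), np.median(dists), dists.var()]
    feats[24:34] = _hist(dists, 10)
    return feats


# ---------------------------------------------------------------------------
# Radon projection statistics (12 = 4 angles x 3-bin histogram)
# ---------------------------------------------------------------------------


def radon_statistics(img: np.ndarray) -> np.ndarray:
    sino = transform.radon(img, theta=[0.0, 45.0, 90.0, 135.0], circle=False)
    return np.concatenate([_hist(sino[:, a], 3) for a in range(4)])


# ---------------------------------------------------------------------------
# Tamura textures (6): contrast, directionality, coarseness sum + 3-bin hist
# ---------------------------------------------------------------------------


def tamura(img: np.ndarray) -> np.ndarray:
    feats = np.zeros(6)
    sd = img.std()
    if sd > _EPS:
        mu4 = float(((img - img.mean()) ** 4).mean())
        kurt = mu4 / sd ** 4
        feats[0] = sd / (kurt ** 0.25)
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    strong = mag > mag.mean()
    if strong.any():
        ang = np.arctan2(gy[strong], gx[strong]) % np.pi
        h = _hist(ang, 16, range_=(0.0, np.pi))
        feats[1] = float((h ** 2).sum())  # 1/16 uniform .. 1 single direction
    # coarseness: best-of-scale box-difference response per pixel
    best = np.zeros_like(img)
    size = np.ones_like(img)
    for k in range(1, 6):
        step = 2 ** (k - 1)
        A = ndimage.uniform_filter(img, size=2 ** k, mode="nearest")
        Eh = np.abs(np.roll(A, -step, axis=1) - np.roll(A, step, axis=1))
        Ev = np.abs(np.roll(A, -step, axis=0) - np.roll(A, step, axis=0))
        E = np.maximum(Eh, Ev)
        take = E > best
        best = np.where(take, E, best)
        size = np.where(take, float(2 ** k), size)
    feats[2] = size.mean()
    feats[3:6] = _hist(np.log2(size), 3, range_=(1.0, 5.0))
    return feats


# ---------------------------------------------------------------------------
# Zernike moment magnitudes (72): orders n <= 15, m >= 0, n - m even
# ---------------------------------------------------------------------------

ZERNIKE_ORDER = 15
ZERNIKE_NM = [
    (n, m)
    for n in range(ZERNIKE_ORDER + 1)
    for m in range(n % 2, n + 1, 2)
]
assert len(ZERNIKE_NM) == 72


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * factorial(n - s)) / (
            factorial(s)
            * factorial((n + m) // 2 - s)
            * factorial((n - m) // 2 - s)
        )
        out += c * rho ** (n - 2 * s)
    return out


@lru_cache(maxsize=32)
def _zernike_basis(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Zernike basis sampled on the inscribed disk of ``shape``."""
    r, theta, inside = _polar_grid(shape)
    basis = np.empty((len(ZERNIKE_NM), r.size), dtype=np.complex128)
    for idx, (n, m) in enumerate(ZERNIKE_NM):
        basis[idx] = _radial_poly(n, m, r) * np.exp(-1j * m * theta)
    flat_inside = np.nonzero(inside.ravel())[0]
    return basis, flat_inside


def zernike_magnitudes(img: np.ndarray) -> np.ndarray:
    basis, flat_inside = _zernike_basis(img.shape)
    vals = img.ravel()[flat_inside]
    mass = float(np.abs(vals).sum())
    if mass <= _EPS:
        return np.zeros(len(ZERNIKE_NM))
    return np.abs(basis @ vals) / mass


# ---------------------------------------------------------------------------
# Registry: family -> (function, length, transforms it runs on)
# ---------------------------------------------------------------------------

_ALL6 = ("raw", "fourier", "wavelet", "chebyshev",
         "wavelet_of_fourier", "chebyshev_of_fourier")

FAMILIES = {
    "chebyshev_statistics": chebyshev_statistics,
    "chebyshev_fourier": chebyshev_fourier,
    "comb_moments": comb_moments,
    "edge_statistics": edge_statistics,
    "gabor": gabor_energies,
    "haralick": haralick,
    "multiscale_histograms": multiscale_histograms,
    "object_statistics": object_statistics,
    "radon": radon_statistics,
    "tamura": tamura,
    "zernike": zernike_magnitudes,
}

FAMILY_SIZES = {
    "chebyshev_statistics": 32,
    "chebyshev_fourier": 32,
    "comb_moments": 48,
    "edge_statistics": 28,
    "gabor": 7,
    "haralick": 28,
    "multiscale_histograms": 24,
    "object_statistics": 34,
    "radon": 12,
    "tamura": 6,
    "zernike": 72,
}

FAMILY_TRANSFORMS = {
    "chebyshev_statistics": ("raw", "fourier"),
    "chebyshev_fourier": ("raw", "fourier"),
    "comb_moments": _ALL6,
    "edge_statistics": ("raw",),
    "gabor": ("raw",),
    "haralick": _ALL6,
    "multiscale_histograms": _ALL6,
    "object_statistics": ("raw",),
    "radon": ("raw", "fourier", "chebyshev", "chebyshev_of_fourier"),
    "tamura": _ALL6,
    "zernike": ("raw", "fourier"),
}


def family_names(family: str) -> list[str]:
    """Stable per-family feature names (unprefixed)."""
    n = FAMILY_SIZES[family]
    if family == "zernike":
        return [f"zernike_n{nn:02d}_m{mm:02d}" for nn, mm in ZERNIKE_NM]
    if family == "haralick":
        stats_ = [
            "asm", "contrast", "correlation", "variance", "idm", "sum_avg",
            "sum_var", "sum_ent", "entropy", "diff_var", "diff_ent",
            "imc1", "imc2", "diff_avg",
        ]
        return [f"haralick_{s}_mean" for s in stats_] + [
            f"haralick_{s}_range" for s in stats_
        ]
    return [f"{family}_{i:02d}" for i in range(n)]
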
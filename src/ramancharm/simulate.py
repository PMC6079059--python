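"""Synthetic single-cell Raman hyperspectral cubes with known ground truth.

The generator emulates the acquisition the classifiers are built for: three
cell classes, 24 cells each (72 cubes), a 40 um field scanned at 120 lines
(120 x 120 px), 1024-point spectra over 600-3100 cm^-1 with bands at
750 cm^-1 (cytochrome), 1687 cm^-1 (protein) and 2850 cm^-1 (lipid).

Each cell is a smooth random blob; inside it three compound maps are drawn:
cytochrome as class-parameterized granules, protein as a smooth interior,
lipid as sparse droplets.  Per-class granule/droplet counts and sizes are
chosen so the *total* compound mass per unit area is equal across classes —
the classes have near-identical average spectra but distinct spatial
patterns, which is exactly the regime where image descriptors outperform
the average spectrum.  A ``pattern_separation`` dial interpolates the class
spatial parameters toward their common mean (0 = identically distributed
classes, 1 = default separation); per-class ``amp_scale`` adds a spectral
(mean-intensity) difference when one is wanted.

Pixel spectra are the compound maps times unit-amplitude Gaussian band
profiles, plus a smooth polynomial baseline, i.i.d. Gaussian noise, and
Poisson-count cosmic-ray spikes.  Everything is a deterministic function of
the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cube import CellMask, HyperspectralCube, WavenumberAxis, write_cube, write_mask

__all__ = [
    "ClassSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cell",
    "iter_cells",
    "generate_dataset",
    "save_dataset",
]

PEAK_CENTERS = {"cytochrome": 750.0, "protein": 1687.0, "lipid": 2850.0}
PEAK_SIGMAS = {"cytochrome": 10.0, "protein": 14.0, "lipid": 12.0}


@dataclass(frozen=True)
class ClassSpec:
    """Spatial-pattern parameters of one cell class (at 120 px field scale)."""

    name: str
    granule_count: float  # cytochrome granules (Poisson mean)
    granule_size: float  # granule sigma, px
    granule_amp: float
    droplet_count: float  # lipid droplets
    droplet_size: float
    droplet_amp: float
    protein_amp: float = 0.6
    protein_texture_scale: float = 3.0  # correlation length of interior texture, px
    protein_texture_depth: float = 0.15  # relative texture amplitude
    amp_scale: float = 1.0  # overall spectral intensity multiplier


def _default_classes() -> tuple[ClassSpec, ...]:
    # counts x sizes^2 equal across classes: equal granule/droplet mass,
    # different granularity -> similar mean spectra, distinct textures.
    # protein differs per class in interior texture (correlation length and
    # depth) and mildly in amplitude, so average spectra stay similar but
    # the protein channel carries real spatial signal.
    return (
        ClassSpec("lineA", 90.0, 1.9, 1.0, 10.0, 4.9, 0.9,
                  protein_amp=0.54, protein_texture_scale=1.5,
                  protein_texture_depth=0.12),
        ClassSpec("lineB", 7.0, 7.0, 1.0, 45.0, 2.3, 0.9,
                  protein_amp=0.60, protein_texture_scale=4.5,
                  protein_texture_depth=0.30),
        ClassSpec("lineC", 25.0, 3.6, 1.0, 30.0, 2.85, 0.9,
                  protein_amp=0.66, protein_texture_scale=2.6,
                  protein_texture_depth=0.20),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic acquisition."""

    seed: int
    n_classes: int = 3
    cells_per_class: int = 24
    field_px: int = 120
    k: int = 1024
    axis_range: tuple[float, float] = (600.0, 3100.0)
    classes: tuple[ClassSpec, ...] = field(default_factory=_default_classes)
    pattern_separation: float = 1.0
    baseline_coeffs: tuple[float, float, float] = (0.3, 0.2, -0.15)
    noise_sd: float = 0.02
    cosmic_rate: float = 1e-6  # spikes per pixel-channel
    cosmic_amp: tuple[float, float] = (10.0, 50.0)
    pixel_size_um: float = 40.0 / 120.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_classes != len(self.classes):
            raise ValueError("n_classes must match the class list")
        if min(self.cells_per_class, self.field_px, self.k) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.axis_range
        if not (lo < min(PEAK_CENTERS.values()) and hi > max(PEAK_CENTERS.values())):
            raise ValueError("axis range must cover all peaks")

    @property
    def n_cells(self) -> int:
        return self.n_classes * self.cells_per_class

    @property
    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(np.linspace(*self.axis_range, self.k))

    @classmethod
    def default(cls, seed: int) -> "SyntheticConfig":
        return cls(seed=seed)

    @classmethod
    def scaled(
        cls,
        seed: int,
        field_px: int = 64,
        k: int = 320,
        cells_per_class: int = 8,
        **kwargs,
    ) -> "SyntheticConfig":
        """Smaller field/spectra/cohort with spatial densities preserved.

        Granule and droplet counts scale with field area and sizes with
        field length (floored at 3 bumps / 0.9 px), so the per-class
        textures keep their character at reduced computational cost.
        """
        f = field_px / 120.0
        classes = tuple(
            replace(
                c,
                granule_count=max(3.0, c.granule_count * f * f),
                granule_size=max(0.9, c.granule_size * f),
                droplet_count=max(3.0, c.droplet_count * f * f),
                droplet_size=max(0.9, c.droplet_size * f),
                protein_texture_scale=max(0.8, c.protein_texture_scale * f),
            )
            for c in kwargs.pop("classes", _default_classes())
        )
        return cls(
            seed=seed, field_px=field_px, k=k, cells_per_class=cells_per_class,
            classes=classes, pixel_size_um=40.0 / field_px, **kwargs,
        )


@dataclass
class GroundTruth:
    """Everything a test oracle needs about one generated cell."""

    label: str
    mask: CellMask
    compound_maps: dict[str, np.ndarray]
    planted: dict


def _effective_class(config: SyntheticConfig, spec: ClassSpec) -> ClassSpec:
    """Interpolate the class pattern toward the across-class mean.

    ``pattern_separation`` = 0 collapses every class onto the mean pattern
    (identically distributed classes); 1 returns the spec unchanged.
    """
    s = config.pattern_separation
    if s == 1.0:
        return spec
    fields = (
        "granule_count", "granule_size", "granule_amp",
        "droplet_count", "droplet_size", "droplet_amp", "protein_amp",
        "protein_texture_scale", "protein_texture_depth",
    )
    means = {
        f: float(np.mean([getattr(c, f) for c in config.classes]))
        for f in fields
    }
    return replace(
        spec,
        **{f: means[f] + s * (getattr(spec, f) - means[f]) for f in fields},
    )


def _cell_blob(field: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random blob mask (perturbed ellipse) centered in the field."""
    r0 = 0.30 * field * (1.0 + 0.08 * rng.standard_normal())
    amps = 0.06 * rng.standard_normal(4)  # harmonics 2..5
    phases = rng.uniform(0, 2 * np.pi, 4)
    yy, xx = np.mgrid[0:field, 0:field]
    cy = cx = (field - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    radius = np.hypot(yy - cy, xx - cx)
    r_theta = r0 * (
        1.0
        + sum(a * np.cos((j + 2) * theta + p) for j, (a, p) in enumerate(zip(amps, phases)))
    )
    return radius <= r_theta


def _add_bumps(
    out: np.ndarray,
    mask: np.ndarray,
    count_mean: float,
    size: float,
    amp: float,
    rng: np.random.Generator,
) -> list[dict]:
    """Scatter Gaussian bumps at random in-mask positions; returns their params."""
    n = int(rng.poisson(count_mean))
    rows, cols = np.nonzero(mask)
    bumps = []
    if rows.size == 0 or n == 0:
        return bumps
    h, w = out.shape
    for _ in range(n):
        i = rng.integers(rows.size)
        cy, cx = int(rows[i]), int(cols[i])
        s = size * float(np.exp(0.10 * rng.standard_normal()))
        a = amp * float(np.exp(0.08 * rng.standard_normal()))
        r = max(2, int(np.ceil(3.0 * s)))
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] += a * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s ** 2)
        )
        bumps.append({"row": cy, "col": cx, "sigma": s, "amplitude": a})
    return bumps


def _band_profiles(axis: WavenumberAxis) -> np.ndarray:
    nu = axis.values
    return np.stack(
        [
            np.exp(-((nu - PEAK_CENTERS[name]) ** 2) / (2.0 * PEAK_SIGMAS[name] ** 2))
            for name in ("cytochrome", "protein", "lipid")
        ]
    )


def generate_cell(
    config: SyntheticConfig,
    class_id: int,
    rng: np.random.Generator,
) -> tuple[HyperspectralCube, GroundTruth]:
    """One synthetic cell cube plus its ground truth, driven by ``rng``."""
    spec = _effective_class(config, config.classes[class_id])
    field_px = config.field_px
    min_area = max(16, int(0.03 * field_px * field_px))
    for _ in range(10):
        blob = _cell_blob(field_px, rng)
        if blob.sum() >= min_area:
            break
    else:
        raise RuntimeError("cell blob degenerated below minimum area")

    # compound maps (zero outside the cell)
    cyto = np.zeros((field_px, field_px))
    granules = _add_bumps(
        cyto, blob, spec.granule_count, spec.granule_size, spec.granule_amp, rng
    )
    lipid = np.zeros_like(cyto)
    droplets = _add_bumps(
        lipid, blob, spec.droplet_count, spec.droplet_size, spec.droplet_amp, rng
    )
    interior = ndimage.gaussian_filter(blob.astype(float), 2.5)
    raw_tex = ndimage.gaussian_filter(
        rng.standard_normal(blob.shape), spec.protein_texture_scale
    )
    raw_tex /= raw_tex.std() + 1e-12  # unit variance at any correlation length
    texture = 1.0 + spec.protein_texture_depth * raw_tex
    protein = spec.protein_amp * interior * np.clip(texture, 0.0, None)
    maps = {
        "cytochrome": np.where(blob, cyto, 0.0) * spec.amp_scale,
        "protein": np.where(blob, protein, 0.0) * spec.amp_scale,
        "lipid": np.where(blob, lipid, 0.0) * spec.amp_scale,
    }

    profiles = _band_profiles(config.axis)
    stacked = np.stack([maps[n] for n in ("cytochrome", "protein", "lipid")], axis=-1)
    data = np.einsum("ijm,mk->ijk", stacked, profiles)
    t = np.linspace(0.0, 1.0, config.k)
    c0, c1, c2 = config.baseline_coeffs
    data += c0 + c1 * t + c2 * t ** 2
    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)
    n_spikes = int(rng.poisson(config.cosmic_rate * data.size))
    if n_spikes:
        flat = rng.integers(data.size, size=n_spikes)
        amps = rng.uniform(*config.cosmic_amp, size=n_spikes)
        data.reshape(-1)[flat] += amps
    cube = HyperspectralCube(
        np.ascontiguousarray(data, dtype=np.float32),
        config.axis,
        config.pixel_size_um,
        {"class": spec.name},
    )
    truth = GroundTruth(
        label=spec.name,
        mask=CellMask(blob, "truth"),
        compound_maps=maps,
        planted={
            "class_spec": spec.__dict__,
            "granules": granules,
            "droplets": droplets,
            "n_cosmic_spikes": n_spikes,
        },
    )
    return cube, truth


def iter_cells(config: SyntheticConfig):
    """Yield ``(index, cube, truth)`` one cell at a time (bounded memory).

    Child generators are derived deterministically from the master seed and
    the cell index, so any cell can be regenerated in isolation.
    """
    idx = 0
    for class_id in range(config.n_classes):
        for _ in range(config.cells_per_class):
            rng = np.random.default_rng([config.seed, idx])
            yield idx, *generate_cell(config, class_id, rng)
            idx += 1


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[HyperspectralCube], list[CellMask], list[str], list[GroundTruth]]:
    """Materialize the whole cohort (use :func:`iter_cells` for large runs)."""
    cubes, masks, labels, truths = [], [], [], []
    for _, cube, truth in iter_cells(config):
        cubes.append(cube)
        masks.append(truth.mask)
        labels.append(truth.label)
        truths.append(truth)
    return cubes, masks, labels, truths


def save_dataset(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write cubes (HDF5), truth masks (PNG), labels.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, truth_summary = [], []
    for idx, cube, truth in iter_cells(config):
        name = f"cell{idx:03d}"
        write_cube(cube, out / f"{name}.h5")
        write_mask(truth.mask, out / f"{name}_mask.png")
        rows.append(f"{name},{truth.label}")
        truth_summary.append(
            {
                "cell_id": name,
                "label": truth.label,
                "mask_area": truth.mask.area,
                "n_granules": len(truth.planted["granules"]),
                "n_droplets": len(truth.planted["droplets"]),
            }
        )
    (out / "labels.csv").write_text("cell_id,label\n" + "\n".join(rows) + "\n")
    (out / "truth.json").write_text(json.dumps(truth_summary, indent=1))
    return out
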
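"""End-to-end orchestration of the three classification approaches.

Approach ``spectral``: per-cell average spectrum -> standardize -> DA-PC.
Approach ``image``: three compound channels -> 3075 descriptors -> Fisher
top-N -> DA-PC.  Approach ``combined``: independent PC blocks from both
representations fused through joint stepwise selection.  Every run can be
replayed from its manifest (config + seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cube import CellMask, HyperspectralCube, average_spectrum, preprocess
from .dapc import DAPC, DAPCResults, FusedDAPC, holdback_split
from .features import FeatureTable, build_feature_table, default_manifest
from .peaks import DEFAULT_PEAKS, reconstruct_channel, segment_cells
from .simulate import SyntheticConfig, iter_cells

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "build_tables", "run_approach", "process_cell"]

APPROACHES = ("spectral", "image", "combined")


@dataclass
class RunConfig:
    """Single-run configuration driving any of the three approaches."""

    approach: str = "image"
    seed: int = 0
    n_top: int = 100
    alpha: float = 0.001
    holdback: float = 0.25
    preprocess: bool = True
    use_truth_masks: bool = True
    simulate: dict = dataclasses.field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        scaled = params.pop("scaled", False)
        if scaled:
            return SyntheticConfig.scaled(**params)
        return SyntheticConfig(**params)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def process_cell(
    cube: HyperspectralCube,
    mask: CellMask | None = None,
    *,
    run_preprocess: bool = True,
    peaks=DEFAULT_PEAKS,
):
    """Preprocess one cube, resolve its mask, and build its representations.

    Returns ``(average spectrum vector, [3 CompoundImages], mask)``.  With
    no mask, the cell is segmented from the protein/lipid channels by Otsu
    thresholding and the largest component is used.  When a mask is given
    the cube is cropped to the mask bounding box first — preprocessing and
    peak fitting are per-pixel operations, so masked results are unchanged
    and off-cell pixels are never fitted.
    """
    if mask is not None:
        rs, cs = mask.bounding_box()
        cube = cube.copy_with(cube.intensities[rs, cs])
        mask = CellMask(mask.pixels[rs, cs], mask.cell_id)
    if run_preprocess:
        cube, _ = preprocess(cube)
    if mask is None:
        protein = reconstruct_channel(cube, peaks[1])
        lipid = reconstruct_channel(cube, peaks[2])
        masks = segment_cells(protein, lipid)
        if not masks:
            raise ValueError("segmentation found no cell in the field")
        mask = masks[0]
    channels = [reconstruct_channel(cube, p, mask) for p in peaks]
    spectrum = average_spectrum(cube, mask)
    return spectrum.intensities, channels, mask


def build_tables(
    config: SyntheticConfig,
    *,
    use_truth_masks: bool = True,
    run_preprocess: bool = True,
    channels_subset: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, FeatureTable]:
    """Spectral table (cells x k) and image FeatureTable for a cohort.

    Cells are generated, preprocessed and reduced one at a time so memory
    stays bounded at one cube.
    """
    spectra, dataset, ids = [], [], []
    for idx, cube, truth in iter_cells(config):
        mask_in = truth.mask if use_truth_masks else None
        spec, channels, used_mask = process_cell(
            cube, mask_in, run_preprocess=run_preprocess
        )
        spectra.append(spec)
        dataset.append((channels, used_mask, truth.label))
        ids.append(f"cell{idx:03d}")
    axis = config.axis.values
    spectral = pd.DataFrame(
        np.vstack(spectra),
        index=pd.Index(ids, name="cell_id"),
        columns=[f"wn_{v:.1f}" for v in axis],
    )
    image_table = build_feature_table(
        dataset, channels_subset=channels_subset, cell_ids=ids
    )
    return spectral, image_table


def run_approach(config: RunConfig) -> DAPCResults:
    """Run one approach end to end and (optionally) write its artifacts."""
    sim = config.synthetic_config()
    spectral, image_table = build_tables(
        sim,
        use_truth_masks=config.use_truth_masks,
        run_preprocess=config.preprocess,
    )
    labels = image_table.labels
    train_idx, test_idx = holdback_split(
        labels, fraction=config.holdback, seed=config.seed
    )
    if config.approach == "spectral":
        model = DAPC(spectral, labels, alpha=config.alpha)
    elif config.approach == "image":
        model = DAPC(
            image_table.data, labels, n_top=config.n_top, alpha=config.alpha
        )
    else:
        model = FusedDAPC(
            spectral, image_table.data, labels,
            alpha=config.alpha, n_top_image=config.n_top,
        )
    results = model.fit(train_idx=train_idx, test_idx=test_idx)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.predictions.to_csv(out / "predictions.csv")
        rows = []
        for split, m in results.metrics.items():
            rows.append(
                {
                    "split": split,
                    "accuracy": m.accuracy,
                    "r2_entropy": m.r2_entropy,
                    "minus2_loglik": m.minus2_loglik,
                    "n": m.n,
                }
            )
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        if results.ranking is not None:
            frame = results.ranking.to_frame()
            manifest = default_manifest()
            family_of = {e.name: e.family for e in manifest.entries}
            parts = frame.index.str.split(".", n=1)
            frame.insert(0, "channel", [p[0] for p in parts])
            frame.insert(
                1, "family",
                [family_of.get(p[1] if len(p) > 1 else "", "") for p in parts],
            )
            frame.to_csv(out / "ranking.csv", index_label="feature_name")
        default_manifest().to_json(out / "feature_manifest.json")
        (out / "summary.txt").write_text(results.summary() + "\n")
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_hash": config.digest(),
            "seed": config.seed,
            "approach": config.approach,
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("artifacts written to %s", out)
    return results
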
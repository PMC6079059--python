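"""Feature manifest and extraction: 1025 descriptors per compound image.

The manifest is the frozen, ordered contract between images and feature
tables: exactly 1025 named (feature, family, transform) entries per channel,
3 x 1025 = 3075 for the concatenated cytochrome/protein/lipid channels of a
cell.  The composition — which family runs on which transform and how many
values it emits — is versioned here and asserted on import, never silently
truncated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..cube import CellMask
from ..peaks import CompoundImage, crop_to_mask
from .families import FAMILIES, FAMILY_SIZES, FAMILY_TRANSFORMS, family_names
from .transforms import compute_transforms

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureManifest",
    "FeatureVector",
    "FeatureTable",
    "ConsistencyError",
    "build_manifest",
    "default_manifest",
    "extract_features",
    "extract_cell_features",
    "build_feature_table",
    "CHANNEL_ORDER",
]

MANIFEST_VERSION = "1.0"
N_FEATURES_PER_CHANNEL = 1025
CHANNEL_ORDER = ("cytochrome", "protein", "lipid")


class ConsistencyError(RuntimeError):
    """Manifest/implementation mismatch — a broken contract, never ignored."""


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    family: str
    transform: str


@dataclass(frozen=True)
class FeatureManifest:
    entries: tuple[ManifestEntry, ...]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConsistencyError("duplicate feature names in manifest")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {"name": e.name, "family": e.family, "transform": e.transform}
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_manifest() -> FeatureManifest:
    """Generate the frozen 1025-entry manifest (family-major order)."""
    entries: list[ManifestEntry] = []
    for family in FAMILIES:
        base_names = family_names(family)
        for tr in FAMILY_TRANSFORMS[family]:
            for nm in base_names:
                entries.append(ManifestEntry(f"{tr}.{nm}", family, tr))
    manifest = FeatureManifest(tuple(entries))
    if len(manifest) != N_FEATURES_PER_CHANNEL:
        raise ConsistencyError(
            f"manifest holds {len(manifest)} entries, contract is "
            f"{N_FEATURES_PER_CHANNEL}"
        )
    return manifest


_DEFAULT: FeatureManifest | None = None


def default_manifest() -> FeatureManifest:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_manifest()
    return _DEFAULT


@dataclass
class FeatureVector:
    """One channel's 1025 descriptor values, aligned to a manifest."""

    values: np.ndarray
    manifest: FeatureManifest
    channel: str = ""
    cell_id: str = ""
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = len(self.names) if self.names else len(self.manifest)
        if self.values.size != expected:
            raise ConsistencyError(
                f"vector length {self.values.size} != manifest {expected}"
            )


def _image_values(image: CompoundImage | np.ndarray) -> np.ndarray:
    if isinstance(image, CompoundImage):
        return image.values
    return np.asarray(image, dtype=np.float64)


def extract_features(
    image: CompoundImage | np.ndarray,
    mask: CellMask | None = None,
    manifest: FeatureManifest | None = None,
    channel: str = "",
    cell_id: str = "",
) -> FeatureVector:
    """Compute the full 1025-value descriptor vector for one channel image.

    With a mask, the image is first zeroed outside the mask and cropped to
    the mask bounding box (translation invariance).  Non-finite descriptor
    values are replaced by 0 and logged, so downstream standardization never
    fails.
    """
    manifest = manifest or default_manifest()
    img = _image_values(image)
    if mask is not None:
        img = crop_to_mask(img, mask)
    transforms = compute_transforms(img)

    blocks: list[np.ndarray] = []
    for family, func in FAMILIES.items():
        for tr in FAMILY_TRANSFORMS[family]:
            vec = np.asarray(func(transforms[tr]), dtype=np.float64)
            if vec.size != FAMILY_SIZES[family]:
                raise ConsistencyError(
                    f"{family} on {tr} returned {vec.size} values, "
                    f"expected {FAMILY_SIZES[family]}"
                )
            bad = ~np.isfinite(vec)
            if bad.any():
                logger.warning(
                    "%d non-finite %s/%s features replaced by 0",
                    int(bad.sum()), family, tr,
                )
                vec = np.where(bad, 0.0, vec)
            blocks.append(vec)
    values = np.concatenate(blocks)
    if values.size != len(manifest):
        raise ConsistencyError(
            f"extracted {values.size} features, manifest {len(manifest)}"
        )
    return FeatureVector(values, manifest, channel, cell_id)


def extract_cell_features(
    channels: list[CompoundImage],
    mask: CellMask,
    manifest: FeatureManifest | None = None,
    cell_id: str = "",
) -> FeatureVector:
    """Concatenate the three channels' descriptors into one 3075-vector.

    Channels must arrive in the fixed (cytochrome, protein, lipid) order;
    a mislabeled order is a consistency error, not a silent reordering.
    """
    manifest = manifest or default_manifest()
    if len(channels) != len(CHANNEL_ORDER):
        raise ValueError(f"expected {len(CHANNEL_ORDER)} channels")
    for ch, expected in zip(channels, CHANNEL_ORDER):
        if ch.peak.name != expected:
            raise ConsistencyError(
                f"channel order must be {CHANNEL_ORDER}, got "
                f"{tuple(c.peak.name for c in channels)}"
            )
    parts, names = [], []
    for ch in channels:
        fv = extract_features(ch, mask, manifest, ch.peak.name, cell_id)
        parts.append(fv.values)
        names.extend(f"{ch.peak.name}.{n}" for n in manifest.names)
    return FeatureVector(
        np.concatenate(parts), manifest, "+".join(CHANNEL_ORDER), cell_id,
        names=names,
    )


@dataclass
class FeatureTable:
    """Cells x named-features matrix with class labels and provenance."""

    data: pd.DataFrame  # index = cell_id, columns = feature names
    labels: pd.Series  # aligned to data.index
    manifest_version: str = MANIFEST_VERSION
    channels: tuple[str, ...] = CHANNEL_ORDER

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.data):
            raise ValueError("labels length does not match row count")
        if not self.labels.index.equals(self.data.index):
            raise ValueError("labels index does not match table index")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, index_label="cell_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="cell_id")
        labels = df.pop("label")
        return cls(df, labels)


def build_feature_table(
    dataset: list[tuple[list[CompoundImage], CellMask, str]],
    channels_subset: tuple[str, ...] | None = None,
    manifest: FeatureManifest | None = None,
    cell_ids: list[str] | None = None,
) -> FeatureTable:
    """One descriptor row per cell; optionally restricted to a channel subset.

    ``dataset`` entries are ``(channel images, mask, class label)``.  A
    single-channel subset yields a width-1025 table; the full three-channel
    table has width 3075.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    manifest = manifest or default_manifest()
    subset = channels_subset or CHANNEL_ORDER
    unknown = set(subset) - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels {unknown}")
    ids = cell_ids or [f"cell{i:03d}" for i in range(len(dataset))]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell_id in dataset")

    rows, labels = [], []
    names: list[str] | None = None
    for (channels, mask, label), cid in zip(dataset, ids):
        by_name = {ch.peak.name: ch for ch in channels}
        parts, row_names = [], []
        for ch_name in subset:
            if ch_name not in by_name:
                raise ValueError(f"cell {cid} is missing channel {ch_name}")
            fv = extract_features(by_name[ch_name], mask, manifest, ch_name, cid)
            parts.append(fv.values)
            row_names.extend(f"{ch_name}.{n}" for n in manifest.names)
        if names is None:
            names = row_names
        rows.append(np.concatenate(parts))
        labels.append(label)
    data = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="cell_id"),
                        columns=names)
    return FeatureTable(
        data, pd.Series(labels, index=data.index, name="label"),
        manifest.version, tuple(subset),
    )
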
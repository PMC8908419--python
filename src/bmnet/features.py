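"""Atlas-based regional feature extraction and feature-table I/O.

A spatially normalized FDG-PET volume is reduced to one mean tracer
intensity per atlas region (90 regions for an AAL-style atlas, 400 for a
Schaefer-style one).  Per-subject SUVR-style normalization divides each
regional mean by the grand mean over all regions, removing subject-level
global uptake so only the regional pattern remains.

Volumes and atlases are NIfTI files on a shared grid (spatial
normalization and smoothing are upstream concerns); feature tables are
CSV/TSV with header ``subject_id,label,<region_1>,...,<region_R>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "AtlasParcellation",
    "RegionalFeatureVector",
    "LabeledCohort",
    "ExtractionError",
    "EmptyRegionError",
    "TableFormatError",
    "load_volume",
    "load_atlas",
    "extract_regional_means",
    "normalize_global_mean",
    "read_feature_table",
    "write_feature_table",
]


class ExtractionError(ValueError):
    """Volume/atlas incompatibility or invalid voxel data."""


class EmptyRegionError(ExtractionError):
    """An atlas region contains no voxels."""


class TableFormatError(ValueError):
    """A feature table violates the expected layout."""


@dataclass
class VolumeGrid:
    """A 3-D intensity volume with its voxel-to-world affine (mm units)."""

    voxel_array: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxel_array = np.asarray(self.voxel_array, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxel_array.ndim != 3 or min(self.voxel_array.shape) < 1:
            raise ExtractionError(f"volume must be 3-D, got shape {self.voxel_array.shape}")
        if self.affine.shape != (4, 4):
            raise ExtractionError(f"affine must be 4x4, got {self.affine.shape}")


@dataclass
class AtlasParcellation:
    """An integer label map (0 = background) with an ordered region list."""

    label_array: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    region_ids: np.ndarray | None = None
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.label_array = np.asarray(self.label_array)
        if self.label_array.ndim != 3:
            raise ExtractionError(f"atlas must be 3-D, got shape {self.label_array.shape}")
        if not np.issubdtype(self.label_array.dtype, np.integer):
            as_int = self.label_array.astype(np.int64)
            if not np.array_equal(as_int, self.label_array):
                raise ExtractionError("atlas labels must be integers")
            self.label_array = as_int
        if self.label_array.min() < 0:
            raise ExtractionError("atlas labels must be non-negative (0 = background)")
        self.affine = np.asarray(self.affine, dtype=float)
        present = np.unique(self.label_array)
        present = present[present > 0]
        if self.region_ids is None:
            self.region_ids = present
        else:
            self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
            if len(np.unique(self.region_ids)) != len(self.region_ids):
                raise ExtractionError("region_ids must be unique")
            unknown = np.setdiff1d(present, self.region_ids)
            if unknown.size:
                raise ExtractionError(
                    f"atlas voxels carry labels not in region_ids: {unknown.tolist()}")
        if self.region_names is not None and len(self.region_names) != len(self.region_ids):
            raise ExtractionError("region_names length must match region_ids")


@dataclass
class RegionalFeatureVector:
    """One subject's per-region mean intensities, ordered as region_ids."""

    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if self.values.shape != self.region_ids.shape:
            raise ExtractionError("values and region_ids must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ExtractionError("regional feature values must be finite")


@dataclass
class LabeledCohort:
    """Feature table + binary labels; the unit of training and evaluation."""

    subject_ids: list[str]
    features: np.ndarray  # (n_subjects, n_regions)
    labels: np.ndarray  # (n_subjects,) in {0, 1}
    region_names: list[str]
    label_names: tuple[str, str] = ("class0", "class1")
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n, r = self.features.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise TableFormatError("subject_ids/labels length must match feature rows")
        if len(self.region_names) != r:
            raise TableFormatError("region_names length must match feature columns")
        if not np.isin(self.labels, (0, 1)).all():
            raise TableFormatError(f"labels must be 0/1, got {np.unique(self.labels)}")
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise TableFormatError(
                f"non-finite feature for subject {self.subject_ids[bad[0]]!r}, "
                f"column {self.region_names[bad[1]]!r}")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_regions(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))


# ---------------------------------------------------------------------------
# NIfTI loading
# ---------------------------------------------------------------------------


def load_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), img.affine)


def load_atlas(path, region_ids=None, region_names=None) -> AtlasParcellation:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    return AtlasParcellation(np.rint(labels).astype(np.int64), img.affine,
                             region_ids=region_ids, region_names=region_names)


# ---------------------------------------------------------------------------
# Extraction and normalization
# ---------------------------------------------------------------------------


def extract_regional_means(volume: VolumeGrid, atlas: AtlasParcellation
                           ) -> RegionalFeatureVector:
    """Mean volume intensity over each atlas region, in region_ids order.

    The volume and atlas must share grid shape and affine; no resampling
    is performed here.  Background voxels (label 0) are ignored; an empty
    region or a NaN voxel inside a region is an error rather than a
    silent exclusion.
    """
    if volume.voxel_array.shape != atlas.label_array.shape:
        raise ExtractionError(
            f"volume shape {volume.voxel_array.shape} != atlas shape "
            f"{atlas.label_array.shape}")
    if not np.allclose(volume.affine, atlas.affine, atol=1e-6):
        raise ExtractionError("volume and atlas affines differ; resample upstream")

    labels = atlas.label_array.ravel()
    data = volume.voxel_array.ravel()
    values = np.empty(len(atlas.region_ids))
    for k, rid in enumerate(atlas.region_ids):
        mask = labels == rid
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise EmptyRegionError(f"region {int(rid)} has no voxels in the atlas")
        vox = data[mask]
        if not np.all(np.isfinite(vox)):
            raise ExtractionError(f"non-finite voxel intensity inside region {int(rid)}")
        values[k] = vox.mean()
    return RegionalFeatureVector(values, atlas.region_ids)


def normalize_global_mean(features: RegionalFeatureVector) -> RegionalFeatureVector:
    """Divide each regional value by the grand mean over regions (SUVR-style).

    The output grand mean is 1, making the vector invariant to
    subject-level global uptake scaling.  Idempotent.
    """
    grand = float(features.values.mean())
    if abs(grand) < 1e-300:
        raise ExtractionError("grand mean is zero; cannot normalize")
    return RegionalFeatureVector(features.values / grand, features.region_ids)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_META_COLS = ("subject_id", "label")


def write_feature_table(cohort: LabeledCohort, path) -> None:
    """Write ``subject_id,label,<regions...>`` as CSV (or TSV for .tsv paths)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(cohort.features, columns=cohort.region_names)
    df.insert(0, "label", [cohort.label_names[y] for y in cohort.labels])
    df.insert(0, "subject_id", cohort.subject_ids)
    df.to_csv(path, sep=sep, index=False)


def read_feature_table(path, positive_label: str | None = None) -> LabeledCohort:
    """Parse a feature table back into a LabeledCohort.

    Labels may be 0/1 already or arbitrary class names; with exactly two
    distinct names, ``positive_label`` (or lexicographic order as a
    fallback) decides which maps to 1.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    for col in _META_COLS:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r} in {path.name}")
    region_names = [c for c in df.columns if c not in _META_COLS]
    if not region_names:
        raise TableFormatError(f"no region columns found in {path.name}")
    feats = df[region_names]
    if feats.isna().any().any():
        row = int(feats.isna().any(axis=1).idxmax())
        col = feats.columns[feats.isna().any(axis=0)][0]
        raise TableFormatError(
            f"NaN feature value at row {row} (subject "
            f"{df['subject_id'].iloc[row]!r}), column {col!r}")
    try:
        features = feats.to_numpy(dtype=float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric feature cell: {exc}") from exc

    raw = df["label"]
    classes = sorted(raw.astype(str).unique())
    if len(classes) > 2:
        raise TableFormatError(f"labels must take at most two values, got {classes}")
    if set(classes) <= {"0", "1"}:
        # already-encoded labels; a single-class table is fine for scoring
        label_names = ("0", "1")
        labels = raw.astype(int).to_numpy()
        if positive_label == "0":
            label_names = ("1", "0")
            labels = 1 - labels
    else:
        if len(classes) < 2:
            raise TableFormatError(
                f"named labels must take exactly two values, got {classes}")
        if positive_label is None:
            positive_label = classes[1]
        elif positive_label not in classes:
            raise TableFormatError(
                f"positive label {positive_label!r} not among classes {classes}")
        negative = [c for c in classes if c != positive_label][0]
        label_names = (negative, positive_label)
        labels = (raw.astype(str) == positive_label).astype(int).to_numpy()
    return LabeledCohort(subject_ids=df["subject_id"].astype(str).tolist(),
                         features=features, labels=labels,
                         region_names=region_names,
                         label_names=(str(label_names[0]), str(label_names[1])))
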
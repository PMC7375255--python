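"""Core data types and file I/O.

Volumes and parcellations travel as single-file NIfTI-1 images; phenotypes
as a tab-separated table with a header; metrics and analysis summaries as
JSON.  Voxel indices are 0-based everywhere; world coordinates exist only
through the affine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GrayMatterVolume",
    "Parcellation",
    "SubjectRecord",
    "Cohort",
    "EvalMetrics",
    "read_volume",
    "write_volume",
    "read_parcellation",
    "write_parcellation",
    "read_phenotypes",
    "write_phenotypes",
    "read_metrics",
    "write_metrics",
    "load_cohort",
]

DIAGNOSES = ("NC", "MCI", "AD")
MCI_SUBTYPES = ("pMCI", "sMCI")

_NUMERIC_FIELDS = ("age", "sex", "mmse", "csf_abeta", "csf_tau", "pgrs",
                   "months_to_conversion")


class FormatError(ValueError):
    """Raised for inputs that are not in the expected on-disk format."""


@dataclass
class GrayMatterVolume:
    """A 3D gray-matter density map on a fixed grid.

    Values are dimensionless densities, expected in [0, 1]; ``affine`` maps
    0-based voxel indices to world (mm) coordinates.
    """

    values: np.ndarray
    voxel_size_mm: float = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise FormatError(f"volume must be 3D with positive shape; got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("gray-matter density cannot be negative")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class Parcellation:
    """Integer label volume defining atlas regions; 0 is background."""

    labels: np.ndarray
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("parcellation labels must be integers")
        present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
        if not self.region_ids:
            self.region_ids = present
        else:
            missing = set(present) - set(self.region_ids)
            if missing:
                raise ValueError(f"labels {sorted(missing)} not in region_ids")
            empty = [r for r in self.region_ids if r not in present]
            if empty:
                raise ValueError(f"regions {empty} are empty")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


@dataclass
class SubjectRecord:
    """Phenotypes of one subject; missing measures are ``None``."""

    id: str
    diagnosis: str
    site: str = "site0"
    mci_subtype: str | None = None
    age: float | None = None
    sex: int | None = None
    mmse: int | None = None
    csf_abeta: float | None = None
    csf_tau: float | None = None
    pgrs: float | None = None
    apoe4_positive: bool | None = None
    months_to_conversion: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"subject {self.id}: diagnosis {self.diagnosis!r} "
                             f"not in {DIAGNOSES}")
        if self.mci_subtype is not None and self.mci_subtype not in MCI_SUBTYPES:
            raise ValueError(f"subject {self.id}: mci_subtype {self.mci_subtype!r}")
        if self.months_to_conversion is not None and self.mci_subtype != "pMCI":
            raise ValueError(f"subject {self.id}: months_to_conversion is only "
                             "meaningful for pMCI subjects")


class Cohort:
    """Subjects plus their volumes — the unit of training and analysis."""

    def __init__(self, records: list[SubjectRecord],
                 volumes: dict[str, GrayMatterVolume]) -> None:
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        missing = [i for i in ids if i not in volumes]
        if missing:
            raise ValueError(f"no volume for subjects: {missing[:5]}")
        shapes = {volumes[i].shape for i in ids}
        if len(shapes) > 1:
            raise ValueError(f"volumes have inconsistent shapes: {shapes}")
        self.records = list(records)
        self.volumes = volumes

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes[self.records[0].id].shape

    def record(self, subject_id: str) -> SubjectRecord:
        return next(r for r in self.records if r.id == subject_id)

    def subset(self, ids: list[str]) -> "Cohort":
        keep = set(ids)
        return Cohort([r for r in self.records if r.id in keep],
                      {i: self.volumes[i] for i in ids})

    def select(self, predicate) -> "Cohort":
        recs = [r for r in self.records if predicate(r)]
        return Cohort(recs, {r.id: self.volumes[r.id] for r in recs})

    def stack(self, ids: list[str] | None = None) -> np.ndarray:
        """Volumes as a (n, H, W, D) float32 array in record order."""
        ids = ids if ids is not None else self.ids
        return np.stack([self.volumes[i].values for i in ids]).astype(np.float32)

    def labels(self, attr: str = "diagnosis") -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records])

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name) for f in fields(SubjectRecord)})
        return pd.DataFrame(rows)


@dataclass
class EvalMetrics:
    """Binary classification metrics at the argmax operating point."""

    acc: float
    sen: float
    spe: float
    auc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0


# ---------------------------------------------------------------------------
# volumes


def read_volume(path) -> GrayMatterVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path} is not a readable NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D single-frame volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return GrayMatterVolume(values=np.asarray(data, dtype=np.float64),
                            voxel_size_mm=float(zooms[0]),
                            affine=np.asarray(img.affine))


def write_volume(volume: GrayMatterVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    img.header.set_zooms([volume.voxel_size_mm] * 3)
    nib.save(img, str(path))


def read_parcellation(path) -> Parcellation:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: parcellation must be 3D, got shape {data.shape}")
    labels = np.rint(data).astype(np.int32)
    return Parcellation(labels=labels)


def write_parcellation(parcellation: Parcellation, path,
                       voxel_size_mm: float = 2.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(parcellation.labels.astype(np.int16), affine), str(path))


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> list[SubjectRecord]:
    """Read a TSV with header columns named after SubjectRecord fields.

    Empty cells become missing values; unknown columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "site": str})
    if "id" not in df.columns or "diagnosis" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs 'id' and 'diagnosis' columns")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids in {path}: {sorted(set(dupes))}")
    records = []
    known = {f.name for f in fields(SubjectRecord)}
    for i, row in df.iterrows():
        kwargs: dict = {}
        for col in df.columns:
            if col not in known:
                continue
            val = row[col]
            if pd.isna(val) or (isinstance(val, str) and not val.strip()):
                kwargs[col] = None
                continue
            if col in ("mmse", "sex"):
                kwargs[col] = int(val)
            elif col in ("age", "csf_abeta", "csf_tau", "pgrs", "months_to_conversion"):
                kwargs[col] = float(val)
            elif col == "apoe4_positive":
                kwargs[col] = bool(int(val)) if not isinstance(val, str) else val.strip().lower() in ("1", "true", "yes")
            else:
                kwargs[col] = val
        try:
            records.append(SubjectRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    return records


def write_phenotypes(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {}
        for f in fields(SubjectRecord):
            v = getattr(r, f.name)
            if f.name == "apoe4_positive" and v is not None:
                v = int(v)
            row[f.name] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metrics


def write_metrics(metrics: EvalMetrics, path) -> None:
    vals = [metrics.acc, metrics.sen, metrics.spe, metrics.auc]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("metrics must be finite")
    payload = {"acc": metrics.acc, "sen": metrics.sen, "spe": metrics.spe,
               "auc": metrics.auc, "roc": [list(p) for p in metrics.roc],
               "n_pos": metrics.n_pos, "n_neg": metrics.n_neg}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_metrics(path) -> EvalMetrics:
    with open(path) as fh:
        d = json.load(fh)
    return EvalMetrics(acc=d["acc"], sen=d["sen"], spe=d["spe"], auc=d["auc"],
                       roc=[tuple(p) for p in d["roc"]],
                       n_pos=d["n_pos"], n_neg=d["n_neg"])


def load_cohort(volumes_dir, phenotypes_path) -> Cohort:
    """Assemble a cohort from ``<volumes_dir>/<id>.nii.gz`` plus a TSV."""
    volumes_dir = Path(volumes_dir)
    records = read_phenotypes(phenotypes_path)
    volumes = {}
    for r in records:
        for ext in (".nii.gz", ".nii"):
            p = volumes_dir / f"{r.id}{ext}"
            if p.exists():
                volumes[r.id] = read_volume(p)
                break
        else:
            raise FileNotFoundError(f"no volume for subject {r.id} in {volumes_dir}")
    return Cohort(records, volumes)
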
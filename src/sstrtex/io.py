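"""Volume/mask I/O, SUV conversion and cohort-table loading.

Activity volumes are stored as NIfTI with voxel spacing taken from the
header; patient physics (body weight, injected activity) travel in a JSON
sidecar next to the image, never in the image header.  Input activity
concentrations are assumed decay-corrected to injection time by the
scanner, which is the standard convention for quantitative PET exports.

Units: activity concentration kBq/mL, body weight kg (converted to g for
SUV), injected activity MBq (converted to kBq), so that

    SUV = concentration [kBq/mL] * weight [g] / injected activity [kBq]

is the dimensionless (g/mL-convention) body-weight SUV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, CohortSchemaError, SuvConversionError, VolumeError

SITES = ("liver", "lymph_node", "bone", "lung", "other")

#: columns every cohort table must carry (one row per lesion)
MANDATORY_COLUMNS = (
    "patient_id",
    "weight_kg",
    "injected_MBq",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "lesion_id",
    "site",
    "volume_path",
    "mask_path",
)

#: optional clinical covariates
COVARIATE_COLUMNS = ("ki67_pct", "cga_ugl", "cum_dose_GBq")

#: patient-level columns that must be constant within a patient_id
_PATIENT_LEVEL = (
    "weight_kg",
    "injected_MBq",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
) + COVARIATE_COLUMNS


@dataclass
class PetVolume:
    """A 3D activity (or SUV) grid with voxel spacing and patient physics."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_weight_kg: Optional[float] = None
    injected_activity_MBq: Optional[float] = None
    is_suv: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise VolumeError(f"expected a 3D grid, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeError(f"voxel spacing must be 3 positive lengths, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class LesionMask:
    """Binary lesion mask aligned to a :class:`PetVolume` grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    lesion_id: str = "lesion"
    site: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        # a voxel counts as inside iff its stored value is exactly 1
        self.values = arr == 1
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.values.ndim != 3:
            raise VolumeError(f"mask must be 3D, got ndim={self.values.ndim}")
        if not self.values.any():
            raise VolumeError(f"mask {self.lesion_id!r} is empty")
        if self.site not in SITES:
            raise VolumeError(f"unknown site {self.site!r}; expected one of {SITES}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class LesionRef:
    """On-disk reference to one segmented lesion."""

    lesion_id: str
    site: str
    volume_path: str
    mask_path: str


@dataclass
class PatientRecord:
    patient_id: str
    weight_kg: float
    injected_MBq: float
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    lesions: list[LesionRef] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)


def check_aligned(volume: PetVolume, mask: LesionMask) -> None:
    """Raise :class:`AlignmentError` unless mask and volume share grid and spacing."""
    if volume.shape != mask.values.shape:
        raise AlignmentError(
            f"mask {mask.lesion_id!r} shape {mask.values.shape} does not match volume shape {volume.shape}"
        )
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise AlignmentError(
            f"mask {mask.lesion_id!r} spacing {mask.spacing_mm} does not match volume spacing {volume.spacing_mm}"
        )


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".meta.json")
    return path.with_suffix(".meta.json")


def write_volume(volume: PetVolume, path: str | Path) -> None:
    """Write a volume as NIfTI plus a JSON metadata sidecar."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    meta = {
        "patient_weight_kg": volume.patient_weight_kg,
        "injected_activity_MBq": volume.injected_activity_MBq,
        "is_suv": volume.is_suv,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path: str | Path) -> PetVolume:
    """Read a NIfTI volume; pick up physics from the sidecar when present."""
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # noqa: BLE001 - normalize parse failures
        raise VolumeError(f"cannot parse volume {path}: {exc}") from exc
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PetVolume(
        values=values,
        spacing_mm=spacing,
        patient_weight_kg=meta.get("patient_weight_kg"),
        injected_activity_MBq=meta.get("injected_activity_MBq"),
        is_suv=bool(meta.get("is_suv", False)),
    )


def write_mask(mask: LesionMask, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(mask.spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path, lesion_id: str = "lesion", site: str = "other") -> LesionMask:
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such mask file: {path}")
    try:
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # noqa: BLE001
        raise VolumeError(f"cannot parse mask {path}: {exc}") from exc
    return LesionMask(values=values, spacing_mm=spacing, lesion_id=lesion_id, site=site)


# ---------------------------------------------------------------------------
# SUV conversion
# ---------------------------------------------------------------------------

def to_suv(volume: PetVolume) -> PetVolume:
    """Convert an activity-concentration volume to body-weight SUV.

    SUV = concentration (kBq/mL) x body weight (g) / injected activity (kBq).
    The conversion is linear in the voxel values and refuses to run twice.
    """
    if volume.is_suv:
        raise SuvConversionError("volume is already in SUV units; refusing double conversion")
    if volume.patient_weight_kg is None or volume.injected_activity_MBq is None:
        raise SuvConversionError(
            "SUV conversion needs patient weight and injected activity; "
            f"got weight={volume.patient_weight_kg}, injected={volume.injected_activity_MBq}"
        )
    if volume.patient_weight_kg <= 0 or volume.injected_activity_MBq <= 0:
        raise SuvConversionError("weight and injected activity must be positive")
    factor = (volume.patient_weight_kg * 1000.0) / (volume.injected_activity_MBq * 1000.0)
    return replace(volume, values=volume.values * factor, is_suv=True)


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def _as_bool(value, row: int, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip().lower() in ("true", "false"):
        return value.strip().lower() == "true"
    raise CohortSchemaError(f"row {row}: column {col!r} must be boolean (0/1), got {value!r}")


def load_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Load and validate a one-row-per-lesion cohort CSV.

    Patient-level columns must be constant within a ``patient_id``;
    conflicting values under the same id raise a schema error, as do
    negative survival times, non-boolean event flags and duplicated
    (patient_id, lesion_id) pairs.  Diagnostics cite the offending row
    (1-based data rows, header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise CohortSchemaError(f"no such cohort table: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "lesion_id": str, "site": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table {path} is missing mandatory columns: {missing}")

    records: dict[str, PatientRecord] = {}
    seen_lesions: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        pid = str(row["patient_id"])
        for tcol in ("pfs_months", "os_months"):
            t = float(row[tcol])
            if not np.isfinite(t) or t < 0:
                raise CohortSchemaError(f"row {i}: {tcol} must be a nonnegative finite time, got {row[tcol]}")
        pfs_event = _as_bool(row["pfs_event"], i, "pfs_event")
        os_event = _as_bool(row["os_event"], i, "os_event")
        covs = {
            c: float(row[c])
            for c in COVARIATE_COLUMNS
            if c in row and row[c] is not None and np.isfinite(float(row[c]))
        }
        patient_fields = dict(
            weight_kg=float(row["weight_kg"]),
            injected_MBq=float(row["injected_MBq"]),
            pfs_months=float(row["pfs_months"]),
            pfs_event=pfs_event,
            os_months=float(row["os_months"]),
            os_event=os_event,
            covariates=covs,
        )
        if pid in records:
            rec = records[pid]
            existing = dict(
                weight_kg=rec.weight_kg,
                injected_MBq=rec.injected_MBq,
                pfs_months=rec.pfs_months,
                pfs_event=rec.pfs_event,
                os_months=rec.os_months,
                os_event=rec.os_event,
                covariates=rec.covariates,
            )
            if existing != patient_fields:
                raise CohortSchemaError(
                    f"row {i}: patient_id {pid!r} repeats with conflicting patient-level values"
                )
        else:
            records[pid] = PatientRecord(patient_id=pid, **patient_fields)
        lid = row["lesion_id"]
        if lid is not None and not (isinstance(lid, float) and np.isnan(lid)) and str(lid) != "":
            key = (pid, str(lid))
            if key in seen_lesions:
                raise CohortSchemaError(f"row {i}: duplicate lesion {lid!r} for patient {pid!r}")
            seen_lesions.add(key)
            records[pid].lesions.append(
                LesionRef(
                    lesion_id=str(lid),
                    site=str(row["site"]),
                    volume_path=str(row["volume_path"]),
                    mask_path=str(row["mask_path"]),
                )
            )
    return list(records.values())


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Patient-level survival/covariate frame (one row per patient)."""
    rows = []
    for r in records:
        row = dict(
            patient_id=r.patient_id,
            weight_kg=r.weight_kg,
            injected_MBq=r.injected_MBq,
            pfs_months=r.pfs_months,
            pfs_event=r.pfs_event,
            os_months=r.os_months,
            os_event=r.os_event,
            n_lesions=len(r.lesions),
        )
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
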
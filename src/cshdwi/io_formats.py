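"""Standard-format I/O: NIfTI volumes and CSV tables.

Volumes are NIfTI (4-D DWI series, 3-D parameter maps and integer lesion
label masks); tables are comma-separated UTF-8 CSV with a header row and
"." decimals. DWI and mask volumes are assumed co-registered; voxel
coordinates are 0-based array indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

COHORT_LABELS = ("reference", "target")
COHORT_COLUMNS = ["patient_id", "cohort", "lesion_id", "pGG", "pTstage", "age", "psa"]
HF_COLUMNS = [
    "patient_id", "lesion_id", "n_voxels", "n_valid_voxels",
    "hf_dwi", "median_adc", "median_fbv",
]
VOXEL_POOL_COLUMNS = ["patient_id", "lesion_id", "adc_mm2_per_s", "fbv"]


@dataclass
class DWISeries:
    """A multi-b-value DWI acquisition of one patient.

    signal : float array, shape (x, y, z, n_b), non-negative, arbitrary units
    bvalues : strictly increasing b-values in s/mm^2, first entry 0
    voxel_size : voxel edge lengths in mm
    """

    signal: np.ndarray
    bvalues: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError(f"DWI signal must be 4-D, got {self.signal.ndim}-D")
        if self.bvalues.ndim != 1 or self.signal.shape[3] != self.bvalues.size:
            raise FormatError(
                f"signal has {self.signal.shape[3]} frames but "
                f"{self.bvalues.size} b-values were given"
            )
        if self.bvalues.size < 3:
            raise ValidationError("need at least 3 b-values (one of them 0)")
        if np.any(np.diff(self.bvalues) <= 0):
            raise ValidationError("b-values must be strictly increasing (no duplicates)")
        if self.bvalues[0] != 0:
            raise ValidationError("first b-value must be 0 (fBV is undefined otherwise)")
        if np.any(self.signal < 0):
            raise ValidationError("DWI signal must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError("voxel_size must be three positive lengths in mm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class LesionMask:
    """Integer lesion-label volume: 0 = background, k > 0 = lesion id."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError(f"lesion mask must be 3-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded, atol=1e-6):
                raise FormatError("lesion mask must contain integer labels")
            labels = rounded.astype(np.int32)
        if labels.min() < 0:
            raise ValidationError("lesion labels must be non-negative")
        self.labels = labels

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    def voxel_indices(self, lesion_id: int) -> tuple[np.ndarray, ...]:
        return np.nonzero(self.labels == lesion_id)


class CohortTable:
    """Per-lesion clinical metadata for the two cohorts.

    One row per (patient, lesion) with pathological Grade Group (pGG, 1-5),
    pathological T stage (pTstage, 2 or 3), age and PSA. Patient-level
    fields must agree across a patient's lesion rows.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _validate_cohort_df(df)

    def __len__(self) -> int:
        return len(self.df)

    def patients(self, cohort: str | None = None) -> list[str]:
        df = self.df if cohort is None else self.df[self.df["cohort"] == cohort]
        return sorted(df["patient_id"].unique())

    def index_lesions(self) -> pd.DataFrame:
        """One row per patient: the index lesion (highest pGG, ties -> lowest id)."""
        df = self.df.sort_values(
            ["patient_id", "pGG", "lesion_id"], ascending=[True, False, True]
        )
        return df.groupby("patient_id", as_index=False).first()[COHORT_COLUMNS]


def _validate_cohort_df(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table is missing columns {missing}")
    df = df[COHORT_COLUMNS].copy().reset_index(drop=True)
    df["patient_id"] = df["patient_id"].astype(str)
    for col, caster in [("lesion_id", int), ("pGG", int), ("pTstage", int)]:
        try:
            df[col] = df[col].astype(caster)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col} is not integer-valued: {exc}") from exc
    for i, row in df.iterrows():
        if row["cohort"] not in COHORT_LABELS:
            raise ValidationError(f"row {i}: cohort must be one of {COHORT_LABELS}")
        if row["lesion_id"] < 1:
            raise ValidationError(f"row {i}: lesion_id must be a positive integer")
        if not 1 <= row["pGG"] <= 5:
            raise ValidationError(f"row {i}: pGG={row['pGG']} outside 1..5")
        if row["pTstage"] not in (2, 3):
            raise ValidationError(f"row {i}: pTstage={row['pTstage']} not in {{2,3}}")
    dup = df.duplicated(subset=["patient_id", "lesion_id"])
    if dup.any():
        raise ValidationError(
            f"row {int(dup.idxmax())}: duplicate (patient_id, lesion_id)"
        )
    for col in ("cohort", "pTstage", "age", "psa"):
        per_patient = df.groupby("patient_id")[col].nunique()
        bad = per_patient[per_patient > 1]
        if len(bad):
            raise ValidationError(
                f"patient-level column {col!r} differs across lesions of "
                f"patient(s) {list(bad.index)[:3]}"
            )
    return df


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _affine(voxel_size: Sequence[float]) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def read_dwi(series_path: str | Path, bvalue_spec: Sequence[float]) -> DWISeries:
    """Load a 4-D NIfTI DWI series and pair it with its b-value scheme.

    Frames are reordered so b-values are ascending. A frame-count mismatch
    is a format error; duplicate b-values are a validation error.
    """
    img = nib.load(str(series_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{series_path}: expected a 4-D DWI volume, got {data.ndim}-D")
    bvals = np.asarray(bvalue_spec, dtype=float)
    if data.shape[3] != bvals.size:
        raise FormatError(
            f"{series_path}: volume has {data.shape[3]} frames but the b-value "
            f"spec lists {bvals.size}"
        )
    if np.unique(bvals).size != bvals.size:
        raise ValidationError("duplicate b-values in the scheme")
    order = np.argsort(bvals, kind="stable")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWISeries(data[..., order], bvals[order], voxel_size)


def write_dwi(series: DWISeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.signal.astype(np.float32), _affine(series.voxel_size))
    nib.save(img, str(path))


def read_lesion_mask(mask_path: str | Path, dwi: DWISeries) -> LesionMask:
    """Load a 3-D integer label mask and check its geometry against the DWI."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{mask_path}: expected a 3-D mask, got {data.ndim}-D")
    mask = LesionMask(data)
    if mask.labels.shape != dwi.shape:
        raise ValidationError(
            f"{mask_path}: mask shape {mask.labels.shape} does not match "
            f"DWI spatial shape {dwi.shape}"
        )
    return mask


def write_lesion_mask(
    mask: LesionMask, path: str | Path, voxel_size: Sequence[float] = (1, 1, 1)
) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def write_param_map(
    pmap,
    adc_path: str | Path,
    fbv_path: str | Path,
    valid_path: str | Path | None = None,
    voxel_size: Sequence[float] = (1, 1, 1),
) -> None:
    """Write ADC (mm^2/s) and fBV maps as float32 NIfTI, validity as uint8."""
    aff = _affine(voxel_size)
    nib.save(nib.Nifti1Image(pmap.adc.astype(np.float32), aff), str(adc_path))
    nib.save(nib.Nifti1Image(pmap.fbv.astype(np.float32), aff), str(fbv_path))
    if valid_path is not None:
        nib.save(nib.Nifti1Image(pmap.valid.astype(np.uint8), aff), str(valid_path))


def read_param_map(
    adc_path: str | Path,
    fbv_path: str | Path,
    valid_path: str | Path | None = None,
):
    from .ivim import ParamMap  # local import: ivim depends on this module

    adc = np.asarray(nib.load(str(adc_path)).dataobj, dtype=float)
    fbv = np.asarray(nib.load(str(fbv_path)).dataobj, dtype=float)
    if adc.ndim != 3 or fbv.ndim != 3:
        raise FormatError("parameter maps must be 3-D")
    if adc.shape != fbv.shape:
        raise ValidationError(f"ADC shape {adc.shape} != fBV shape {fbv.shape}")
    if valid_path is not None:
        valid = np.asarray(nib.load(str(valid_path)).dataobj) > 0
        if valid.shape != adc.shape:
            raise ValidationError("validity mask shape does not match maps")
    else:
        valid = np.isfinite(adc) & np.isfinite(fbv)
    return ParamMap(adc=adc, fbv=fbv, valid=valid)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: str | Path,
               metadata: Mapping[str, object] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_cohort_table(csv_path: str | Path) -> CohortTable:
    df = pd.read_csv(csv_path, comment="#")
    return CohortTable(df)


def write_cohort_table(table: CohortTable | pd.DataFrame, csv_path: str | Path,
                       metadata: Mapping[str, object] | None = None) -> None:
    df = table.df if isinstance(table, CohortTable) else table
    _write_csv(df[COHORT_COLUMNS], csv_path, metadata)


def write_hf_table(results: Iterable, csv_path: str | Path,
                   metadata: Mapping[str, object] | None = None) -> None:
    """Write per-lesion hypoxia results (list of HypoxiaResult or a DataFrame)."""
    if isinstance(results, pd.DataFrame):
        df = results[HF_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "lesion_id": r.lesion_id,
                    "n_voxels": r.n_voxels,
                    "n_valid_voxels": r.n_valid_voxels,
                    "hf_dwi": r.hf_dwi,
                    "median_adc": r.median_adc,
                    "median_fbv": r.median_fbv,
                }
                for r in results
            ],
            columns=HF_COLUMNS,
        )
    _write_csv(df, csv_path, metadata)


def read_hf_table(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, comment="#")
    missing = [c for c in HF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"HF table is missing columns {missing}")
    return df[HF_COLUMNS]


def write_voxel_pool(pool: pd.DataFrame, csv_path: str | Path,
                     metadata: Mapping[str, object] | None = None) -> None:
    """Write one row per voxel: patient_id, lesion_id, adc_mm2_per_s, fbv."""
    df = pool.rename(columns={"adc": "adc_mm2_per_s"})
    _write_csv(df[VOXEL_POOL_COLUMNS], csv_path, metadata)


def read_voxel_pool(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, comment="#")
    missing = [c for c in VOXEL_POOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"voxel pool is missing columns {missing}")
    return df[VOXEL_POOL_COLUMNS].rename(columns={"adc_mm2_per_s": "adc"})
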
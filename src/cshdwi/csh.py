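"""The Consumption-and-Supply Hypoxia (CSH) model.

A voxel is hypoxic when both its oxygen consumption proxy (low ADC, i.e.
high cellularity) and its supply proxy (low fractional blood volume) are
deficient. On a (fBV, ADC) scatter the hypoxic region is bounded by the
line ADC/ADC0 + fBV/fBV0 = 1, whose axis intercepts ADC0 and fBV0 were
trained against pimonidazole staining in prostatectomy specimens. The
published intercepts, ADC0 = 0.79e-3 mm^2/s and fBV0 = 0.43, are frozen
here as defaults and never refit.

Per voxel the model exports the score s = ADC/ADC0 + fBV/fBV0, a strict
hypoxia flag s < 1 (boundary voxels count as non-hypoxic), and a clipped
linear hypoxia level HL = max(0, 1 - s) used for visualisation only. Per
lesion the biomarker is the hypoxia fraction HF_DWI: the share of valid
voxels classified hypoxic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateLesionError, ValidationError
from .io_formats import LesionMask
from .ivim import ParamMap


@dataclass(frozen=True)
class CSHParams:
    """Intercepts of the hypoxia discrimination line."""

    adc0: float = 0.79e-3  # mm^2/s
    fbv0: float = 0.43  # a.u.

    def __post_init__(self) -> None:
        if self.adc0 <= 0 or self.fbv0 <= 0:
            raise ValidationError("CSH intercepts must be positive")


DEFAULT_CSH_PARAMS = CSHParams()


@dataclass
class HypoxiaResult:
    """Per-lesion hypoxia summary."""

    patient_id: str
    lesion_id: int
    hf_dwi: float
    n_voxels: int
    n_valid_voxels: int
    median_adc: float
    median_fbv: float
    hl_map: np.ndarray | None = field(default=None, repr=False)


def _check_nonneg(adc, fbv) -> tuple[np.ndarray, np.ndarray]:
    adc = np.asarray(adc, dtype=float)
    fbv = np.asarray(fbv, dtype=float)
    if np.any(adc < 0) or np.any(fbv < 0):
        raise ValidationError("ADC and fBV must be non-negative")
    return adc, fbv


def csh_score(adc, fbv, params: CSHParams = DEFAULT_CSH_PARAMS):
    """s = ADC/ADC0 + fBV/fBV0; the hypoxic region is s < 1."""
    adc, fbv = _check_nonneg(adc, fbv)
    return adc / params.adc0 + fbv / params.fbv0


def is_hypoxic(adc, fbv, params: CSHParams = DEFAULT_CSH_PARAMS):
    """Strictly below the discrimination line; s = 1 is non-hypoxic."""
    return csh_score(adc, fbv, params) < 1.0


def hypoxia_level(adc, fbv, params: CSHParams = DEFAULT_CSH_PARAMS):
    """HL = max(0, 1 - s): zero on/above the line, 1 at the origin."""
    return np.maximum(0.0, 1.0 - csh_score(adc, fbv, params))


def lesion_hf(
    param_map: ParamMap,
    mask: LesionMask,
    lesion_id: int,
    params: CSHParams = DEFAULT_CSH_PARAMS,
    patient_id: str = "",
    with_hl_map: bool = False,
) -> HypoxiaResult:
    """Hypoxia fraction of one lesion: hypoxic valid voxels / valid voxels.

    Invalid-fit voxels are excluded from numerator and denominator; a
    lesion with zero valid voxels has no defined HF and raises
    DegenerateLesionError rather than reporting 0.
    """
    if param_map.shape != mask.labels.shape:
        raise ValidationError("parameter map and mask geometries differ")
    in_lesion = mask.labels == lesion_id
    n_voxels = int(in_lesion.sum())
    if n_voxels == 0:
        raise ValidationError(f"lesion {lesion_id} not present in the mask")
    sel = in_lesion & param_map.valid
    n_valid = int(sel.sum())
    if n_valid == 0:
        raise DegenerateLesionError(
            f"lesion {lesion_id}: no valid voxels, HF_DWI undefined"
        )
    adc = param_map.adc[sel]
    fbv = param_map.fbv[sel]
    flags = is_hypoxic(adc, fbv, params)
    hl_map = None
    if with_hl_map:
        hl_map = np.zeros(param_map.shape, dtype=np.float32)
        hl_map[sel] = hypoxia_level(adc, fbv, params)
    return HypoxiaResult(
        patient_id=patient_id,
        lesion_id=int(lesion_id),
        hf_dwi=float(np.mean(flags)),
        n_voxels=n_voxels,
        n_valid_voxels=n_valid,
        median_adc=float(np.median(adc)),
        median_fbv=float(np.median(fbv)),
        hl_map=hl_map,
    )
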
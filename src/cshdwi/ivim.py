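"""Segmented IVIM estimation of ADC and fractional blood volume.

The intravoxel-incoherent-motion signal is bi-exponential,

    S(b) = S0 [ f exp(-b D*) + (1 - f) exp(-b D) ],

with tissue diffusivity D and a fast pseudo-diffusion component D* that is
essentially fully attenuated above a perfusion-suppression threshold
(conventionally b >= 200 s/mm^2). The segmented approach therefore never
estimates D*: an ordinary least-squares line through log S(b) over the
high-b samples gives slope -ADC and, extrapolated to b = 0, an intercept
S_int = S0 (1 - f); the fractional blood volume follows as

    fBV = 1 - S_int / S(0).

With only two or three high-b samples per scheme this closed form is both
the conventional estimator and the numerically stable one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import DWISeries, LesionMask


@dataclass(frozen=True)
class IVIMFitConfig:
    """Segmented-fit settings.

    b_threshold : s/mm^2, inclusive lower bound of the "high-b" segment.
        200 keeps {200, 800} from the 3-point scheme and {300, 800} from
        the 4-point scheme, so either printed scheme yields >= 2 samples.
    min_high_b_points : minimum high-b samples for a valid fit.
    adc_bounds : mm^2/s, physiologic clamp for the fitted ADC.
    fbv_bounds : clamp for fBV; small negative noise excursions are clamped
        rather than rejected so lesion voxel counts are preserved.
    """

    b_threshold: float = 200.0
    min_high_b_points: int = 2
    adc_bounds: tuple[float, float] = (0.0, 4.0e-3)
    fbv_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.b_threshold <= 0:
            raise ValidationError("b_threshold must be positive")
        if self.min_high_b_points < 2:
            raise ValidationError("need at least 2 high-b points for a slope")
        for lo, hi in (self.adc_bounds, self.fbv_bounds):
            if not lo < hi:
                raise ValidationError("bounds must be ordered (lo < hi)")


DEFAULT_FIT_CONFIG = IVIMFitConfig()


@dataclass
class ParamMap:
    """Co-registered voxel grids of ADC (mm^2/s), fBV and fit validity."""

    adc: np.ndarray
    fbv: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.fbv = np.asarray(self.fbv, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not self.adc.shape == self.fbv.shape == self.valid.shape:
            raise ValidationError("adc, fbv and valid grids must share one shape")
        if self.adc.ndim != 3:
            raise ValidationError("parameter maps must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc.shape


def _fit_signals(
    signals: np.ndarray, bvalues: np.ndarray, config: IVIMFitConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised segmented fit of an (n_voxels, n_b) signal block."""
    bvalues = np.asarray(bvalues, dtype=float)
    if not np.any(bvalues == 0):
        raise ValidationError("b-value scheme must include b=0 (fBV undefined)")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != bvalues.size:
        raise ValidationError(
            f"signal length {signals.shape[1]} != number of b-values {bvalues.size}"
        )

    high = bvalues >= config.b_threshold
    n_high = int(high.sum())
    s0 = signals[:, bvalues == 0][:, 0]
    n = signals.shape[0]
    adc = np.zeros(n)
    fbv = np.zeros(n)

    if n_high < config.min_high_b_points:
        return adc, fbv, np.zeros(n, dtype=bool)

    sh = signals[:, high]
    valid = (s0 > 0) & np.all(sh > 0, axis=1)
    if valid.any():
        b = bvalues[high]
        y = np.log(sh[valid])
        bc = b - b.mean()
        # OLS of log-signal on b: slope = -ADC, intercept (b=0) = log S_int
        slope = (y * bc).sum(axis=1) / (bc**2).sum()
        intercept = y.mean(axis=1) - slope * b.mean()
        adc[valid] = np.clip(-slope, *config.adc_bounds)
        fbv[valid] = np.clip(1.0 - np.exp(intercept) / s0[valid], *config.fbv_bounds)
    return adc, fbv, valid


def fit_voxel_segmented(
    signal, bvalues, config: IVIMFitConfig = DEFAULT_FIT_CONFIG
) -> tuple[float, float, bool]:
    """Fit a single voxel; returns (adc in mm^2/s, fbv, valid flag).

    The fit is invalid (adc = fbv = 0, valid = False) when S(0) <= 0, any
    high-b sample is <= 0, or fewer than ``min_high_b_points`` samples lie
    at or above the threshold.
    """
    adc, fbv, valid = _fit_signals(np.asarray(signal, dtype=float)[None, :],
                                   bvalues, config)
    return float(adc[0]), float(fbv[0]), bool(valid[0])


def fit_map(
    dwi: DWISeries,
    mask: LesionMask | None = None,
    config: IVIMFitConfig = DEFAULT_FIT_CONFIG,
    whole_volume: bool = False,
) -> ParamMap:
    """Fit every labelled voxel (or the whole volume) of a DWI series.

    Voxels outside the mask are marked invalid and excluded from every
    downstream median and hypoxia-fraction computation.
    """
    shape = dwi.shape
    if whole_volume:
        sel = np.ones(shape, dtype=bool)
    else:
        if mask is None or not mask.lesion_ids:
            raise ValidationError("empty mask: pass a labelled mask or whole_volume=True")
        if mask.labels.shape != shape:
            raise ValidationError("mask geometry does not match the DWI series")
        sel = mask.labels > 0

    adc = np.zeros(shape)
    fbv = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    signals = dwi.signal[sel]
    a, f, v = _fit_signals(signals, dwi.bvalues, config)
    adc[sel] = a
    fbv[sel] = f
    valid[sel] = v
    return ParamMap(adc=adc, fbv=fbv, valid=valid)
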
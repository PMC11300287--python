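"""Cross-cohort transfer of the CSH model.

Two steps make a quantitative DWI biomarker portable between centers with
different acquisition protocols:

1. *Clinical matching.* Target-cohort patients are 1:1 matched to the
   reference cohort by propensity scores (logistic regression of cohort
   membership on indicator-coded pGG and pTstage), with *optimal* matching
   on the logit scale solved as a rectangular assignment problem. Only
   target patients may be dropped; every reference patient is kept (the
   "average treatment effect on the control" estimand). Balance is
   diagnosed with standardized mean differences before and after matching.

2. *Median scaling.* With clinically comparable cohorts, residual
   differences in the pooled voxel distributions are attributed to the
   scanner/protocol, and the target voxels are rescaled multiplicatively:
   F_ADC = median ADC(reference) / median ADC(target), likewise F_fBV.
   The reference cohort is never altered.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import CalibrationError, InfeasibleMatchError, ValidationError
from .ivim import ParamMap

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("pGG", "pTstage")
_PROB_CLIP = 1e-6


@dataclass
class MatchResult:
    """Outcome of propensity matching."""

    pairs: list[tuple[str, str]]  # (reference_patient_id, target_patient_id)
    propensity: pd.Series  # per patient_id, P(cohort == target | covariates)
    logit: pd.Series
    smd_before: pd.Series  # per indicator-coded covariate column
    smd_after: pd.Series

    @property
    def matched_target_ids(self) -> list[str]:
        return [t for _, t in self.pairs]


@dataclass(frozen=True)
class ScalingFactors:
    """Multiplicative cross-cohort harmonisation factors."""

    f_adc: float
    f_fbv: float

    def __post_init__(self) -> None:
        if self.f_adc <= 0 or self.f_fbv <= 0:
            raise ValidationError("scaling factors must be positive")


def _indicator_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Full (non-dropped) indicator coding of categorical covariates."""
    cols = {}
    for cov in covariates:
        for level in sorted(df[cov].unique()):
            cols[f"{cov}={level}"] = (df[cov] == level).astype(float)
    return pd.DataFrame(cols, index=df.index)


def fit_propensity(
    patient_df: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Per-patient propensity of target-cohort membership.

    ``patient_df`` holds one row per patient with a ``cohort`` column and
    the covariates. Fits a maximum-likelihood logistic regression on
    indicator-coded covariates and returns a frame with ``propensity`` and
    ``logit`` columns. If some covariate stratum occurs in only one cohort
    the logistic fit is perfectly separated; the model then falls back to
    empirical stratum proportions (the saturated fit) with clipped
    probabilities, which reduces matching to stratum-exact behaviour.
    """
    df = patient_df.reset_index(drop=True)
    for col in ("cohort", *covariates):
        if col not in df.columns:
            raise ValidationError(f"patient table is missing column {col!r}")
    if set(df["cohort"].unique()) != {"reference", "target"}:
        raise ValidationError("both cohort labels must be present")
    y = (df["cohort"] == "target").astype(float)

    strata = df[list(covariates)].apply(tuple, axis=1)
    method = "logistic"
    one_cohort = df.groupby(strata)["cohort"].nunique() < 2
    if one_cohort.any():
        logger.warning(
            "perfect separation: %d covariate stratum(s) present in only one "
            "cohort; falling back to stratum-exact matching",
            int(one_cohort.sum()),
        )
        method = "stratum"
        prop = strata.map(y.groupby(strata).mean()).astype(float)
    else:
        import statsmodels.api as sm

        design = _indicator_design(df, covariates)
        # drop one level per covariate for identifiability, keep intercept
        keep = []
        for cov in covariates:
            levels = [c for c in design.columns if c.startswith(f"{cov}=")]
            keep.extend(levels[1:])
        X = sm.add_constant(design[keep], has_constant="add")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            prop = pd.Series(model.fit().predict(X), index=df.index)
        except Exception:  # numerical separation not caught above
            logger.warning("logistic fit failed; using stratum proportions")
            method = "stratum"
            prop = strata.map(y.groupby(strata).mean()).astype(float)

    prop = prop.clip(_PROB_CLIP, 1 - _PROB_CLIP)
    out = df[["patient_id", "cohort"]].copy()
    out["propensity"] = prop.to_numpy()
    out["logit"] = np.log(out["propensity"] / (1 - out["propensity"]))
    out["stratum"] = strata.map(lambda t: "|".join(str(v) for v in t)).to_numpy()
    out.attrs["method"] = method
    return out


def optimal_match(
    ref_logits: pd.Series, target_logits: pd.Series
) -> list[tuple[str, str]]:
    """Optimal 1:1 matching without replacement on |logit difference|.

    ``ref_logits`` and ``target_logits`` are indexed by patient id. Every
    reference patient is matched; target patients may be dropped. The total
    absolute logit distance is minimised globally (rectangular assignment);
    ties are broken deterministically in (reference id, target id) lexical
    order via an infinitesimal perturbation.
    """
    ref = ref_logits.sort_index()
    tgt = target_logits.sort_index()
    if len(tgt) < len(ref):
        raise InfeasibleMatchError(
            f"target cohort ({len(tgt)}) smaller than reference ({len(ref)})"
        )
    cost = np.abs(ref.to_numpy()[:, None] - tgt.to_numpy()[None, :])
    scale = max(cost.max(), 1.0)
    jitter = np.add.outer(
        np.arange(len(ref)) * len(tgt), np.arange(len(tgt))
    ).astype(float)
    cost = cost + jitter * (1e-12 * scale / max(jitter.max(), 1.0))
    rows, cols = linear_sum_assignment(cost)
    pairs = [(str(ref.index[i]), str(tgt.index[j])) for i, j in zip(rows, cols)]
    return sorted(pairs)


def exhaustive_match(
    ref_logits: pd.Series, target_logits: pd.Series
) -> tuple[float, list[tuple[str, str]]]:
    """Brute-force minimum-distance 1:1 matching (oracle; tiny instances only)."""
    ref = ref_logits.sort_index()
    tgt = target_logits.sort_index()
    if len(tgt) < len(ref):
        raise InfeasibleMatchError("target smaller than reference")
    best, best_pairs = np.inf, None
    for combo in itertools.permutations(range(len(tgt)), len(ref)):
        total = sum(abs(ref.iloc[i] - tgt.iloc[j]) for i, j in enumerate(combo))
        if total < best - 1e-15:
            best = total
            best_pairs = [(str(ref.index[i]), str(tgt.index[j]))
                          for i, j in enumerate(combo)]
    return float(best), sorted(best_pairs)


def _stratum_exact_match(ref: pd.DataFrame, tgt: pd.DataFrame
                         ) -> list[tuple[str, str]]:
    """Exact within-stratum 1:1 pairing; leftover references matched on logits.

    Used when the logistic model is perfectly separated. Pairing within a
    stratum is in lexical patient-id order; reference patients in strata
    without enough targets fall back to optimal logit matching against the
    remaining targets, so every reference patient is still kept.
    """
    if len(tgt) < len(ref):
        raise InfeasibleMatchError(
            f"target cohort ({len(tgt)}) smaller than reference ({len(ref)})"
        )
    pairs: list[tuple[str, str]] = []
    leftover_ref, used_tgt = [], set()
    for stratum, ref_grp in ref.groupby("stratum"):
        ref_ids = sorted(ref_grp["patient_id"])
        tgt_ids = sorted(tgt.loc[tgt["stratum"] == stratum, "patient_id"])
        for r, t in zip(ref_ids, tgt_ids):
            pairs.append((r, t))
            used_tgt.add(t)
        leftover_ref.extend(ref_ids[len(tgt_ids):])
    if leftover_ref:
        logger.warning(
            "%d reference patient(s) lack same-stratum targets; matching "
            "them on propensity logits", len(leftover_ref))
        remaining = tgt[~tgt["patient_id"].isin(used_tgt)]
        pairs.extend(optimal_match(
            ref.set_index("patient_id").loc[leftover_ref, "logit"],
            remaining.set_index("patient_id")["logit"],
        ))
    return sorted(pairs)


def standardized_mean_difference(group_a, group_b) -> float:
    """(mean_a - mean_b) / sqrt((var_a + var_b)/2), sample variances; 0/0 -> 0."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values for an SMD")
    num = a.mean() - b.mean()
    denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float(num / denom)


def match_cohorts(
    patient_df: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> MatchResult:
    """Propensity-match target patients to the reference cohort.

    ``patient_df``: one row per patient (use ``CohortTable.index_lesions()``
    so multi-lesion patients enter with their highest-grade lesion).
    """
    scores = fit_propensity(patient_df, covariates)
    merged = patient_df.merge(
        scores[["patient_id", "propensity", "logit", "stratum"]], on="patient_id")
    ref = merged[merged["cohort"] == "reference"]
    tgt = merged[merged["cohort"] == "target"]
    if scores.attrs.get("method") == "stratum":
        pairs = _stratum_exact_match(ref, tgt)
    else:
        pairs = optimal_match(
            ref.set_index("patient_id")["logit"],
            tgt.set_index("patient_id")["logit"],
        )
    matched_ids = {t for _, t in pairs}

    design = _indicator_design(merged, covariates)
    ref_idx = merged["cohort"] == "reference"
    tgt_idx = merged["cohort"] == "target"
    tgt_matched_idx = tgt_idx & merged["patient_id"].isin(matched_ids)
    smd_before = design.apply(
        lambda c: standardized_mean_difference(c[ref_idx], c[tgt_idx])
    )
    smd_after = design.apply(
        lambda c: standardized_mean_difference(c[ref_idx], c[tgt_matched_idx])
    )
    return MatchResult(
        pairs=pairs,
        propensity=merged.set_index("patient_id")["propensity"],
        logit=merged.set_index("patient_id")["logit"],
        smd_before=smd_before,
        smd_after=smd_after,
    )


def compute_scaling_factors(
    ref_voxels: pd.DataFrame, target_voxels: pd.DataFrame
) -> ScalingFactors:
    """Median-scaling factors from pooled lesion voxels of both cohorts.

    Each frame has one row per voxel with ``adc`` (mm^2/s) and ``fbv``
    columns, pooled over all lesions of the (matched) cohort.
    """
    for name, pool in (("reference", ref_voxels), ("target", target_voxels)):
        if len(pool) == 0:
            raise ValidationError(f"{name} voxel pool is empty")
    med_ref_adc = float(np.median(ref_voxels["adc"]))
    med_tgt_adc = float(np.median(target_voxels["adc"]))
    med_ref_fbv = float(np.median(ref_voxels["fbv"]))
    med_tgt_fbv = float(np.median(target_voxels["fbv"]))
    if med_tgt_adc <= 0 or med_tgt_fbv <= 0:
        raise CalibrationError("target median is zero; scaling undefined")
    return ScalingFactors(f_adc=med_ref_adc / med_tgt_adc,
                          f_fbv=med_ref_fbv / med_tgt_fbv)


def apply_scaling(data, factors: ScalingFactors):
    """Multiply ADC by F_ADC and fBV by F_fBV.

    Accepts a ParamMap (returns a new map, validity untouched) or a voxel
    DataFrame with ``adc``/``fbv`` columns (returns a copy). Scaled fBV is
    re-clamped to [0, 1]; the number of clamped voxels is logged.
    """
    if isinstance(data, ParamMap):
        fbv = data.fbv * factors.f_fbv
        n_clamped = int(np.sum((fbv > 1.0) & data.valid))
        if n_clamped:
            logger.info("apply_scaling: clamped fBV in %d voxel(s)", n_clamped)
        return ParamMap(
            adc=data.adc * factors.f_adc,
            fbv=np.clip(fbv, 0.0, 1.0),
            valid=data.valid.copy(),
        )
    out = data.copy()
    out["adc"] = out["adc"] * factors.f_adc
    fbv = out["fbv"] * factors.f_fbv
    n_clamped = int((fbv > 1.0).sum())
    if n_clamped:
        logger.info("apply_scaling: clamped fBV in %d voxel(s)", n_clamped)
    out["fbv"] = fbv.clip(0.0, 1.0)
    return out
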
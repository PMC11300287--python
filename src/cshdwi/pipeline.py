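"""End-to-end orchestration: simulate -> fit -> HF -> match -> calibrate -> compare.

Single-process and deterministic: rerunning with the same config and seed
reproduces identical artifacts. Every written table embeds the seed and a
hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    MatchResult,
    ScalingFactors,
    apply_scaling,
    compute_scaling_factors,
    match_cohorts,
)
from .cohort_stats import (
    compare_groups,
    kruskal_wallis_by_grade,
    pearson_hf_vs_grade,
)
from .csh import DEFAULT_CSH_PARAMS, CSHParams, lesion_hf
from .errors import CSHError
from .io_formats import write_cohort_table, write_hf_table
from .ivim import DEFAULT_FIT_CONFIG, IVIMFitConfig, ParamMap, fit_map
from .synthetic_cohort import SimulationConfig, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)


class PipelineStageError(CSHError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    csh: CSHParams = field(default_factory=CSHParams)
    ivim: IVIMFitConfig = field(default_factory=IVIMFitConfig)
    alpha: float = 0.05
    covariates: tuple[str, ...] = ("pGG", "pTstage")

    def to_dict(self) -> dict:
        return _tuples_to_lists(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(
            sim=_dataclass_from_dict(SimulationConfig, data.get("sim", {})),
            csh=_dataclass_from_dict(CSHParams, data.get("csh", {})),
            ivim=_dataclass_from_dict(IVIMFitConfig, data.get("ivim", {})),
            alpha=float(data.get("alpha", 0.05)),
            covariates=tuple(data.get("covariates", ("pGG", "pTstage"))),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _dataclass_from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: SyntheticStudy
    hf_reference: pd.DataFrame  # per lesion, reference cohort (unscaled)
    hf_target: pd.DataFrame  # per lesion, target cohort after scaling
    match: MatchResult
    factors: ScalingFactors
    pooled_medians: dict
    comparisons: dict
    summary: dict


def _lesion_voxel_pool(pmaps: dict[str, ParamMap], study: SyntheticStudy,
                       patient_ids) -> pd.DataFrame:
    """Pool valid fitted lesion voxels of the given patients."""
    frames = []
    for pid in sorted(patient_ids):
        pmap = pmaps[pid]
        mask = study.patients[pid][1]
        sel = (mask.labels > 0) & pmap.valid
        frames.append(pd.DataFrame({
            "patient_id": pid,
            "lesion_id": mask.labels[sel],
            "adc": pmap.adc[sel],
            "fbv": pmap.fbv[sel],
        }))
    return pd.concat(frames, ignore_index=True)


def _hf_table(pmaps: dict[str, ParamMap], study: SyntheticStudy,
              patient_ids, params: CSHParams) -> pd.DataFrame:
    rows = []
    for pid in sorted(patient_ids):
        mask = study.patients[pid][1]
        for lid in mask.lesion_ids:
            r = lesion_hf(pmaps[pid], mask, lid, params, patient_id=pid)
            rows.append({
                "patient_id": pid, "lesion_id": lid,
                "n_voxels": r.n_voxels, "n_valid_voxels": r.n_valid_voxels,
                "hf_dwi": r.hf_dwi, "median_adc": r.median_adc,
                "median_fbv": r.median_fbv,
            })
    return pd.DataFrame(rows)


def _per_patient_hf(hf: pd.DataFrame, cohort_index: pd.DataFrame) -> pd.DataFrame:
    """Join lesion HF onto the per-patient index-lesion table."""
    return cohort_index.merge(hf, on=["patient_id", "lesion_id"], how="inner")


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole study pipeline; optionally write stage artifacts."""

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
        return _Ctx()

    with stage("simulate"):
        study = simulate_study(config.sim, csh_params=config.csh)
        table = study.cohort_table
        ref_ids = table.patients("reference")
        tgt_ids = table.patients("target")

    with stage("ivim-fit"):
        pmaps = {
            pid: fit_map(dwi, mask, config.ivim)
            for pid, (dwi, mask) in study.patients.items()
        }

    with stage("hf"):
        hf_ref = _hf_table(pmaps, study, ref_ids, config.csh)

    with stage("match"):
        match = match_cohorts(table.index_lesions(), config.covariates)

    with stage("calibrate"):
        ref_pool = _lesion_voxel_pool(pmaps, study, ref_ids)
        tgt_pool = _lesion_voxel_pool(pmaps, study, match.matched_target_ids)
        factors = compute_scaling_factors(ref_pool, tgt_pool)
        pooled_medians = {
            "reference_adc": float(np.median(ref_pool["adc"])),
            "reference_fbv": float(np.median(ref_pool["fbv"])),
            "target_adc": float(np.median(tgt_pool["adc"])),
            "target_fbv": float(np.median(tgt_pool["fbv"])),
        }

    with stage("scale"):
        pmaps_scaled = {pid: apply_scaling(pmaps[pid], factors) for pid in tgt_ids}
        pmaps_scaled.update({pid: pmaps[pid] for pid in ref_ids})

    with stage("hf-target"):
        hf_tgt = _hf_table(pmaps_scaled, study, tgt_ids, config.csh)

    with stage("compare"):
        index = table.index_lesions()
        ref_patient_hf = _per_patient_hf(hf_ref, index[index["cohort"] == "reference"])
        matched_index = index[index["patient_id"].isin(match.matched_target_ids)]
        tgt_patient_hf = _per_patient_hf(hf_tgt, matched_index)

        comparisons = {}
        for label, df in (("reference", ref_patient_hf), ("target_matched", tgt_patient_hf)):
            for grouping in ("pGG_low_vs_high", "pTstage_2_vs_3"):
                cmp = compare_groups(df, grouping, alpha=config.alpha)
                comparisons[f"{label}.{grouping}"] = cmp.as_dict()

        full_tgt = _per_patient_hf(
            hf_tgt, table.df[table.df["cohort"] == "target"]
        )  # per lesion: join on all lesion rows
        hf_by_grade = {
            g: full_tgt.loc[full_tgt["pGG"] == g, "hf_dwi"].to_numpy()
            for g in range(1, 6)
        }
        kw = kruskal_wallis_by_grade(hf_by_grade)
        comparisons["target_full.pGG_1_to_5"] = kw.as_dict()
        rho, rho_p = pearson_hf_vs_grade(full_tgt["hf_dwi"], full_tgt["pGG"])
        comparisons["target_full.pearson"] = {
            "grouping": "pGG_1_to_5", "test_used": "pearson",
            "statistic": rho, "p_value": rho_p,
            "n_lesions": int(len(full_tgt)),
        }

    summary = {
        "seed": config.sim.seed,
        "config_hash": config.config_hash,
        "n_reference_patients": len(ref_ids),
        "n_target_patients": len(tgt_ids),
        "n_matched_pairs": len(match.pairs),
        "scaling_factors": {"f_adc": factors.f_adc, "f_fbv": factors.f_fbv},
        "pooled_medians_pre_scaling": pooled_medians,
        "max_abs_smd_before": float(match.smd_before.abs().max()),
        "max_abs_smd_after": float(match.smd_after.abs().max()),
        "comparisons": comparisons,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": config.sim.seed, "config_hash": config.config_hash}
        write_cohort_table(table, out / "cohort.csv", metadata=meta)
        write_hf_table(hf_ref, out / "hf_reference.csv", metadata=meta)
        write_hf_table(hf_tgt, out / "hf_target_scaled.csv", metadata=meta)
        pd.DataFrame(match.pairs, columns=["reference_patient_id", "target_patient_id"]
                     ).to_csv(out / "pairs.csv", index=False)
        (out / "factors.json").write_text(json.dumps(
            {"f_adc": factors.f_adc, "f_fbv": factors.f_fbv, **meta},
            indent=2, sort_keys=True))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))

    return PipelineResult(
        config=config, study=study, hf_reference=hf_ref, hf_target=hf_tgt,
        match=match, factors=factors, pooled_medians=pooled_medians,
        comparisons=comparisons, summary=summary,
    )
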
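import numpy as np
import pandas as pd
import pytest

from cshdwi import (
    InfeasibleMatchError,
    ParamMap,
    ScalingFactors,
    ValidationError,
    apply_scaling,
    compute_scaling_factors,
    fit_propensity,
    match_cohorts,
    optimal_match,
    standardized_mean_difference,
)
from cshdwi.calibration import exhaustive_match


def _patient_df(ref_rows, tgt_rows):
    """rows: list of (pGG, pTstage) per cohort."""
    rows = []
    for i, (g, t) in enumerate(ref_rows):
        rows.append({"patient_id": f"R{i:03d}", "cohort": "reference",
                     "pGG": g, "pTstage": t})
    for i, (g, t) in enumerate(tgt_rows):
        rows.append({"patient_id": f"T{i:03d}", "cohort": "target",
                     "pGG": g, "pTstage": t})
    return pd.DataFrame(rows)


class TestPropensity:
    def test_identical_cohorts_give_zero_distances(self):
        rows = [(2, 2), (3, 3), (5, 3)] * 4
        scores = fit_propensity(_patient_df(rows, rows))
        merged = scores.merge(_patient_df(rows, rows), on=["patient_id", "cohort"])
        for _, grp in merged.groupby(["pGG", "pTstage"]):
            assert np.ptp(grp["logit"]) < 1e-6

    def test_null_model_returns_cohort_proportion(self):
        # covariate independent of cohort: propensity ~ target share (2/3)
        ref = [(2, 2)] * 10 + [(3, 3)] * 10
        tgt = [(2, 2)] * 20 + [(3, 3)] * 20
        scores = fit_propensity(_patient_df(ref, tgt))
        np.testing.assert_allclose(scores["propensity"], 2 / 3, atol=1e-6)

    def test_two_stratum_closed_form(self):
        # stratum A: 10 ref / 30 tgt -> 0.75; stratum B: 30 ref / 10 tgt -> 0.25
        ref = [(1, 2)] * 10 + [(2, 2)] * 30
        tgt = [(1, 2)] * 30 + [(2, 2)] * 10
        scores = fit_propensity(_patient_df(ref, tgt), covariates=("pGG",))
        merged = scores.merge(_patient_df(ref, tgt), on=["patient_id", "cohort"])
        np.testing.assert_allclose(
            merged.loc[merged["pGG"] == 1, "propensity"], 0.75, atol=1e-6)
        np.testing.assert_allclose(
            merged.loc[merged["pGG"] == 2, "propensity"], 0.25, atol=1e-6)

    def test_separated_stratum_falls_back(self, caplog):
        ref = [(1, 2)] * 5 + [(2, 2)] * 5
        tgt = [(2, 2)] * 12  # pGG=1 stratum exists only in the reference
        with caplog.at_level("WARNING"):
            scores = fit_propensity(_patient_df(ref, tgt), covariates=("pGG",))
        assert "separation" in caplog.text
        assert scores["propensity"].between(0, 1).all()

    def test_missing_cohort_label_rejected(self):
        df = _patient_df([(2, 2)] * 3, [])
        with pytest.raises(ValidationError):
            fit_propensity(df)


class TestOptimalMatch:
    def test_exact_overlap(self):
        pairs = optimal_match(pd.Series([0.0, 1.0], index=["r1", "r2"]),
                              pd.Series([1.0, 0.0, 5.0], index=["t1", "t2", "t3"]))
        assert pairs == [("r1", "t2"), ("r2", "t1")]

    def test_nearest_target_chosen(self):
        pairs = optimal_match(pd.Series([0.0], index=["r1"]),
                              pd.Series([0.4, 0.3], index=["t1", "t2"]))
        assert pairs == [("r1", "t2")]

    def test_global_not_greedy_optimum(self):
        ref = pd.Series([0.0, 0.6], index=["r1", "r2"])
        tgt = pd.Series([0.1, 0.5], index=["t1", "t2"])
        pairs = optimal_match(ref, tgt)
        total = sum(abs(ref[r] - tgt[t]) for r, t in pairs)
        best, _ = exhaustive_match(ref, tgt)
        assert total == pytest.approx(best) == pytest.approx(0.2)

    def test_target_smaller_than_reference_infeasible(self):
        with pytest.raises(InfeasibleMatchError):
            optimal_match(pd.Series([0.0, 1.0], index=["r1", "r2"]),
                          pd.Series([0.5], index=["t1"]))

    def test_every_reference_matched_no_target_reused(self, rng):
        ref = pd.Series(rng.normal(size=6), index=[f"r{i}" for i in range(6)])
        tgt = pd.Series(rng.normal(size=10), index=[f"t{i}" for i in range(10)])
        pairs = optimal_match(ref, tgt)
        assert len(pairs) == 6
        assert sorted(r for r, _ in pairs) == sorted(ref.index)
        assert len({t for _, t in pairs}) == 6

    def test_optimality_equals_exhaustive_enumeration(self, rng):
        """On all tiny random instances the assignment total is the minimum."""
        for _ in range(40):
            n_ref = int(rng.integers(1, 5))
            n_tgt = int(rng.integers(n_ref, 7))
            ref = pd.Series(rng.normal(size=n_ref),
                            index=[f"r{i}" for i in range(n_ref)])
            tgt = pd.Series(rng.normal(size=n_tgt),
                            index=[f"t{i}" for i in range(n_tgt)])
            pairs = optimal_match(ref, tgt)
            total = sum(abs(ref[r] - tgt[t]) for r, t in pairs)
            best, _ = exhaustive_match(ref, tgt)
            assert total == pytest.approx(best, rel=1e-12)


class TestSMD:
    def test_identical_groups_zero(self):
        assert standardized_mean_difference([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_example(self):
        smd = standardized_mean_difference([1, 1, 0, 0], [1, 0, 0, 0])
        assert smd == pytest.approx(0.25 / np.sqrt((1 / 3 + 0.25) / 2), rel=1e-12)
        assert smd == pytest.approx(0.463, abs=5e-4)

    def test_constant_equal_groups_zero_by_convention(self):
        assert standardized_mean_difference([2, 2, 2], [2, 2]) == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            standardized_mean_difference([1.0], [1, 2])


class TestMatchCohorts:
    def test_balance_improves_under_injected_imbalance(self, rng):
        # target over-represents low grades, as the full external cohort did
        ref_g = rng.choice([1, 2, 3, 4, 5], size=50, p=[.08, .42, .25, .15, .10])
        tgt_g = rng.choice([1, 2, 3, 4, 5], size=150, p=[.30, .40, .15, .10, .05])
        df = _patient_df([(g, 2 + int(rng.random() < 0.5)) for g in ref_g],
                         [(g, 2 + int(rng.random() < 0.3)) for g in tgt_g])
        res = match_cohorts(df)
        assert len(res.pairs) == 50
        assert res.smd_after.abs().max() <= res.smd_before.abs().max()

    def test_matched_marginals_identical_when_counts_permit(self):
        ref = [(2, 2)] * 5 + [(3, 3)] * 5
        tgt = [(2, 2)] * 20 + [(3, 3)] * 7 + [(1, 2)] * 10
        res = match_cohorts(_patient_df(ref, tgt))
        df = _patient_df(ref, tgt).set_index("patient_id")
        matched = df.loc[res.matched_target_ids]
        assert matched["pGG"].value_counts().to_dict() == {2: 5, 3: 5}
        assert res.smd_after.abs().max() < 1e-12


class TestScaling:
    def test_printed_median_worked_example(self):
        # pools engineered to the printed medians 0.70e-3 and 0.84e-3
        ref = pd.DataFrame({"adc": [0.6e-3, 0.70e-3, 0.9e-3],
                            "fbv": [0.10, 0.12, 0.15]})
        tgt = pd.DataFrame({"adc": [0.7e-3, 0.84e-3, 1.1e-3],
                            "fbv": [0.05, 0.08, 0.20]})
        factors = compute_scaling_factors(ref, tgt)
        assert round(factors.f_adc, 2) == 0.83
        assert factors.f_fbv == pytest.approx(0.12 / 0.08, rel=1e-12)

    def test_identical_pools_give_unit_factors(self, rng):
        pool = pd.DataFrame({"adc": rng.uniform(0.3e-3, 1.5e-3, 100),
                             "fbv": rng.uniform(0.01, 0.4, 100)})
        factors = compute_scaling_factors(pool, pool)
        assert factors.f_adc == 1.0 and factors.f_fbv == 1.0

    def test_median_equivariance(self, rng):
        pool = pd.DataFrame({"adc": rng.uniform(0.3e-3, 1.5e-3, 101),
                             "fbv": rng.uniform(0.01, 0.4, 101)})
        doubled = pool.assign(adc=pool["adc"] * 2, fbv=pool["fbv"] * 2)
        factors = compute_scaling_factors(pool, doubled)
        assert factors.f_adc == 0.5 and factors.f_fbv == 0.5

    def test_bias_recovery_is_exact(self, rng):
        """Copy a cohort, inject biases (1.2, 0.65): factors are the inverses."""
        pool = pd.DataFrame({"adc": rng.uniform(0.3e-3, 1.5e-3, 500),
                             "fbv": rng.uniform(0.01, 0.4, 500)})
        biased = pool.assign(adc=pool["adc"] * 1.2, fbv=pool["fbv"] * 0.65)
        factors = compute_scaling_factors(pool, biased)
        assert factors.f_adc == pytest.approx(1 / 1.2, rel=1e-12)
        assert factors.f_fbv == pytest.approx(1 / 0.65, rel=1e-12)
        scaled = apply_scaling(biased, factors)
        for col in ("adc", "fbv"):
            assert np.median(scaled[col]) == pytest.approx(
                np.median(pool[col]), rel=1e-12)

    def test_identity_factors_leave_data_unchanged(self, rng):
        pool = pd.DataFrame({"adc": rng.uniform(0, 2e-3, 50),
                             "fbv": rng.uniform(0, 1, 50)})
        out = apply_scaling(pool, ScalingFactors(1.0, 1.0))
        pd.testing.assert_frame_equal(out, pool)

    def test_fbv_clamped_after_scaling(self, caplog):
        pmap = ParamMap(adc=np.full((1, 1, 1), 1e-3),
                        fbv=np.full((1, 1, 1), 0.9),
                        valid=np.ones((1, 1, 1), dtype=bool))
        with caplog.at_level("INFO"):
            out = apply_scaling(pmap, ScalingFactors(1.0, 1.54))
        assert out.fbv[0, 0, 0] == 1.0
        assert "clamped" in caplog.text
        assert out.valid.all()  # validity untouched

    def test_empty_pool_rejected(self):
        ref = pd.DataFrame({"adc": [1e-3], "fbv": [0.1]})
        with pytest.raises(ValidationError):
            compute_scaling_factors(ref, ref.iloc[:0])

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValidationError):
            ScalingFactors(0.0, 1.0)
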
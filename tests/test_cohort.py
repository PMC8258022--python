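"""Synthetic-cohort generator: determinism, moment and structure recovery,
diary consistency, Goldberg round-trip, and clinical-marker calibration."""

import numpy as np
import pandas as pd
import pytest

from upfmed.association import mediator_model, outcome_model
from upfmed.cmr import score_frame
from upfmed.cohort import (
    CohortConfig,
    StructuralCoefficients,
    TABLE_COLUMNS,
    build_catalogue,
    calibrate_generator,
    component_probabilities,
    generate_clinical,
    generate_cohort,
)
from upfmed.diet import compute_dash_score, food_group_intakes, goldberg_classify_array
from upfmed.nova import classify_catalogue, nova4_share_by_participant


class TestContracts:
    def test_empty_cohort_has_full_schema(self):
        cohort = generate_cohort(CohortConfig(n=0, seed=1))
        assert list(cohort.table.columns) == list(TABLE_COLUMNS)
        assert len(cohort.table) == 0

    def test_same_seed_is_byte_identical(self):
        cfg = CohortConfig(n=200, seed=77, mode="diary")
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for name in ("table", "participants", "clinical", "diary", "catalogue"):
            assert getattr(c1, name).to_csv(index=False) == getattr(c2, name).to_csv(index=False)

    def test_different_seeds_differ(self):
        t1 = generate_cohort(CohortConfig(n=100, seed=1)).table
        t2 = generate_cohort(CohortConfig(n=100, seed=2)).table
        assert not np.allclose(t1["nova4_pct"], t2["nova4_pct"])

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(misreporting_proportions=(0.5, 0.4, 0.2))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(mode="panel")


@pytest.fixture(scope="module")
def moments_cohort():
    return generate_cohort(CohortConfig(n=20000, seed=2024)).table


@pytest.fixture(scope="module")
def structure_cohort():
    return generate_cohort(CohortConfig(n=20000, seed=515)).table


@pytest.fixture(scope="module")
def diary_cohort():
    return generate_cohort(CohortConfig(n=250, seed=99, mode="diary"))


class TestMomentRecovery:
    def test_exposure_moments(self, moments_cohort):
        n = len(moments_cohort)
        se_mean = 11.6 / np.sqrt(n)
        assert moments_cohort["nova4_pct"].mean() == pytest.approx(58.3, abs=3 * se_mean)
        assert moments_cohort["nova4_pct"].std() == pytest.approx(11.6, abs=3 * 11.6 / np.sqrt(2 * n))

    def test_age_and_sex_composition(self, moments_cohort):
        assert moments_cohort["age"].mean() == pytest.approx(40.9, abs=0.35)
        assert (moments_cohort["sex"] == "male").mean() == pytest.approx(0.608, abs=0.015)

    def test_misreporting_split(self, moments_cohort):
        freq = moments_cohort["misreporting"].value_counts(normalize=True)
        for level, target in zip(("under", "acceptable", "over"), (0.384, 0.597, 0.019)):
            se = np.sqrt(target * (1 - target) / len(moments_cohort))
            assert freq[level] == pytest.approx(target, abs=3 * se + 1e-12)

    def test_reporting_groups_order_exposure_means(self, moments_cohort):
        means = moments_cohort.groupby("misreporting")["nova4_pct"].mean()
        assert means["under"] < means["acceptable"] < means["over"]

    def test_crude_correlation_near_target(self, moments_cohort):
        r = np.corrcoef(moments_cohort["nova4_pct"], moments_cohort["dash"])[0, 1]
        assert r == pytest.approx(-0.32, abs=0.02)


class TestStructureRecovery:
    def test_adjusted_mediator_slope(self, structure_cohort):
        fit = mediator_model(structure_cohort, variant="text")
        a = fit.params["nova4_pct"]
        assert abs(a - (-0.197)) < 3 * fit.bse["nova4_pct"]

    def test_outcome_slopes(self, structure_cohort):
        fit = outcome_model(structure_cohort, adjust_for_diet_quality=True)
        assert abs(fit.params["dash"] - (-0.008)) < 3 * fit.bse["dash"]
        assert abs(fit.params["nova4_pct"] - 0.001) < 3 * fit.bse["nova4_pct"]


class TestDiaryMode:
    def test_recomputed_exposure_matches_assigned(self, diary_cohort):
        assignments = classify_catalogue(diary_cohort.catalogue_codes)
        share = nova4_share_by_participant(diary_cohort.diary, diary_cohort.catalogue_codes, assignments)
        assigned = diary_cohort.table.set_index("participant_id")["nova4_pct"]
        within = ((share - assigned).abs() <= 1.0).mean()
        assert within >= 0.99

    def test_recomputed_dash_close_to_assigned(self, diary_cohort):
        sub = diary_cohort.table.set_index("participant_id")["dash"]
        errs = []
        for pid, entries in diary_cohort.diary.groupby("participant_id"):
            intakes = food_group_intakes(entries.to_dict("records"),
                                         diary_cohort.catalogue_codes, n_days=7)
            errs.append(compute_dash_score(intakes).total - sub[pid])
        assert np.median(np.abs(errs)) < 1.0

    def test_goldberg_roundtrip_reproduces_misreporting(self, diary_cohort):
        # classification of the generated intakes recovers the latent category
        diary = diary_cohort.diary
        codes = diary_cohort.catalogue_codes
        e100 = diary["code_id"].map(lambda c: codes[c].energy_per_100g)
        energy = (diary["grams"] * e100 / 100.0).groupby(diary["participant_id"]).sum()
        p = diary_cohort.participants.set_index("participant_id")
        from upfmed.diet import compute_bmr_array

        bmr = compute_bmr_array(p["age"].to_numpy(), p["sex"].to_numpy() == "male",
                                p["weight_kg"].to_numpy())
        status = goldberg_classify_array(energy[p.index].to_numpy() / 7.0, bmr)
        assigned = diary_cohort.table.set_index("participant_id").loc[p.index, "misreporting"]
        assert (status == assigned.to_numpy()).mean() == 1.0

    def test_clinical_table_scores_to_table_cmr(self, diary_cohort):
        scored = score_frame(diary_cohort.clinical)
        assert (scored["cmr"].to_numpy() == diary_cohort.table["cmr"].to_numpy()).all()


class TestClinicalGeneration:
    def test_extreme_negative_risk_floors_all_probabilities(self):
        p = component_probabilities(np.array([-1e6]))
        assert np.allclose(p, StructuralCoefficients().prob_clip[0])

    def test_half_probability_components_give_mean_cmr_2_5(self):
        coeffs = StructuralCoefficients(component_base_probs=(0.5,) * 5)
        n = 20000
        clin = generate_clinical(np.zeros(n), np.array(["male"] * n, dtype=object),
                                 coefficients=coeffs, seed=5)
        mean_cmr = score_frame(clin)["cmr"].mean()
        assert mean_cmr == pytest.approx(2.5, abs=3 * np.sqrt(5 * 0.25 / n))

    def test_component_exceedance_tracks_latent_risk(self):
        n = 40000
        eta = np.full(n, 0.5)  # each component probability shifted up by 0.1
        clin = generate_clinical(eta, np.array(["female"] * n, dtype=object), seed=8)
        scored = score_frame(clin)
        base = StructuralCoefficients().component_base_probs
        for j, comp in enumerate(("obesity", "dyslipidaemia", "hypertension",
                                  "inflammation", "dysglycaemia")):
            target = base[j] + 0.1
            se = np.sqrt(target * (1 - target) / n)
            assert scored[comp].mean() == pytest.approx(target, abs=4 * se)

    def test_nonfinite_latent_risk_rejected(self):
        with pytest.raises(ValueError):
            generate_clinical(np.array([np.nan]), np.array(["male"], dtype=object))


class TestCalibration:
    def test_null_targets_converge_to_null_slopes(self):
        targets = StructuralCoefficients(b_mediator_to_outcome=0.0, c_direct=0.0)
        out = calibrate_generator(targets, n_pilot=10000, seed=3)
        assert out["converged"]
        assert out["outcome_scale_b"] == 1.0 and out["outcome_scale_c"] == 1.0
        last = out["history"][-1]
        assert abs(last["b_hat"]) < 0.005 and abs(last["c_hat"]) < 0.005

    def test_default_targets_within_two_se(self):
        out = calibrate_generator(n_pilot=10000, seed=3)
        assert out["converged"]

    def test_same_seed_identical_scales(self):
        o1 = calibrate_generator(n_pilot=10000, seed=4)
        o2 = calibrate_generator(n_pilot=10000, seed=4)
        assert o1 == o2

    def test_small_pilot_rejected(self):
        with pytest.raises(ValueError):
            calibrate_generator(n_pilot=500, seed=1)


def test_catalogue_energy_consistent_with_macros():
    codes, frame = build_catalogue()
    for code in codes.values():
        nut = code.nutrients_per_100g
        expected = 9 * nut.get("fat", 0) + 4 * nut.get("protein", 0) + 3.75 * nut.get("carbohydrate", 0)
        assert code.energy_per_100g == pytest.approx(expected)
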
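"""Cross-validated unit-weighted item profiler: oracle equality, planted
recovery, permutation nulls and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from emodiv.items import ALL_ITEMS
from emodiv.profiler import (
    EmotionProfiler,
    ProfilerError,
    cross_validated_profile,
    profile_all_symptoms,
    profiles_to_frame,
    render_profile_table,
    unit_weighted_score,
    zero_order_correlations,
)
from emodiv.simulate import default_spec, generate_cohort, plant_item_effect

from oracles import pearson_oracle


def planted_chr_frame(n=2000, seed=0, plants=(("sadness", "N1"), ("guilt", "P2"))):
    spec = default_spec(seed=seed)
    spec.n_chr = n
    spec.n_hc = 2
    spec.symptom_loadings = {}
    for item, sym in plants:
        spec = plant_item_effect(spec, item, sym, 0.5)
    frame = generate_cohort(spec).to_frame()
    return frame[frame["group"] == "CHR"].reset_index(drop=True)


class TestZeroOrderCorrelations:
    def test_item_identical_to_criterion_gives_one(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, size=(50, 18)).astype(float)
        r = zero_order_correlations(X, X[:, 3])
        assert r.iloc[3] == pytest.approx(1.0, abs=1e-12)

    def test_independent_criterion_null_bound(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = rng.integers(0, 5, size=(n, 18)).astype(float)
        r = zero_order_correlations(X, rng.normal(size=n))
        assert np.abs(r).max() < 3 / np.sqrt(n) + 0.02

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(12, 5))
            y = rng.normal(size=12)
            r = zero_order_correlations(X, y)
            for j in range(5):
                assert r.iloc[j] == pytest.approx(
                    pearson_oracle(X[:, j], y), abs=1e-10
                )

    def test_constant_criterion_rejected(self):
        X = np.random.default_rng(3).normal(size=(20, 18))
        with pytest.raises(ProfilerError, match="constant"):
            zero_order_correlations(X, np.ones(20))

    def test_zero_variance_item_gets_zero(self, caplog):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 18))
        X[:, 5] = 2.0
        with caplog.at_level("WARNING", logger="emodiv"):
            r = zero_order_correlations(X, rng.normal(size=30))
        assert r.iloc[5] == 0.0


class TestUnitWeightedScore:
    def test_single_positive_key_is_standardized_item(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 18))
        comp = unit_weighted_score(X, {ALL_ITEMS[2]: 1})
        expected = (X[:, 2] - X[:, 2].mean()) / X[:, 2].std(ddof=1)
        assert np.allclose(comp, expected)

    def test_flipping_signs_negates_composite(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 18))
        keys = {ALL_ITEMS[0]: 1, ALL_ITEMS[4]: -1, ALL_ITEMS[11]: 1}
        flipped = {k: -s for k, s in keys.items()}
        assert np.allclose(
            unit_weighted_score(X, keys), -unit_weighted_score(X, flipped)
        )

    def test_perfectly_correlated_items_composite_r_one(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=60)
        X = np.zeros((60, 18))
        X[:, 0] = base
        X[:, 1] = 2 * base + 3  # same direction, different scale
        comp = unit_weighted_score(X[:, :2], {0: 1, 1: 1}, item_names=[0, 1])
        assert np.corrcoef(comp, base)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_training_parameters_applied_to_new_data(self):
        rng = np.random.default_rng(8)
        train = rng.normal(loc=5, size=(50, 18))
        test = rng.normal(loc=0, size=(10, 18))
        item = ALL_ITEMS[0]
        center = {item: train[:, 0].mean()}
        scale = {item: train[:, 0].std(ddof=1)}
        comp = unit_weighted_score(test, {item: 1}, center, scale)
        # centered with the training mean, so strongly negative here
        assert comp.mean() < -1

    def test_empty_keys_rejected(self):
        with pytest.raises(ProfilerError):
            unit_weighted_score(np.zeros((5, 18)), {})


@pytest.fixture(scope="module")
def frame():
    return planted_chr_frame(n=2000, seed=31)


class TestCrossValidatedProfile:
    def test_planted_item_ranked_first_with_plausible_r(self, frame):
        prof = cross_validated_profile(frame, "N1", k=10, n_keep=3, seed=1)
        assert prof.selected[0] == "sadness"
        assert 0.4 <= prof.per_item.loc["sadness", "mean_r"] <= 0.6
        assert prof.cv_composite_r > 0.3

    def test_permuted_criterion_null(self, frame):
        null = frame.copy()
        null["N1"] = np.random.default_rng(9).permutation(null["N1"].to_numpy())
        prof = cross_validated_profile(null, "N1", k=10, n_keep=3, seed=1)
        assert abs(prof.cv_composite_r) < 0.1

    def test_determinism_same_seed(self, frame):
        a = cross_validated_profile(frame, "N1", k=10, n_keep=3, seed=2)
        b = cross_validated_profile(frame, "N1", k=10, n_keep=3, seed=2)
        assert a.selected == b.selected
        assert a.cv_composite_r == b.cv_composite_r
        assert a.per_item.equals(b.per_item)

    def test_selection_consistency_grows_with_n(self):
        small = planted_chr_frame(n=200, seed=33)
        large = planted_chr_frame(n=2000, seed=33)
        hits_small = hits_large = 0
        for seed in range(10):
            if cross_validated_profile(small, "N1", seed=seed).selected[0] == "sadness":
                hits_small += 1
            if cross_validated_profile(large, "N1", seed=seed).selected[0] == "sadness":
                hits_large += 1
        assert hits_large >= hits_small
        assert hits_large == 10

    def test_no_optimistic_leakage_on_null(self, frame):
        # held-out composite r should not beat the training-fold item r
        null = frame.copy()
        null["N1"] = np.random.default_rng(10).permutation(null["N1"].to_numpy())
        prof = cross_validated_profile(null, "N1", k=10, n_keep=3, seed=3)
        max_train = prof.fold_train_r.abs().to_numpy().max()
        assert abs(prof.cv_composite_r) <= max_train + 1e-9

    def test_too_few_participants_rejected(self, frame):
        with pytest.raises(ProfilerError, match="2k"):
            cross_validated_profile(frame.head(15), "N1", k=10)

    def test_constant_training_criterion_rejected(self, frame):
        flat = frame.head(40).copy()
        flat["N1"] = 3
        with pytest.raises(ProfilerError, match="constant"):
            cross_validated_profile(flat, "N1", k=10)

    def test_ties_broken_by_canonical_order(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(
            rng.integers(0, 5, size=(60, 18)), columns=list(ALL_ITEMS)
        )
        frame["N1"] = rng.integers(0, 7, size=60)
        prof = cross_validated_profile(frame, "N1", k=5, n_keep=18, seed=4)
        ranked = prof.selected
        mean_r = prof.per_item["mean_r"]
        for a, b in zip(ranked, ranked[1:]):
            if abs(mean_r[a]) == abs(mean_r[b]):
                assert ALL_ITEMS.index(a) < ALL_ITEMS.index(b)
            else:
                assert abs(mean_r[a]) > abs(mean_r[b])


class TestProfileAllSymptoms:
    def test_multi_effect_recovery(self):
        frame = planted_chr_frame(n=2000, seed=35)
        profiles = {p.criterion: p for p in profile_all_symptoms(frame, seed=5)}
        assert profiles["N1"].selected[0] == "sadness"
        assert profiles["P2"].selected[0] == "guilt"

    def test_null_cohort_all_low_signal(self):
        frame = planted_chr_frame(n=2000, seed=36, plants=())
        profiles = profile_all_symptoms(frame, seed=6)
        for p in profiles:
            assert p.per_item["mean_r"].abs().max() < 0.1

    def test_eleven_rows_and_rendering(self):
        frame = planted_chr_frame(n=200, seed=37)
        profiles = profile_all_symptoms(frame, n_keep=3, seed=7)
        assert len(profiles) == 11
        assert [p.criterion for p in profiles] == [
            "P1", "P2", "P3", "P4", "P5", "N1", "N2", "N3", "N4", "N5", "N6",
        ]
        table = render_profile_table(profiles, top=3)
        rows = [ln for ln in table.splitlines() if ln.startswith("| ")]
        assert len(rows) == 12  # header + 11 symptoms
        long = profiles_to_frame(profiles)
        assert (long.groupby("criterion")["selected"].sum() == 3).all()

    def test_constant_symptom_skipped_with_warning(self, caplog):
        frame = planted_chr_frame(n=100, seed=38)
        frame["P3"] = 0
        with caplog.at_level("WARNING", logger="emodiv"):
            profiles = profile_all_symptoms(frame, seed=8)
        assert len(profiles) == 10
        assert any("P3" in r.message for r in caplog.records)

    def test_threshold_selection_mode(self):
        frame = planted_chr_frame(n=2000, seed=39)
        prof = EmotionProfiler(frame, seed=9, r_threshold=0.3).fit("N1")
        assert prof.selected[0] == "sadness"
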
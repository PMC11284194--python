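import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneumatch.errors import MatchingError, UnmatchableError
from aneumatch.matching import (
    FeatureSpec,
    Feature,
    StandardizedMatrix,
    encode_features,
    knn,
    resolve_conflicts,
    select_matching_features,
    sequential_match,
    stratify,
    weighted_distance,
    zscore_standardize,
)
from aneumatch.schema import ARM_AOI
from aneumatch.synthetic import CohortConfig, PlantedTwinSpec, generate_cohort, plant_twins

from conftest import make_matching_table


# ---------------------------------------------------------------------------
# encoding and standardization


def test_codebook_encoding(default_cohort):
    spec = select_matching_features(ruptured=False)
    mat, ids = encode_features(default_cohort, spec)
    assert mat.shape == (len(default_cohort), 4)
    gcol = spec.names.index("gender")
    assert set(mat[:, gcol]) <= {0.0, 1.0}
    expected = (default_cohort["gender"] == "female").astype(float).to_numpy()
    assert np.array_equal(mat[:, gcol], expected)


def test_ordinal_grades_pass_through_as_levels(default_cohort):
    ruptured = default_cohort[default_cohort["ruptured"] == 1]
    spec = select_matching_features(ruptured=True)
    mat, _ = encode_features(ruptured, spec)
    hh = spec.names.index("hunt_hess")
    assert np.array_equal(mat[:, hh], ruptured["hunt_hess"].astype(float).to_numpy())


def test_missing_feature_value_names_case_and_feature():
    table = make_matching_table([{"case_id": "A1", "age": None}, {"case_id": "A2"}])
    with pytest.raises(MatchingError, match=r"A1.*age"):
        encode_features(table, select_matching_features(ruptured=False))


def test_zscore_example_and_constant_flag():
    std = zscore_standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), ["a", "b", "c"], ["x", "const"])
    assert np.allclose(std.values[:, 0], [-1.0, 0.0, 1.0])  # sd with denominator n-1 is 1
    assert np.allclose(std.values[:, 1], 0.0)
    assert std.constant_columns == ["const"]


def test_zscore_rejects_single_row():
    with pytest.raises(MatchingError):
        zscore_standardize(np.array([[1.0, 2.0]]), ["a"], ["x", "y"])


@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
@settings(max_examples=100)
def test_zscore_columns_have_unit_scale(values):
    col = np.array(values)
    if np.std(col, ddof=0) < 1e-6:
        return
    std = zscore_standardize(col[:, None], [str(i) for i in range(len(col))], ["x"])
    assert abs(std.values[:, 0].mean()) < 1e-9
    assert abs(std.values[:, 0].std(ddof=1) - 1) < 1e-9


# ---------------------------------------------------------------------------
# distances


def test_weighted_distance_examples():
    assert weighted_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert weighted_distance([3.0, 4.0], [0.0, 0.0]) == pytest.approx(5.0)
    assert weighted_distance([1.0, 2.0], [0.0, 0.0], [4.0, 1.0]) == pytest.approx(np.sqrt(8))


def test_weighted_distance_validates_inputs():
    with pytest.raises(MatchingError):
        weighted_distance([1.0], [1.0, 2.0])
    with pytest.raises(MatchingError):
        weighted_distance([1.0, 2.0], [0.0, 0.0], [-1.0, 1.0])


@given(
    st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    st.lists(st.floats(-100, 100), min_size=3, max_size=3),
)
@settings(max_examples=200)
def test_metric_axioms_on_random_triples(x, y, z):
    x, y, z = np.array(x), np.array(y), np.array(z)
    dxy = weighted_distance(x, y)
    assert dxy >= 0
    assert dxy == pytest.approx(weighted_distance(y, x))
    if np.all(x == y):
        assert dxy == 0
    elif dxy == 0:  # only squared-difference underflow can give 0 for unequal vectors
        assert np.max(np.abs(x - y)) < 1e-150
    assert weighted_distance(x, z) <= dxy + weighted_distance(y, z) + 1e-9


# ---------------------------------------------------------------------------
# k-NN retrieval


def _pool_from(values: np.ndarray, prefix: str = "R") -> StandardizedMatrix:
    ids = [f"{prefix}{i + 1}" for i in range(len(values))]
    return StandardizedMatrix(
        ids=ids,
        names=["x"],
        values=np.asarray(values, dtype=float)[:, None],
        means=np.zeros(1),
        sds=np.ones(1),
    )


def test_inverse_distance_weights_match_hand_computation():
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    pool = _pool_from([1.0, 2.0, 4.0])
    ns = knn("A1", np.array([0.0]), pool, spec, variant="inverse_distance")
    assert np.allclose([w for _, _, w in ns.neighbors], [4 / 7, 2 / 7, 1 / 7])


def test_minmax_scaling_puts_all_weight_on_the_scaled_zero():
    # pool distances {2, 4, 6} min-max scale to {0, 0.5, 1}; inverse weighting
    # of a scaled-zero distance degenerates to weight 1 on the nearest case
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    ns = knn("A1", np.array([0.0]), _pool_from([2.0, 4.0, 6.0]), spec, variant="minmax_inverse")
    assert [w for _, _, w in ns.neighbors] == pytest.approx([1.0, 0.0, 0.0])


def test_equal_pool_distances_fall_back_to_equal_weights():
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    ns = knn("A1", np.array([0.0]), _pool_from([3.0, 3.0, 3.0]), spec, variant="minmax_inverse")
    assert [w for _, _, w in ns.neighbors] == pytest.approx([1 / 3] * 3)


def test_plain_knn_matches_brute_force_on_five_point_pool(rng):
    vals = rng.normal(size=5)
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    pool = _pool_from(vals)
    ns = knn("A1", np.array([0.2]), pool, spec, variant="plain")
    brute = sorted(pool.ids, key=lambda r: (abs(0.2 - vals[pool.ids.index(r)]), r))[:3]
    assert ns.reference_ids == brute
    assert [w for _, _, w in ns.neighbors] == pytest.approx([1 / 3] * 3)


def test_all_variants_retrieve_the_same_neighbor_set(rng):
    vals = rng.normal(size=20)
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    pool = _pool_from(vals)
    sets = {
        v: knn("A1", np.array([0.0]), pool, spec, variant=v).reference_ids
        for v in ("plain", "inverse_distance", "minmax_inverse")
    }
    assert sets["plain"] == sets["inverse_distance"] == sets["minmax_inverse"]


def test_weighted_variant_weights_sum_to_one_and_distances_sorted(rng):
    vals = rng.normal(size=30)
    spec = FeatureSpec((Feature("x", "continuous"),), k=3)
    for variant in ("plain", "inverse_distance", "minmax_inverse"):
        ns = knn("A1", np.array([0.4]), _pool_from(vals), spec, variant=variant)
        d = [dist for _, dist, _ in ns.neighbors]
        assert d == sorted(d)
        assert sum(w for _, _, w in ns.neighbors) == pytest.approx(1.0)


def test_scale_and_shift_of_raw_features_leave_distances_unchanged(rng):
    """Z-scoring makes the distance invariant to affine rescaling of any raw
    continuous feature."""
    raw = rng.normal(size=(12, 2)) * [5.0, 0.3] + [100.0, 2.0]
    ids = [f"C{i}" for i in range(12)]
    spec = FeatureSpec((Feature("a", "continuous"), Feature("b", "continuous")), k=3)
    std1 = zscore_standardize(raw, ids, ["a", "b"])
    scaled = raw.copy()
    scaled[:, 0] = scaled[:, 0] * 37.0 - 11.0
    std2 = zscore_standardize(scaled, ids, ["a", "b"])
    for i in range(3):
        for j in range(3, 6):
            d1 = weighted_distance(std1.values[i], std1.values[j], spec.weights)
            d2 = weighted_distance(std2.values[i], std2.values[j], spec.weights)
            assert d1 == pytest.approx(d2)


# ---------------------------------------------------------------------------
# feature selection and stratification


def test_matching_feature_sets_per_rupture_stratum():
    unrupt = select_matching_features(ruptured=False)
    rupt = select_matching_features(ruptured=True)
    assert unrupt.names == ["gender", "age", "shape", "size_mm"]
    assert rupt.names == ["gender", "age", "hunt_hess", "fisher_grade", "shape", "size_mm"]
    assert all(w == 1.0 for w in unrupt.weights) and all(w == 1.0 for w in rupt.weights)
    assert unrupt.k == rupt.k == 3


def test_stratify_groups_by_rupture_and_fda():
    aois = make_matching_table([{"case_id": "A1", "arm": ARM_AOI, "ruptured": 1, "hunt_hess": 2, "fisher_grade": 2, "fda_category": 2}])
    refs = make_matching_table(
        [
            {"case_id": "R1", "ruptured": 1, "hunt_hess": 1, "fisher_grade": 3, "fda_category": 2},
            {"case_id": "R2", "ruptured": 0, "fda_category": 2},
        ]
    )
    strata, merges = stratify(aois, refs)
    assert len(strata) == 1 and merges == []
    assert strata[0].reference_ids == ["R1"]  # the unruptured R2 is never a candidate


def test_fda_category_3_merges_into_4_when_empty():
    aois = make_matching_table([{"case_id": "A1", "arm": ARM_AOI, "fda_category": 3}])
    refs = make_matching_table(
        [{"case_id": "R1", "fda_category": 4}, {"case_id": "R2", "fda_category": 4}]
    )
    strata, merges = stratify(aois, refs)
    assert strata[0].categories == (3, 4) and strata[0].merged
    assert len(merges) == 1 and "merged with category 4" in merges[0]


def test_unmatchable_aoi_is_reported():
    aois = make_matching_table([{"case_id": "A1", "arm": ARM_AOI, "fda_category": 1}])
    refs = make_matching_table([{"case_id": "R1", "ruptured": 1, "hunt_hess": 1, "fisher_grade": 1, "fda_category": 1}])
    with pytest.raises(UnmatchableError, match="A1"):
        stratify(aois, refs)


# ---------------------------------------------------------------------------
# sequential assignment and conflicts


def test_adjudicator_prefers_smaller_distance_then_lower_id():
    assert resolve_conflicts("R1", [("A2", 0.9), ("A1", 0.5)]) == "A1"
    assert resolve_conflicts("R1", [("A2", 0.5), ("A1", 0.5)]) == "A1"
    with pytest.raises(MatchingError):
        resolve_conflicts("R1", [("A1", 0.5)])


def test_adjudication_minimizes_total_distance_for_two_claimants():
    """Brute-force check: giving the contested case to the closer claimant
    minimizes the summed matched distance over both feasible assignments."""
    d = {("A1", "R1"): 0.5, ("A2", "R1"): 0.9, ("A1", "R2"): 1.4, ("A2", "R2"): 1.0}
    winner = resolve_conflicts("R1", [("A1", d[("A1", "R1")]), ("A2", d[("A2", "R1")])])
    chosen = d[(winner, "R1")] + d[("A2" if winner == "A1" else "A1", "R2")]
    alternative = d[("A2", "R1")] + d[("A1", "R2")] if winner == "A1" else d[("A1", "R1")] + d[("A2", "R2")]
    assert chosen <= alternative


def test_shared_top_neighbor_is_logged_and_loser_falls_back():
    # ages place R1 nearest to both A1 (exact) and A2; A1 wins, A2 takes R2
    aois = make_matching_table(
        [
            {"case_id": "A1", "arm": ARM_AOI, "age": 40.0},
            {"case_id": "A2", "arm": ARM_AOI, "age": 42.0},
        ]
    )
    refs = make_matching_table(
        [
            {"case_id": "R1", "age": 40.0},
            {"case_id": "R2", "age": 50.0},
            {"case_id": "R3", "age": 70.0},
        ]
    )
    cohort = sequential_match(aois, refs)
    assert len(cohort.conflicts) == 1
    assert cohort.conflicts[0].reference_id == "R1"
    got = dict(zip(cohort.pairs["aoi_id"], cohort.pairs["reference_id"]))
    assert got == {"A1": "R1", "A2": "R2"}


def test_loser_skips_taken_second_neighbor_and_uses_third():
    # processing order A1, A2, A3: A1 takes R1, A2 takes R2; A3 then loses the
    # contest for R1 and its second neighbor R2 is taken, so it ends on R3
    aois = make_matching_table(
        [
            {"case_id": "A1", "arm": ARM_AOI, "age": 40.0},
            {"case_id": "A2", "arm": ARM_AOI, "age": 50.0},
            {"case_id": "A3", "arm": ARM_AOI, "age": 41.0},
        ]
    )
    refs = make_matching_table(
        [
            {"case_id": "R1", "age": 40.0},
            {"case_id": "R2", "age": 49.0},
            {"case_id": "R3", "age": 70.0},
        ]
    )
    cohort = sequential_match(aois, refs)
    got = dict(zip(cohort.pairs["aoi_id"], cohort.pairs["reference_id"]))
    assert got == {"A1": "R1", "A2": "R2", "A3": "R3"}
    assert len(cohort.conflicts) == 1
    assert "A3 falls back to R3" in cohort.conflicts[0].resolution


def test_claimant_exhausting_k_neighbors_is_an_error():
    aois = make_matching_table(
        [
            {"case_id": "A1", "arm": ARM_AOI, "age": 40.0},
            {"case_id": "A2", "arm": ARM_AOI, "age": 40.0},
        ]
    )
    refs = make_matching_table([{"case_id": "R1", "age": 40.0}])
    with pytest.raises(UnmatchableError):
        sequential_match(aois, refs)


def test_zero_noise_twins_are_recovered_without_conflicts():
    aois = generate_cohort(CohortConfig(seed=21)).query("arm == @ARM_AOI")
    refs, twin_map = plant_twins(aois, PlantedTwinSpec(noise_scale=0.0, flip_prob=0.0, n_decoys=2, seed=1))
    cohort = sequential_match(aois, refs)
    got = dict(zip(cohort.pairs["aoi_id"], cohort.pairs["reference_id"]))
    expected = dict(zip(twin_map["aoi_id"], twin_map["twin_id"]))
    assert got == expected
    assert cohort.conflicts == []
    assert cohort.pairs["distance"].max() == pytest.approx(0.0)


def test_null_matched_cohorts_stay_balanced_on_matching_covariates():
    """On null cohorts the baseline comparison flags matching covariates at no
    more than the nominal alpha rate (matching can only tighten balance)."""
    from aneumatch.compare import BASELINE_VARIABLES, baseline_table
    from aneumatch.pipeline import matched_case_table

    matching_vars = {v.name for v in BASELINE_VARIABLES if v.role == "matching covariate"}
    seeds = np.random.SeedSequence(77).generate_state(40) % (2**31)
    flags = []
    for s in seeds:
        cases = generate_cohort(CohortConfig(seed=int(s)).with_null_outcomes())
        cohort = sequential_match(cases.query("arm == @ARM_AOI"), cases.query("arm != @ARM_AOI"))
        table = baseline_table(matched_case_table(cases, cohort))
        for _, row in table.iterrows():
            if row["variable"] in matching_vars and row["p_value"] != "—":
                flags.append(int(float(row["p_value"]) < 0.05))
    rate = np.mean(flags)
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(flags))


def test_matched_pairs_share_rupture_status_and_fda_stratum():
    cases = generate_cohort(CohortConfig(seed=33))
    aois = cases.query("arm == @ARM_AOI")
    refs = cases.query("arm != @ARM_AOI")
    cohort = sequential_match(aois, refs)
    by_id = cases.set_index("case_id")
    merged_strata = {s for s in cohort.pairs["stratum"] if "merged" in s}
    for _, row in cohort.pairs.iterrows():
        a, r = by_id.loc[row["aoi_id"]], by_id.loc[row["reference_id"]]
        assert a["ruptured"] == r["ruptured"]
        if row["stratum"] not in merged_strata:
            assert a["fda_category"] == r["fda_category"]
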
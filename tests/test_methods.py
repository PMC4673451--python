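import pytest

from exomesift.errors import ValidationError
from exomesift.filters import FilterThresholds
from exomesift.methods import (
    MethodResult,
    control_union,
    genotype_concordance,
    intersect_cases,
    run_method_a,
    run_method_b,
    run_method_c,
)
from exomesift.model import CohortStudy, VariantKey

from conftest import make_call, make_callset


def key(pos, chrom="1"):
    return VariantKey(chrom, pos, "A", "G")


def cohort_from_keys(case_map, control_map, bad_in=()):
    """Build a cohort where every call passes the filter except the
    (sample_id, pos) pairs listed in bad_in (DP forced under threshold)."""

    def build(sample_id, group, positions):
        calls = [
            make_call(pos=p, DP=(5 if (sample_id, p) in bad_in else 50))
            for p in positions
        ]
        return make_callset(sample_id, group, "M", calls)

    cases = [build(sid, "case", ps) for sid, ps in case_map.items()]
    controls = [build(sid, "control", ps) for sid, ps in control_map.items()]
    return CohortStudy(cases=cases, controls=controls)


class TestMethodA:
    def test_per_sample_filtered_catalogs(self, toy_cohort):
        result = run_method_a(toy_cohort)
        assert result.method == "A"
        assert {sid: len(k) for sid, k in result.per_sample.items()} == {"A1": 3, "C1": 2}
        assert result.common == set()

    def test_all_failing_calls_yield_empty_sets(self):
        cohort = cohort_from_keys(
            {"A1": [1, 2]}, {"C1": [3]},
            bad_in={("A1", 1), ("A1", 2), ("C1", 3)},
        )
        result = run_method_a(cohort)
        assert all(not keys for keys in result.per_sample.values())

    def test_includes_controls_without_comparison(self):
        cohort = cohort_from_keys({"A1": [1, 2]}, {"C1": [1]})
        result = run_method_a(cohort)
        # the shared key 1 stays in both catalogs: A never subtracts
        assert key(1) in result.per_sample["A1"]
        assert key(1) in result.per_sample["C1"]


class TestControlUnion:
    def test_raw_union(self):
        cohort = cohort_from_keys({"A1": []}, {"C1": [1, 2], "C2": [2, 3]})
        assert control_union(cohort, "raw") == {key(1), key(2), key(3)}

    def test_filtered_union_drops_failing_calls(self):
        cohort = cohort_from_keys(
            {"A1": []}, {"C1": [1, 2], "C2": [2, 3]},
            bad_in={("C1", 2), ("C2", 2)},
        )
        assert control_union(cohort, "filtered") == {key(1), key(3)}
        # raw level still sees the failing call
        assert control_union(cohort, "raw") == {key(1), key(2), key(3)}

    def test_empty_control_contributes_nothing(self):
        cohort = cohort_from_keys({"A1": []}, {"C1": [1], "C2": []})
        assert control_union(cohort, "raw") == {key(1)}

    def test_bad_level_rejected(self, toy_cohort):
        with pytest.raises(ValidationError):
            control_union(toy_cohort, "half-filtered")


class TestMethodB:
    def test_subtracts_filtered_control_union(self):
        cohort = cohort_from_keys({"A1": [1, 2, 3]}, {"C1": [3, 4]})
        result = run_method_b(cohort)
        assert result.per_sample["A1"] == {key(1), key(2)}

    def test_control_only_failure_leaks_through(self):
        # k3 fails the filter in the control but passes in the case: the
        # filtered control union no longer contains it, so B wrongly keeps it
        cohort = cohort_from_keys({"A1": [1, 2, 3]}, {"C1": [3, 4]}, bad_in={("C1", 3)})
        result = run_method_b(cohort)
        assert key(3) in result.per_sample["A1"]

    def test_disjoint_controls_leave_cases_untouched(self):
        cohort = cohort_from_keys({"A1": [1, 2]}, {"C1": [5, 6]})
        assert run_method_b(cohort).per_sample["A1"] == {key(1), key(2)}

    def test_common_is_cross_case_intersection(self):
        cohort = cohort_from_keys({"A1": [1, 2], "A2": [2, 3]}, {"C1": [9]})
        result = run_method_b(cohort)
        assert result.common == {key(2)} == intersect_cases(result)


class TestMethodC:
    def test_raw_subtraction_removes_control_only_failure(self):
        # same cohort as the leak-through case above: C subtracts at raw level
        cohort = cohort_from_keys({"A1": [1, 2, 3]}, {"C1": [3, 4]}, bad_in={("C1", 3)})
        result = run_method_c(cohort)
        assert key(3) not in result.per_sample["A1"]
        assert result.per_sample["A1"] == {key(1), key(2)}

    def test_case_side_filter_still_applies(self):
        cohort = cohort_from_keys({"A1": [1, 2]}, {"C1": [9]}, bad_in={("A1", 2)})
        assert run_method_c(cohort).per_sample["A1"] == {key(1)}

    def test_empty_case_callset_gives_empty_result(self):
        cohort = cohort_from_keys({"A1": [], "A2": [1]}, {"C1": [9]})
        result = run_method_c(cohort)
        assert result.per_sample["A1"] == set()
        assert result.common == set()

    def test_order_independence_over_sample_ordering(self):
        case_map = {"A1": [1, 2, 3], "A2": [2, 3, 4]}
        control_map = {"C1": [4, 5], "C2": [5, 6]}
        fwd = run_method_c(cohort_from_keys(case_map, control_map))
        rev_cohort = cohort_from_keys(
            dict(reversed(case_map.items())), dict(reversed(control_map.items()))
        )
        rev = run_method_c(rev_cohort)
        assert fwd.per_sample == rev.per_sample
        assert fwd.common == rev.common


class TestIntersectCases:
    def test_examples(self):
        per_sample = {"A1": {key(1), key(2)}, "A2": {key(2)}, "A3": {key(2), key(3)}}
        result = MethodResult("B", per_sample, common={key(2)})
        assert intersect_cases(result) == {key(2)}

    def test_any_empty_per_sample_empties_intersection(self):
        result = MethodResult("C", {"A1": {key(1)}, "A2": set()}, common=set())
        assert intersect_cases(result) == set()

    def test_identical_sets_intersect_to_themselves(self):
        s = {key(1), key(2)}
        result = MethodResult("B", {"A1": set(s), "A2": set(s)}, common=set(s))
        assert intersect_cases(result) == s

    def test_method_a_rejected(self):
        with pytest.raises(ValidationError):
            intersect_cases(MethodResult("A", {"A1": set()}, common=set()))


class TestGenotypeConcordance:
    def brain_blood(self, n_discordant=0, n=4):
        brain, blood = [], []
        for i in range(n):
            gt = ("A", "G")
            brain.append(make_call(pos=i + 1, genotype=gt))
            other = ("G", "G") if i < n_discordant else gt
            blood.append(make_call(pos=i + 1, genotype=other))
        return (
            make_callset("brain", "case", "M", brain),
            make_callset("blood", "case", "M", blood),
        )

    def test_identical_callsets_fully_concordant(self):
        a, b = self.brain_blood(n_discordant=0, n=10)
        frac, table = genotype_concordance(a, b, a.keys())
        assert frac == 1.0
        assert all(row["concordant"] for row in table)

    def test_one_of_four_discordant(self):
        a, b = self.brain_blood(n_discordant=1, n=4)
        frac, table = genotype_concordance(a, b, a.keys())
        assert frac == 0.75
        assert sum(not r["concordant"] for r in table) == 1

    def test_empty_key_set_rejected(self):
        a, b = self.brain_blood()
        with pytest.raises(ValidationError):
            genotype_concordance(a, b, set())

    def test_absent_key_named_in_error(self):
        a, b = self.brain_blood()
        missing = key(999)
        with pytest.raises(ValidationError, match="999"):
            genotype_concordance(a, b, {missing})


def random_cohort(rng, max_cases=3, max_controls=3, universe=30, fail_prob=0.3):
    """A small random cohort over a shared key universe with random
    per-sample quality failures, built without the simulator."""
    case_map, control_map, bad = {}, {}, set()
    n_cases = int(rng.integers(1, max_cases + 1))
    n_controls = int(rng.integers(1, max_controls + 1))
    for i in range(n_cases):
        sid = f"A{i + 1}"
        case_map[sid] = [int(p) for p in rng.choice(universe, size=rng.integers(0, 15), replace=False) + 1]
    for i in range(n_controls):
        sid = f"C{i + 1}"
        control_map[sid] = [int(p) for p in rng.choice(universe, size=rng.integers(0, 15), replace=False) + 1]
    for sid, ps in {**case_map, **control_map}.items():
        for p in ps:
            if rng.random() < fail_prob:
                bad.add((sid, p))
    return cohort_from_keys(case_map, control_map, bad_in=bad)


class TestRandomCohortProperties:
    def test_containment_disjointness_and_b_minus_c(self, rng):
        """Method C stays inside method B; both stay disjoint from their
        control unions; B-minus-C is exactly the keys present in some raw
        control callset but in no filtered one (brute-force audit)."""
        for _ in range(150):
            cohort = random_cohort(rng)
            b = run_method_b(cohort)
            c = run_method_c(cohort)
            raw_union = control_union(cohort, "raw")
            filt_union = control_union(cohort, "filtered")
            leak = raw_union - filt_union  # raw-only control keys
            for sid in b.per_sample:
                assert c.per_sample[sid] <= b.per_sample[sid]
                assert not (b.per_sample[sid] & filt_union)
                assert not (c.per_sample[sid] & raw_union)
                assert b.per_sample[sid] - c.per_sample[sid] == b.per_sample[sid] & leak
            assert c.common <= b.common
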
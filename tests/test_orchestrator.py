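import numpy as np
import pytest

from p4anon.core import (
    AttributeConfig,
    Dataset,
    ReferenceStats,
    build_hierarchy,
    group_into_classes,
    reference_stats,
)
from p4anon.models import PrivacyModel, check_class
from p4anon.orchestrator import (
    STAGES,
    compliance_check,
    harmonize_schemes,
    lexicographic_partition,
    reapply_harmonized,
    run_p4,
)
from p4anon.synthetic import generate_dataset
from p4anon.transform import AnonymizationResult, apply_scheme, search_optimal
from p4anon.utility import dataset_fidelity
from p4anon.verify import check_output


class TestLexicographicPartition:
    def test_balanced_sizes(self):
        d = generate_dataset(10, (4,), seed=0)
        parts = lexicographic_partition(d, 3)
        assert [p.dataset.n for p in parts] == [4, 3, 3]
        ids = [i for p in parts for i in p.dataset.df.index]
        assert sorted(ids) == sorted(d.df.index)

    def test_sorted_by_qi_tuple(self):
        h = build_hierarchy([("a", "*"), ("b", "*")])
        h2 = build_hierarchy([("1", "*"), ("2", "*")])
        attrs = [
            AttributeConfig("x", "quasi_identifier"),
            AttributeConfig("y", "quasi_identifier"),
        ]
        d = Dataset.from_records(
            [("b", "1"), ("a", "2"), ("a", "1")], attrs, {"x": h, "y": h2}
        )
        parts = lexicographic_partition(d, 1)
        tuples = list(
            parts[0].dataset.df.itertuples(index=False, name=None)
        )
        assert tuples == [("a", "1"), ("a", "2"), ("b", "1")]

    def test_single_partition_is_sorted_dataset(self):
        d = generate_dataset(20, (4, 5), seed=1)
        parts = lexicographic_partition(d, 1)
        assert parts[0].dataset.n == 20

    def test_invalid_partition_count(self):
        d = generate_dataset(5, (4,), seed=0)
        with pytest.raises(ValueError):
            lexicographic_partition(d, 0)


class TestHarmonize:
    @pytest.mark.parametrize(
        "schemes, strategy, expected",
        [
            ([(1,), (2,), (2,)], "average", (2,)),  # 5/3 rounds half-up to 2
            ([(1,), (2,), (2,)], "minimum", (1,)),
            ([(1,), (2,), (2,)], "median", (2,)),
            ([(0,), (0,), (0,)], "average", (0,)),
            ([(1,), (2,)], "median", (1,)),  # lower median
            ([(0, 3), (1, 1)], "average", (1, 2)),  # 0.5 and 2.0 round half-up
        ],
    )
    def test_strategies(self, schemes, strategy, expected):
        assert harmonize_schemes(schemes, strategy) == expected

    def test_result_within_min_max_envelope(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            w = int(rng.integers(1, 4))
            schemes = [
                tuple(int(x) for x in rng.integers(0, 5, size=w))
                for _ in range(int(rng.integers(1, 6)))
            ]
            for strat in ("average", "minimum", "median"):
                out = harmonize_schemes(schemes, strat)
                for i in range(w):
                    levels = [s[i] for s in schemes]
                    assert min(levels) <= out[i] <= max(levels)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            harmonize_schemes([], "average")


class TestReapplyHarmonized:
    def test_partitions_already_at_scheme_untouched(self):
        d = generate_dataset(40, (4, 5), seed=2)
        parts = lexicographic_partition(d, 2)
        models = [PrivacyModel("k_anonymity", k=2)]
        from p4anon.orchestrator import anonymize_partitions

        anonymize_partitions(parts, models)
        schemes = [p.result.chosen_scheme for p in parts]
        before = [p.result.output.df.copy() for p in parts]
        if schemes[0] == schemes[1]:
            reapply_harmonized(parts, schemes[0], models)
            for b, p in zip(before, parts):
                assert p.result.output.df.equals(b)

    def test_forced_finer_scheme_suppresses_failing_classes(self):
        # partition needs level 1 for k=2 but is forced to level 0:
        # its singletons must be suppressed even though the limit is 0
        h = build_hierarchy(
            [
                ("30", "30-31", "*"),
                ("31", "30-31", "*"),
                ("32", "32-33", "*"),
                ("33", "32-33", "*"),
            ]
        )
        attrs = [
            AttributeConfig("age", "quasi_identifier"),
            AttributeConfig("sex", "sensitive"),
        ]
        d = Dataset.from_records(
            [("30", "F"), ("31", "M"), ("32", "F"), ("32", "M")],
            attrs,
            {"age": h},
        )
        from p4anon.orchestrator import Partition

        part = Partition(0, d)
        part.result = search_optimal(d, [PrivacyModel("k_anonymity", k=2)])
        assert part.result.chosen_scheme == (1,)
        reapply_harmonized([part], (0,), [PrivacyModel("k_anonymity", k=2)])
        assert part.result.chosen_scheme == (0,)
        # "30" and "31" are singletons at level 0
        assert len(part.result.suppressed_row_ids) == 2

    def test_top_scheme_passes_everything(self):
        d = generate_dataset(10, (4,), seed=3)
        from p4anon.orchestrator import Partition

        part = Partition(0, d)
        reapply_harmonized([part], (2,), [PrivacyModel("k_anonymity", k=5)])
        assert not part.result.suppressed_row_ids
        assert (part.result.output.df["qi1"] == "*").all()


def two_partition_tcloseness_case():
    """Two partitions whose shared class passes locally but fails on merge.

    Partition A holds class 'a' with sensitive counts (4 F, 1 M) and local
    reference (0.8, 0.2); partition B holds class 'a' with (5 F, 0 M) and
    local reference (1.0, 0.0).  Each passes equal-distance t-closeness at
    t=0.2 locally (EMD 0).  Merged, class 'a' has counts (9, 1) against a
    global reference of (0.5, 0.5): EMD 0.4 > 0.2, so compliance must
    suppress it.
    """
    h = build_hierarchy([("a", "*"), ("b", "*")])
    attrs = [
        AttributeConfig("zip", "quasi_identifier"),
        AttributeConfig("diag", "sensitive"),
    ]
    rec_a = [("a", "F")] * 4 + [("a", "M")]
    rec_b = [("a", "F")] * 5
    da = Dataset.from_records(rec_a, attrs, {"zip": h})
    db_df = Dataset.from_records(rec_b, attrs, {"zip": h}).df
    db_df.index = range(5, 10)  # keep row ids globally unique
    db = Dataset(db_df, attrs, {"zip": h})
    model = PrivacyModel("t_closeness_equal", t=0.2, sensitive="diag")
    results = []
    for d in (da, db):
        out = apply_scheme(d, (0,))
        results.append(
            AnonymizationResult(
                output=out,
                chosen_scheme=(0,),
                suppressed_row_ids=frozenset(),
                fidelity=dataset_fidelity(out).mean_fidelity,
                classes=group_into_classes(d, (0,)),
            )
        )
    global_ref = ReferenceStats(20, {"diag": {"F": 0.5, "M": 0.5}})
    return da, db, model, results, global_ref


class TestComplianceCheck:
    def test_monotonic_only_configuration_is_noop(self):
        d = generate_dataset(30, (4,), seed=4)
        res = search_optimal(d, [PrivacyModel("k_anonymity", k=2)])
        out = compliance_check(
            [res], [PrivacyModel("k_anonymity", k=2)], reference_stats(d)
        )
        assert out == {}

    def test_merged_class_failing_globally_is_suppressed(self):
        da, db, model, results, global_ref = two_partition_tcloseness_case()
        # each partition passes locally against its own reference
        for d, res in zip((da, db), results):
            local_ref = reference_stats(d, scope="partition")
            assert all(
                check_class(model, c, local_ref) for c in res.classes
            )
        removed = compliance_check(results, [model], global_ref)
        assert ("a",) in removed
        assert len(removed[("a",)]) == 10
        for res in results:
            assert (res.output.df["zip"] == "*").all()

    def test_classes_matching_global_reference_survive(self):
        h = build_hierarchy([("a", "*")])
        attrs = [
            AttributeConfig("zip", "quasi_identifier"),
            AttributeConfig("diag", "sensitive"),
        ]
        model = PrivacyModel("t_closeness_equal", t=0.2, sensitive="diag")
        results = []
        for lo in (0, 4):
            d = Dataset.from_records(
                [("a", "F"), ("a", "F"), ("a", "M"), ("a", "M")],
                attrs,
                {"zip": h},
            )
            df = d.df
            df.index = range(lo, lo + 4)
            d = Dataset(df, attrs, {"zip": h})
            out = apply_scheme(d, (0,))
            results.append(
                AnonymizationResult(
                    output=out,
                    chosen_scheme=(0,),
                    suppressed_row_ids=frozenset(),
                    fidelity=1.0,
                    classes=group_into_classes(d, (0,)),
                )
            )
        ref = ReferenceStats(8, {"diag": {"F": 0.5, "M": 0.5}})
        assert compliance_check(results, [model], ref) == {}


class TestRunP4:
    def test_single_partition_equals_direct_anonymizer(self):
        d = generate_dataset(80, (4, 6), sensitive_domain=3, seed=5)
        models = [PrivacyModel("k_anonymity", k=3)]
        out, rep = run_p4(d, models, 1)
        direct = search_optimal(
            lexicographic_partition(d, 1)[0].dataset, models
        )
        assert out.df.equals(direct.output.df)
        assert rep.fidelity == pytest.approx(direct.fidelity)

    def test_k4_output_indistinguishability(self):
        # every kept record shares its QI tuple with at least 3 others
        d = generate_dataset(200, (4, 5), seed=6)
        out, _ = run_p4(d, [PrivacyModel("k_anonymity", k=4)], 4)
        qi = d.qi_names
        kept = out.df[~(out.df[qi] == "*").all(axis=1)]
        if len(kept):
            sizes = kept.groupby(qi).size()
            assert (sizes >= 4).all()

    def test_local_mode_skips_harmonization(self):
        d = generate_dataset(60, (4, 5), seed=7)
        _, rep = run_p4(
            d, [PrivacyModel("k_anonymity", k=2)], 2, transformation="local"
        )
        assert rep.step_durations["harmonization"] == 0.0
        assert rep.step_durations["compliance"] == 0.0
        assert rep.harmonized_scheme is None

    def test_report_contains_all_four_stages(self):
        d = generate_dataset(40, (4,), seed=8)
        _, rep = run_p4(d, [PrivacyModel("k_anonymity", k=2)], 2)
        assert set(rep.step_durations) == set(STAGES)
        assert all(v >= 0 for v in rep.step_durations.values())
        assert set(rep.suppressed_counts) == set(STAGES)

    def test_merged_output_row_count_and_order_restoration(self):
        d = generate_dataset(50, (4, 5), seed=9)
        out, _ = run_p4(
            d, [PrivacyModel("k_anonymity", k=2)], 4, restore_order=True
        )
        assert out.n == d.n
        assert list(out.df.index) == list(d.df.index)

    def test_harmonized_scheme_within_partition_envelope(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            d = generate_dataset(
                int(rng.integers(60, 200)),
                (5, 6),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _, rep = run_p4(d, [PrivacyModel("k_anonymity", k=4)], 4)
            schemes = rep.per_partition_schemes
            for i in range(len(rep.harmonized_scheme)):
                levels = [s[i] for s in schemes]
                assert min(levels) <= rep.harmonized_scheme[i] <= max(levels)

    def test_nonmonotonic_end_to_end_guarantee(self):
        d = generate_dataset(300, (4, 6), sensitive_domain=2, skew=0.8, seed=11)
        models = [
            PrivacyModel("k_anonymity", k=3),
            PrivacyModel("t_closeness_equal", t=0.25, sensitive="sensitive"),
        ]
        out, _ = run_p4(d, models, 4)
        rep = check_output(out.df, d.qi_names, models)
        assert rep.passed, rep.failures

    def test_workers_do_not_change_results(self):
        d = generate_dataset(120, (4, 5), sensitive_domain=2, seed=12)
        models = [
            PrivacyModel("k_anonymity", k=2),
            PrivacyModel("delta_disclosure", delta=2.0, sensitive="sensitive"),
        ]
        out1, rep1 = run_p4(d, models, 4, workers=1)
        out4, rep4 = run_p4(d, models, 4, workers=4)
        assert out1.df.equals(out4.df)
        d1, d4 = rep1.to_dict(), rep4.to_dict()
        d1.pop("step_durations")
        d4.pop("step_durations")
        assert d1 == d4
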
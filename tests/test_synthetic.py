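import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from completelink import (
    GeneratorSpec,
    classify_clusters,
    corrupt_one_edit,
    find_exact_clusters,
    generate_base,
    generate_type1,
    generate_type2,
    generate_type3,
    link,
    simulation_config,
    truth_from_datasets,
    worked_example_fixture,
)

from conftest import dp_levenshtein


def values_of(datasets):
    return [[r.values for r in ds.records] for ds in datasets]


class TestGenerateBase:
    def test_deterministic_under_seed(self):
        assert values_of([generate_base(50, 1)]) == values_of([generate_base(50, 1)])

    def test_seeds_differ(self):
        assert values_of([generate_base(50, 1)]) != values_of([generate_base(50, 2)])

    def test_ssn_unique(self):
        base = generate_base(500, 3)
        ssns = [r.values["ssn"] for r in base.records]
        assert len(set(ssns)) == 500
        assert all(len(s) == 9 and s.isdigit() for s in ssns)

    def test_pairwise_last_name_separation(self):
        # distinct individuals stay beyond twice the default threshold (2)
        base = generate_base(300, 4)
        names = [r.values["last_name"] for r in base.records]
        for a, b in itertools.combinations(names, 2):
            assert dp_levenshtein(a, b) > 4

    def test_capacity_error_suggests_larger_pool(self):
        with pytest.raises(ValueError, match="increase code_digits"):
            generate_base(626, 0, code_digits=4)  # 5**4 = 625 < 626


class TestCorruptOneEdit:
    @given(st.text(alphabet="ABCDE", min_size=1, max_size=12),
           st.integers(0, 1000))
    def test_single_edit_distance(self, value, seed):
        rng = np.random.default_rng(seed)
        out = corrupt_one_edit(value, rng)
        assert out != value
        assert dp_levenshtein(value, out) == 1

    def test_reproducible_under_seed(self):
        a = corrupt_one_edit("GLENN", np.random.default_rng(9))
        b = corrupt_one_edit("GLENN", np.random.default_rng(9))
        assert a == b

    def test_operation_mix_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ops = Counter()
        for _ in range(3000):
            out = corrupt_one_edit("ABCDEF", rng)
            if len(out) > 6:
                ops["ins"] += 1
            elif len(out) < 6:
                ops["del"] += 1
            else:
                ops["sub"] += 1
        for count in ops.values():
            assert 850 <= count <= 1150  # ~±5 sigma around 1000


class TestType1:
    def test_layout_and_corruption_rate(self):
        spec = GeneratorSpec(n_individuals=100, copies=10,
                             error_probability=0.15, seed=7)
        datasets = generate_type1(spec)
        assert len(datasets) == 10
        assert sum(len(ds) for ds in datasets) == 1000
        base = generate_base(100, 7)
        originals = [r.values["last_name"] for r in base.records]
        corrupted = sum(
            ds.records[i].values["last_name"] != originals[i]
            for ds in datasets
            for i in range(100)
        )
        # binomial(1000, 0.15): mean 150, sigma 11.3; +-4 sigma bounds
        assert 105 <= corrupted <= 196

    def test_zero_probability_copies_identical(self):
        spec = GeneratorSpec(n_individuals=20, copies=3,
                             error_probability=0.0, seed=1)
        datasets = generate_type1(spec)
        base = generate_base(20, 1)
        for ds in datasets:
            assert [r.values for r in ds.records] == [
                {**r.values} for r in base.records
            ]

    def test_certain_corruption_every_record_one_edit(self):
        spec = GeneratorSpec(n_individuals=20, copies=2,
                             error_probability=1.0, seed=2)
        datasets = generate_type1(spec)
        base = generate_base(20, 2)
        for ds in datasets:
            for i, rec in enumerate(ds.records):
                assert dp_levenshtein(
                    rec.values["last_name"], base.records[i].values["last_name"]
                ) == 1

    def test_truth_preserved_in_ssn(self):
        spec = GeneratorSpec(n_individuals=10, copies=2, seed=3)
        datasets = generate_type1(spec)
        truth = truth_from_datasets(datasets, "ssn")
        assert len(set(truth.values())) == 10


class TestType2:
    def test_mixture_plan(self):
        spec = GeneratorSpec(n_individuals=25, seed=5)
        datasets = generate_type2(spec)
        assert len(datasets) == 10
        base = generate_base(25, 5)
        base_values = [r.values for r in base.records]
        clean = [ds for ds in datasets
                 if [r.values for r in ds.records] == base_values]
        assert len(clean) == 4
        # the two corrupted variants appear three times each
        variants = {}
        for ds in datasets:
            key = tuple(r.values["last_name"] for r in ds.records)
            variants.setdefault(key, []).append(ds.dataset_id)
        counts = sorted(len(v) for v in variants.values())
        assert counts == [3, 3, 4]

    def test_every_corrupted_record_differs(self):
        spec = GeneratorSpec(n_individuals=25, seed=5)
        datasets = generate_type2(spec)
        base = generate_base(25, 5)
        corrupted = datasets[4:]
        for ds in corrupted:
            for i, rec in enumerate(ds.records):
                assert (
                    rec.values["last_name"]
                    != base.records[i].values["last_name"]
                )

    def test_deterministic(self):
        spec = GeneratorSpec(n_individuals=10, seed=8)
        assert values_of(generate_type2(spec)) == values_of(generate_type2(spec))


class TestType3:
    def test_schemas_pairwise_distinct_and_cloned(self):
        spec = GeneratorSpec(n_individuals=15, seed=6)
        datasets = generate_type3(spec)
        assert len(datasets) == 6
        schemas = {tuple(ds.attributes) for ds in datasets}
        assert len(schemas) == 3
        for v in range(3):
            original = datasets[2 * v]
            clone = datasets[2 * v + 1]
            assert [r.values for r in original.records] == [
                r.values for r in clone.records
            ]

    def test_exact_phase_collapses_clones(self):
        spec = GeneratorSpec(n_individuals=15, seed=6)
        datasets = generate_type3(spec)
        exact = find_exact_clusters(datasets)
        members = exact.members_of_representative()
        for v in range(3):
            ds_id = datasets[2 * v].dataset_id
            clone_id = datasets[2 * v + 1].dataset_id
            for i in range(15):
                cluster = next(
                    c for c in exact.clusters if (ds_id, i) in c
                )
                assert (clone_id, i) in cluster
        assert all(len(c) % 2 == 0 for c in exact.clusters)
        assert len(exact) <= 45
        assert sum(len(m) for m in members.values()) == 90

    def test_bad_drop_plan_warns(self):
        spec = GeneratorSpec(
            n_individuals=5,
            seed=1,
            attribute_drop_plan=[
                ["first_name", "last_name"],
                ["first_name", "ssn"],
            ],
        )
        with pytest.warns(UserWarning, match="comparison-critical"):
            generate_type3(spec)


class TestWorkedExampleFixture:
    def test_five_records_two_datasets(self):
        datasets, config = worked_example_fixture()
        assert [ds.dataset_id for ds in datasets] == ["A", "B"]
        assert [len(ds) for ds in datasets] == [3, 2]
        assert config.threshold == 1
        assert config.priority_attributes == ["dob"]

    def test_end_to_end_counts(self):
        datasets, config = worked_example_fixture()
        final, counts = link(datasets, config)
        assert counts.n_exact_clusters == 4
        assert counts.n_components == 2
        assert len(final) == 3


class TestRecoverability:
    def test_type1_pipeline_recovers_ground_truth(self):
        """Errors are confined to one last-name edit, so at threshold 2 every
        individual's records stay within distance 2 of one another while
        distinct individuals stay beyond it: the pipeline should recover the
        planted partition essentially perfectly."""
        spec = GeneratorSpec(n_individuals=300, copies=10,
                             error_probability=0.15, seed=13)
        datasets = generate_type1(spec)
        final, _ = link(datasets, simulation_config(threshold=2))
        truth = truth_from_datasets(datasets, "ssn")
        report = classify_clusters(final, truth)
        assert report.type_percentages["I"] > 99.0
        assert report.accuracy > 0.999
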
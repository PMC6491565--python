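"""Cohort data model: label transformations, correlation, splitting, I/O."""

import itertools

import numpy as np
import pytest

from groupnet import (
    CohortTable,
    br_views,
    lp_decode,
    lp_encode,
    pmcc_matrix,
    read_cohort_csv,
    split_cohort,
    standardize,
    write_cohort_csv,
)
from groupnet.cohort import LP_PATTERNS, Scaler, feature_names
from groupnet.exceptions import SchemaError, ValidationError


class TestLabelPowerset:
    def test_fixed_combination_order(self):
        # the class code follows the combination order 000, 100, 010, 001, ...
        assert lp_encode([[0, 0, 0]])[0] == 0
        assert lp_encode([[1, 1, 1]])[0] == 7
        assert tuple(lp_decode([4])[0]) == (1, 1, 0)
        assert tuple(lp_decode([0])[0]) == (0, 0, 0)

    def test_bijection_over_all_triples(self):
        triples = np.array(list(itertools.product((0, 1), repeat=3)))
        codes = lp_encode(triples)
        assert sorted(codes.tolist()) == list(range(8))
        assert np.array_equal(lp_decode(codes), triples)

    def test_roundtrip_random_triples(self, rng):
        x = rng.integers(0, 2, size=(1000, 3))
        assert np.array_equal(lp_decode(lp_encode(x)), x)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValidationError):
            lp_encode([[0, 2, 0]])
        with pytest.raises(ValidationError):
            lp_decode([8])
        with pytest.raises(ValidationError):
            lp_decode([-1])

    def test_patterns_table_consistent(self):
        for code, pattern in enumerate(LP_PATTERNS):
            assert lp_encode([list(pattern)])[0] == code


class TestBinaryRelevance:
    def test_column_projection(self):
        cohort = CohortTable(features=np.zeros((1, 62)), labels=[[1, 0, 1]])
        views = br_views(cohort)
        assert [v.labels[0] for v in views] == [1, 0, 1]
        assert [v.disease for v in views] == ["H", "D", "FL"]

    def test_recombination_and_independence(self, small_cohort):
        views = br_views(small_cohort)
        recombined = np.column_stack([v.labels for v in views])
        assert np.array_equal(recombined, small_cohort.labels)
        for j, v in enumerate(views):
            assert v.labels.mean() == small_cohort.labels[:, j].mean()
        views[0].labels[:] = 0  # shuffling/mutating a view must not leak back
        assert small_cohort.labels[:, 0].any()


class TestPmcc:
    def test_definition_cases(self):
        x = np.array([1, 1, 0, 0, 1, 0, 1])
        labels = np.column_stack([x, x, 1 - x])
        m = pmcc_matrix(labels)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_independent_pair_phi_zero(self):
        # 2x2 table with all four cells equal: phi = 0 by hand computation
        labels = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert pmcc_matrix(labels)[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_pearson(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, size=(50, 3))
            if (labels.std(axis=0) == 0).any():
                continue
            m = pmcc_matrix(labels)
            for i in range(3):
                for j in range(3):
                    a = labels[:, i] - labels[:, i].mean()
                    b = labels[:, j] - labels[:, j].mean()
                    expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
                    assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_error_names_label(self):
        labels = np.column_stack([np.ones(10), np.arange(10) % 2, np.arange(10) % 2])
        with pytest.raises(ValidationError, match="'H'"):
            pmcc_matrix(labels)


class TestSplit:
    def test_total_train_count(self):
        labels = np.tile(np.array(LP_PATTERNS), (13, 1))[:100]
        cohort = CohortTable(features=np.zeros((100, 62)), labels=labels)
        split = split_cohort(cohort, 0.7, seed=1)
        assert len(split.train_rows) + len(split.test_rows) == 100
        assert abs(len(split.train_rows) - 70) <= 4  # within 8 strata roundings

    def test_deterministic_and_disjoint(self, small_cohort):
        s1 = split_cohort(small_cohort, 0.7, seed=5)
        s2 = split_cohort(small_cohort, 0.7, seed=5)
        assert np.array_equal(s1.train_rows, s2.train_rows)
        assert np.array_equal(s1.test_rows, s2.test_rows)
        assert not set(s1.train_rows) & set(s1.test_rows)
        assert len(s1.train_rows) + len(s1.test_rows) == small_cohort.n

    def test_stratified_within_one_record(self, rng):
        # skewed 1000-row cohort: every stratum lands within 1 of 0.7*size
        codes = rng.choice(8, size=1000, p=[0.4, 0.2, 0.01, 0.14, 0.05, 0.15, 0.02, 0.03])
        cohort = CohortTable(features=np.zeros((1000, 62)), labels=lp_decode(codes))
        split = split_cohort(cohort, 0.7, seed=2)
        train_codes = lp_encode(cohort.labels[split.train_rows])
        test_codes = lp_encode(cohort.labels[split.test_rows])
        for c in range(8):
            size = np.sum(codes == c)
            in_train = np.sum(train_codes == c)
            assert abs(in_train - 0.7 * size) <= 1
            if size >= 2:
                assert in_train >= 1 and np.sum(test_codes == c) >= 1

    def test_singleton_stratum_goes_to_train(self):
        labels = np.vstack([np.tile([0, 0, 0], (10, 1)), [[1, 1, 1]]])
        cohort = CohortTable(features=np.zeros((11, 62)), labels=labels)
        with pytest.warns(UserWarning, match="single record"):
            split = split_cohort(cohort, 0.7, seed=0)
        assert 10 in split.train_rows

    def test_invalid_fraction(self, small_cohort):
        with pytest.raises(ValidationError):
            split_cohort(small_cohort, 1.2, seed=0)


class TestStandardize:
    def test_training_columns_zscored(self, small_cohort, small_split):
        std, scaler = standardize(small_cohort, small_split)
        train = std.features[small_split.train_rows]
        assert np.allclose(train.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(train.std(axis=0), 1, atol=1e-9)
        # test rows use the training statistics, not their own
        expected = (small_cohort.features[small_split.test_rows] - scaler.mean) / scaler.sd
        assert np.array_equal(std.features[small_split.test_rows], expected)

    def test_scaler_reapplication_is_deterministic(self, small_cohort, small_split):
        std, scaler = standardize(small_cohort, small_split)
        again = scaler.transform(small_cohort.features)
        assert np.array_equal(again, std.features)
        # documented non-idempotence: transforming twice is not the identity
        assert not np.allclose(scaler.transform(std.features), std.features)

    def test_constant_column_centred_only(self, small_split, small_cohort):
        features = small_cohort.features.copy()
        features[:, 5] = 3.0
        cohort = CohortTable(features=features, labels=small_cohort.labels)
        with pytest.warns(UserWarning, match="constant"):
            std, scaler = standardize(cohort, small_split)
        assert np.allclose(std.features[:, 5], 0.0)
        assert scaler.sd[5] == 1.0

    def test_scaler_json_roundtrip(self, small_cohort, small_split):
        _, scaler = standardize(small_cohort, small_split)
        restored = Scaler.from_json(scaler.to_json())
        assert np.array_equal(
            restored.transform(small_cohort.features),
            scaler.transform(small_cohort.features),
        )


class TestCsvIO:
    def test_write_read_identity(self, tmp_path, rng):
        cohort = CohortTable(
            features=rng.normal(size=(3, 62)).round(9),
            labels=rng.integers(0, 2, size=(3, 3)),
        )
        path = tmp_path / "c.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        assert np.allclose(back.features, cohort.features)
        assert np.array_equal(back.labels, cohort.labels)

    def test_missing_values_dropped_and_logged(self, tmp_path, rng, caplog):
        cohort = CohortTable(
            features=rng.normal(size=(10, 62)),
            labels=rng.integers(0, 2, size=(10, 3)),
        )
        path = tmp_path / "c.csv"
        write_cohort_csv(cohort, path)
        lines = path.read_text().splitlines()
        fields = lines[4].split(",")
        fields[10] = ""  # blank one feature cell in data row 3
        lines[4] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("INFO", logger="groupnet.cohort"):
            back = read_cohort_csv(path)
        assert back.n == 9
        assert "dropped 1 rows" in caplog.text

    def test_nonbinary_label_cites_row(self, tmp_path, rng):
        cohort = CohortTable(
            features=rng.normal(size=(8, 62)),
            labels=rng.integers(0, 2, size=(8, 3)),
        )
        path = tmp_path / "c.csv"
        write_cohort_csv(cohort, path)
        lines = path.read_text().splitlines()
        fields = lines[6].split(",")
        fields[-1] = "2"  # data row 5
        lines[6] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="row 5"):
            read_cohort_csv(path)

    def test_malformed_header_names_column(self, tmp_path, rng):
        cohort = CohortTable(
            features=rng.normal(size=(2, 62)),
            labels=rng.integers(0, 2, size=(2, 3)),
        )
        path = tmp_path / "c.csv"
        write_cohort_csv(cohort, path)
        text = path.read_text().replace("f007", "foo07")
        path.write_text(text)
        with pytest.raises(SchemaError, match="foo07"):
            read_cohort_csv(path)

    def test_feature_names_layout(self):
        names = feature_names()
        assert len(names) == 62
        assert names[0] == "f001" and names[-1] == "f062"
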
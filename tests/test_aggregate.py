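import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fedcube.aggregate import AggregateMatrix, MatrixMetadata, cube_counts, merge, suppress
from fedcube.errors import MergeError, ValidationError
from helpers import brute_force_cube, random_cohort


def tiny_cohort():
    return pd.DataFrame({"disease": ["1", "1", "0", "1"],
                         "cough": ["1", "0", "0", "1"]})


class TestCubeCounts:
    def test_worked_example_two_booleans(self):
        m = cube_counts(tiny_cohort(), ["disease", "cough"])
        assert len(m.rows) == 8
        assert m.total == 4
        assert m.count({"disease": "1"}) == 3
        assert m.count({"disease": "0"}) == 1
        assert m.count({"cough": "1"}) == 2
        assert m.count({"cough": "0"}) == 2
        assert m.count({"disease": "1", "cough": "1"}) == 2
        assert m.count({"disease": "1", "cough": "0"}) == 1
        assert m.count({"disease": "0", "cough": "0"}) == 1

    def test_empty_cohort_single_null_row(self):
        m = cube_counts(pd.DataFrame({"a": []}), ["a"])
        assert m.rows == {(): 0}

    def test_null_set_row_equals_cohort_size(self):
        rng = np.random.default_rng(0)
        cohort = random_cohort(rng, 57, 3)
        assert cube_counts(cohort, list(cohort.columns)).total == 57

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cohort = random_cohort(rng, int(rng.integers(1, 200)), int(rng.integers(1, 5)))
            variables = list(cohort.columns)
            assert cube_counts(cohort, variables).rows == brute_force_cube(cohort, variables)

    def test_unobserved_combinations_omitted(self):
        cohort = pd.DataFrame({"a": ["x", "x"], "b": ["y", "y"]})
        m = cube_counts(cohort, ["a", "b"])
        # only 1 level per variable observed: 4 rows, not 2^2 x levels
        assert len(m.rows) == 4
        assert m.count({"a": "z"}) is None

    def test_continuous_column_rejected(self):
        cohort = pd.DataFrame({"bp": [120.5, 130.2]})
        with pytest.raises(ValidationError, match="bin"):
            cube_counts(cohort, ["bp"])

    def test_variable_cap_enforced(self):
        cohort = pd.DataFrame({f"v{i}": ["a"] for i in range(11)})
        with pytest.raises(ValidationError, match="2\\^11"):
            cube_counts(cohort, list(cohort.columns))

    def test_marginal_consistency(self):
        """Summing one variable's levels inside a fixed context reproduces
        the context row (pre-suppression)."""
        rng = np.random.default_rng(2)
        cohort = random_cohort(rng, 300, 3)
        m = cube_counts(cohort, ["v0", "v1", "v2"])
        ctx_count = m.count({"v0": "0"})
        if ctx_count is not None:
            levels = sorted(cohort["v1"].unique())
            sub = sum(m.count({"v0": "0", "v1": l}) or 0 for l in levels)
            assert sub == ctx_count

    def test_every_row_bounded_by_null_set(self):
        rng = np.random.default_rng(3)
        cohort = random_cohort(rng, 500, 4)
        m = cube_counts(cohort, list(cohort.columns))
        assert all(c <= m.total for c in m.rows.values())


class TestSuppression:
    def test_rows_below_threshold_removed_entirely(self):
        m = AggregateMatrix(["d", "c"], {(): 15, (("d", "1"),): 12,
                                         (("c", "1"), ("d", "1")): 9})
        s = suppress(m, 10)
        assert (("c", "1"), ("d", "1")) not in s.rows
        assert s.rows == {(): 15, (("d", "1"),): 12}
        assert s.metadata.threshold == 10

    def test_threshold_one_is_identity(self):
        m = cube_counts(tiny_cohort(), ["disease", "cough"])
        assert suppress(m, 1).rows == m.rows

    def test_whole_cohort_below_threshold_yields_empty_matrix(self, caplog):
        m = cube_counts(tiny_cohort().head(3), ["disease"])
        with caplog.at_level("WARNING"):
            s = suppress(m, 10)
        assert s.rows == {}
        assert any("refusing" in r.message for r in caplog.records)

    def test_suppression_never_increases_counts_only_removes(self):
        rng = np.random.default_rng(4)
        cohort = random_cohort(rng, 400, 3)
        m = cube_counts(cohort, list(cohort.columns))
        s = suppress(m, 10)
        assert set(s.rows) <= set(m.rows)
        assert all(s.rows[a] == m.rows[a] for a in s.rows)
        assert all(c >= 10 for c in s.rows.values())


def mat(rows, sites=("A",), threshold=10):
    return AggregateMatrix(["d"], rows, MatrixMetadata(
        sites=list(sites), study_period=("2020-01", "2020-12"), threshold=threshold))


class TestMerge:
    def test_cellwise_sum(self):
        a = mat({(): 15, (("d", "1"),): 12}, sites=("A",))
        b = mat({(): 20, (("d", "1"),): 11}, sites=("B",))
        m = merge([a, b])
        assert m.rows == {(): 35, (("d", "1"),): 23}
        assert m.metadata.sites == ["A", "B"]

    def test_merge_of_one_is_identity(self):
        a = mat({(): 15, (("d", "1"),): 12})
        m = merge([a])
        assert m.rows == a.rows and m.variables == a.variables

    def test_commutative(self):
        a = mat({(): 15, (("d", "1"),): 12}, sites=("A",))
        b = mat({(): 20, (("d", "0"),): 11}, sites=("B",))
        assert merge([a, b]).rows == merge([b, a]).rows

    def test_associative_against_single_pass_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ms = []
            for s in "ABC":
                rows = {(): 0}
                for lev in range(int(rng.integers(1, 4))):
                    c = int(rng.integers(10, 100))
                    rows[(("d", str(lev)),)] = c
                    rows[()] += c
                ms.append(mat(rows, sites=(s,)))
            a, b, c = ms
            left = merge([a, merge([b, c])]).rows
            right = merge([merge([a, b]), c]).rows
            single = merge([a, b, c]).rows
            assert left == right == single

    def test_locally_suppressed_cells_contribute_zero(self):
        """A cell of 7 suppressed at site B is invisible: the merged count is
        site A's alone — the documented undercount of suppress-then-merge."""
        a_raw = mat({(): 30, (("d", "1"),): 25}, sites=("A",), threshold=None)
        b_raw = mat({(): 30, (("d", "1"),): 7}, sites=("B",), threshold=None)
        a, b = suppress(a_raw, 10), suppress(b_raw, 10)
        assert (("d", "1"),) not in b.rows
        m = merge([a, b])
        assert m.rows[(("d", "1"),)] == 25

    def test_variable_mismatch_names_divergence(self):
        a = mat({(): 15})
        b = AggregateMatrix(["x"], {(): 15}, MatrixMetadata(
            sites=["B"], study_period=("2020-01", "2020-12"), threshold=10))
        with pytest.raises(MergeError, match="d.*x"):
            merge([a, b])

    def test_study_period_mismatch_rejected(self):
        a = mat({(): 15})
        b = AggregateMatrix(["d"], {(): 15}, MatrixMetadata(
            sites=["B"], study_period=("2021-01", "2021-12"), threshold=10))
        with pytest.raises(MergeError, match="period"):
            merge([a, b])


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        m = cube_counts(tiny_cohort(), ["disease", "cough"],
                        metadata=MatrixMetadata(sites=["site1"],
                                                study_period=("2020-03", "2021-02"),
                                                compiled="2021-03-01T00:00:00"))
        m = suppress(m, 1)
        path = m.write_csv(tmp_path / "m.csv")
        back = AggregateMatrix.read_csv(path)
        assert back.rows == m.rows
        assert back.variables == m.variables
        assert back.metadata.sites == ["site1"]
        assert back.metadata.threshold == 1

    def test_byte_stable_output(self, tmp_path):
        m = suppress(cube_counts(tiny_cohort(), ["disease", "cough"]), 1)
        p1 = m.write_csv(tmp_path / "a.csv")
        p2 = m.write_csv(tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 4), st.integers(1, 120))
def test_cube_oracle_property(seed, n_vars, n_rows):
    """For any random discrete cohort, the grouped cube equals subset-by-subset
    brute-force enumeration exactly."""
    rng = np.random.default_rng(seed)
    cohort = random_cohort(rng, n_rows, n_vars)
    variables = list(cohort.columns)
    assert cube_counts(cohort, variables).rows == brute_force_cube(cohort, variables)
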
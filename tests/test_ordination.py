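import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from microttr import (
    CovariateTable,
    cca,
    forward_select,
    partial_cca,
    transform_covariates,
    variance_partition,
)
from microttr.community_io import ValidationError
from microttr.ordination import total_inertia

from conftest import make_table


def chi_square_residuals_oracle(counts):
    """Direct double-loop chi-square standardization (independent oracle)."""
    counts = np.asarray(counts, dtype=float)
    grand = counts.sum()
    P = counts / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    q = np.zeros_like(P)
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            e = r[i] * c[j]
            q[i, j] = (P[i, j] - e) / np.sqrt(e)
    return q, r


def covtab(table, data, group="W", groups=None):
    df = pd.DataFrame(data, index=table.sample_ids)
    df.columns = [str(c) for c in df.columns]
    groups = groups or {c: group for c in df.columns}
    return CovariateTable(table.sample_ids, df, groups)


class TestTransformCovariates:
    def test_log2_values(self):
        t = make_table([[1, 1]] * 3)
        cov = covtab(t, {"v": [0.0, 1.0, 7.0]})
        out = transform_covariates(cov)
        assert list(out.data["v"]) == pytest.approx([0.0, 1.0, 3.0])
        assert out.groups == cov.groups

    def test_negative_rejected(self):
        t = make_table([[1, 1]] * 3)
        with pytest.raises(ValidationError):
            transform_covariates(covtab(t, {"v": [-1.0, 0.0, 1.0]}))


class TestCCA:
    def test_total_inertia_matches_chi_square_oracle(self, rng):
        for _ in range(30):
            n, p = rng.integers(3, 9, size=2)
            counts = rng.integers(1, 25, size=(n, p))
            t = make_table(counts)
            q, _ = chi_square_residuals_oracle(counts)
            assert abs(total_inertia(t) - (q**2).sum()) < 1e-10

    def test_full_rank_covariates_explain_everything(self, rng):
        counts = rng.integers(1, 30, size=(6, 8))
        t = make_table(counts)
        cov = covtab(t, rng.normal(size=(6, 5)))
        res = cca(t, cov)
        assert res.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_covariate_zero_inertia(self, rng):
        counts = rng.integers(1, 20, size=(6, 3))
        t = make_table(counts)
        q, r = chi_square_residuals_oracle(counts)
        v = null_space(q.T)[:, 0]  # v @ q == 0
        x = v / np.sqrt(r)
        res = cca(t, covtab(t, {"v": x}))
        assert res.constrained_inertia < 1e-10

    def test_duplicated_blocks_binary_covariate(self, rng):
        # two blocks of duplicated samples: the block indicator captures all
        # compositional variation, which equals the inertia of the collapsed
        # two-row table
        row_a = rng.integers(1, 20, size=4)
        row_b = rng.integers(1, 20, size=4)
        t = make_table(np.array([row_a, row_a, row_b, row_b]))
        res = cca(t, covtab(t, {"block": [0.0, 0.0, 1.0, 1.0]}))
        collapsed = make_table(np.array([2 * row_a, 2 * row_b]))
        assert res.constrained_inertia == pytest.approx(
            total_inertia(collapsed), abs=1e-10
        )
        assert res.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_axis_count_bounded_by_covariates(self, rng):
        counts = rng.integers(1, 30, size=(7, 10))
        t = make_table(counts)
        res = cca(t, covtab(t, rng.normal(size=(7, 2))))
        assert len(res.eigenvalues) <= 2
        assert all(e >= 0 for e in res.eigenvalues)
        assert list(res.eigenvalues) == sorted(res.eigenvalues, reverse=True)

    def test_invariances(self, rng):
        counts = rng.integers(1, 30, size=(6, 9))
        t = make_table(counts)
        x = rng.normal(size=(6, 2))
        base = cca(t, covtab(t, x)).eigenvalues
        perm = rng.permutation(9)
        shuffled = make_table(counts[:, perm])
        assert np.allclose(cca(shuffled, covtab(shuffled, x)).eigenvalues, base)
        rescaled = covtab(t, 3.7 * x + 11.0)
        assert np.allclose(cca(t, rescaled).eigenvalues, base)

    def test_constant_covariate_named(self, rng):
        t = make_table(rng.integers(1, 10, size=(4, 3)))
        with pytest.raises(ValidationError, match="flatvar"):
            cca(t, covtab(t, {"flatvar": [2.0] * 4}))

    def test_too_many_covariates(self, rng):
        t = make_table(rng.integers(1, 10, size=(4, 3)))
        with pytest.raises(ValidationError):
            cca(t, covtab(t, rng.normal(size=(4, 4))))


class TestPartialCCA:
    def test_empty_condition_reduces_to_cca(self, rng):
        counts = rng.integers(1, 30, size=(6, 5))
        t = make_table(counts)
        cov = covtab(t, rng.normal(size=(6, 2)))
        assert partial_cca(t, cov, None).constrained_inertia == pytest.approx(
            cca(t, cov).constrained_inertia
        )

    def test_condition_equals_covariates_leaves_nothing(self, rng):
        counts = rng.integers(1, 30, size=(6, 5))
        t = make_table(counts)
        x = rng.normal(size=6)
        cov = covtab(t, {"a": x})
        cond = covtab(t, {"b": x.copy()}, group="O")
        assert partial_cca(t, cov, cond).constrained_inertia < 1e-9

    def test_orthogonal_covariates_partial_equals_marginal(self):
        # equal sample totals make row masses uniform, so +/- design columns
        # stay orthogonal under weighting
        base = np.array([10, 10, 10, 10])
        v1 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        v2 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        counts = np.array(
            [base + 3 * a * np.array([1, -1, 0, 0]) + 3 * b * np.array([0, 0, 1, -1])
             for a, b in zip(v1, v2)],
            dtype=int,
        )
        t = make_table(counts)
        c1, c2 = covtab(t, {"v1": v1}), covtab(t, {"v2": v2}, group="O")
        marginal = cca(t, c1).constrained_inertia
        partial = partial_cca(t, c1, c2).constrained_inertia
        assert partial == pytest.approx(marginal, abs=1e-10)


class TestForwardSelect:
    def test_strong_gradient_gets_minimal_p(self, rng):
        # composition tracks the gradient tightly: the observed statistic
        # should beat every permutation, p = 1/(m+1)
        grad = np.arange(8, dtype=float)
        counts = np.column_stack(
            [100 + 10 * grad, 180 - 10 * grad, np.full(8, 50)]
        ).astype(int)
        t = make_table(counts)
        cov = covtab(t, {"grad": grad, "noise": rng.normal(size=8)})
        res = forward_select(t, cov, n_permutations=199, seed=3)
        assert res.selected and res.selected[0][0] == "grad"
        assert res.selected[0][1] == pytest.approx(1.0 / 200.0)

    def test_no_candidate_passes(self, rng):
        counts = rng.integers(10, 20, size=(6, 4))
        t = make_table(counts)
        cov = covtab(t, {"n1": rng.normal(size=6)})
        res = forward_select(t, cov, n_permutations=99, threshold=1e-6, seed=0)
        assert res.selected == []
        assert [v for v, _ in res.rejected] == ["n1"]

    def test_bad_permutation_count(self, rng):
        t = make_table(rng.integers(1, 9, size=(4, 3)))
        with pytest.raises(ValidationError):
            forward_select(t, covtab(t, {"v": [1.0, 2, 3, 4]}), n_permutations=0)


class TestVariancePartition:
    def _random_setup(self, rng, n=8, p=6):
        counts = rng.integers(1, 30, size=(n, p))
        t = make_table(counts)
        data = {
            "w1": rng.normal(size=n),
            "o1": rng.normal(size=n),
            "s1": rng.normal(size=n),
        }
        groups = {"w1": "W", "o1": "O", "s1": "S"}
        return t, covtab(t, data, groups=groups)

    def test_fractions_sum_to_one(self, rng):
        t, cov = self._random_setup(rng)
        v = variance_partition(t, cov)
        assert sum(v.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_group_label_symmetry(self, rng):
        t, cov = self._random_setup(rng)
        v1 = variance_partition(t, cov)
        relabeled = CovariateTable(
            cov.sample_ids, cov.data, {"w1": "O", "o1": "W", "s1": "S"}
        )
        v2 = variance_partition(t, relabeled)
        assert v1.fractions["W"] == pytest.approx(v2.fractions["O"], abs=1e-9)
        assert v1.fractions["O"] == pytest.approx(v2.fractions["W"], abs=1e-9)
        assert v1.fractions["W&S"] == pytest.approx(v2.fractions["O&S"], abs=1e-9)
        assert v1.fractions["W&O&S"] == pytest.approx(
            v2.fractions["W&O&S"], abs=1e-9
        )

    def test_orthogonal_groups_have_zero_intersections(self):
        v1 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        v2 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        v3 = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        base = np.full(5, 40)
        counts = np.array(
            [base + (4 * a * np.array([1, -1, 0, 0, 0])
                     + 4 * b * np.array([0, 0, 1, -1, 0])
                     + 4 * c * np.array([0, 0, 0, 1, -1]))
             for a, b, c in zip(v1, v2, v3)],
            dtype=int,
        )
        t = make_table(counts)
        cov = covtab(
            t, {"w1": v1, "o1": v2, "s1": v3},
            groups={"w1": "W", "o1": "O", "s1": "S"},
        )
        v = variance_partition(t, cov)
        for key in ("W&O", "W&S", "O&S", "W&O&S"):
            assert abs(v.fractions[key]) < 1e-9
        for key, var in (("W", "w1"), ("O", "o1"), ("S", "s1")):
            marginal = cca(t, cov.subset([var])).explained_fraction
            assert v.fractions[key] == pytest.approx(marginal, abs=1e-9)

    def test_identical_groups_share_everything(self, rng):
        n = 8
        counts = rng.integers(1, 30, size=(n, 5))
        t = make_table(counts)
        x = rng.normal(size=n)
        cov = covtab(
            t,
            {"w1": x, "o1": x.copy(), "s1": rng.normal(size=n)},
            groups={"w1": "W", "o1": "O", "s1": "S"},
        )
        v = variance_partition(t, cov)
        assert abs(v.fractions["W"]) < 1e-9
        assert abs(v.fractions["O"]) < 1e-9
        assert v.fractions["W&O"] + v.fractions["W&O&S"] > 0

    def test_empty_group_rejected(self, rng):
        t = make_table(rng.integers(1, 9, size=(5, 4)))
        cov = covtab(t, {"w1": rng.normal(size=5), "o1": rng.normal(size=5)},
                     groups={"w1": "W", "o1": "O"})
        with pytest.raises(ValidationError):
            variance_partition(t, cov)
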
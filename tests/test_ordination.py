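"""Correspondence analysis, detrending, DCA and supplementary variables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from vegclass.ordination import (
    OrdinationError,
    ca,
    community_matrix,
    cwm_eiv,
    cwm_table,
    dca,
    detrend_segments,
    fit_supplementary,
    load_eiv,
    transform_cover,
)
from vegclass.releve_io import ReleveTable
from vegclass.synthetic_data import gradient_matrix

from conftest import make_releve


def _df(arr):
    arr = np.asarray(arr, float)
    return pd.DataFrame(
        arr,
        index=[f"p{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def ca_eigvals_oracle(X):
    """Eigenvalues of the row-to-row transition operator (independent of the
    SVD route): eig of D_r^-1 P D_c^-1 P^T, dropping the trivial 1."""
    P = X / X.sum()
    r, c = P.sum(1), P.sum(0)
    M = np.diag(1 / r) @ P @ np.diag(1 / c) @ P.T
    vals = np.sort(np.real(np.linalg.eigvals(M)))[::-1]
    return vals[1:]  # drop trivial eigenvalue 1


class TestTransform:
    def test_sqrt_and_zero(self):
        out = transform_cover(_df([[25.0, 0.0]]), p=0.5)
        assert out.iloc[0, 0] == 5.0 and out.iloc[0, 1] == 0.0

    def test_identity_at_p1(self):
        df = _df([[4.0, 9.0]])
        assert transform_cover(df, p=1.0).equals(df)

    def test_negative_rejected(self):
        with pytest.raises(OrdinationError):
            transform_cover(_df([[-1.0]]))


class TestCA:
    def test_disjoint_blocks_give_unit_eigenvalue(self):
        X = _df([[5, 3, 0, 0], [2, 4, 0, 0], [0, 0, 6, 1], [0, 0, 2, 2]])
        assert ca(X).eigenvalues[0] == pytest.approx(1.0)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(OrdinationError, match="rank 0"):
            ca(_df(np.ones((4, 5))))

    def test_eigenvalues_match_transition_oracle(self):
        rng = np.random.default_rng(42)
        for n, m in [(6, 8), (10, 7), (20, 30)]:
            X = rng.uniform(0, 10, size=(n, m))
            X[X < 2] = 0.0
            X += 0.01  # avoid empty rows/cols
            res = ca(_df(X), n_axes=4)
            oracle = ca_eigvals_oracle(X)
            np.testing.assert_allclose(
                res.eigenvalues, oracle[: len(res.eigenvalues)], atol=1e-8
            )

    def test_transition_formula(self):
        # weighted average of column scores = sqrt(eigenvalue) * row scores
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 5, size=(8, 6))
        res = ca(_df(X), n_axes=3)
        P = X / X.sum()
        r = P.sum(1)
        for k in range(3):
            avg = (P @ res.col_scores.to_numpy()[:, k]) / r
            expect = np.sqrt(res.eigenvalues[k]) * res.row_scores.to_numpy()[:, k]
            np.testing.assert_allclose(avg, expect, atol=1e-8)

    def test_eigenvalues_bounded_and_sorted(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 4, size=(12, 9)) + 0.01
        ev = ca(_df(X), n_axes=6).eigenvalues
        assert np.all(ev >= -1e-12) and np.all(ev <= 1 + 1e-12)
        assert np.all(np.diff(ev) <= 1e-12)


class TestDetrend:
    def test_constant_target_zeroed(self):
        primary = np.linspace(0, 1, 40)
        out = detrend_segments(primary, np.full(40, 3.0), 26)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_segment_is_mean_centering(self):
        primary = np.linspace(0, 1, 10)
        target = primary.copy()
        out = detrend_segments(primary, target, 1)
        np.testing.assert_allclose(out, target - target.mean(), atol=1e-12)

    def test_arch_removed_segmentwise(self):
        # quadratic arch over a uniform primary: recomputed segment means of
        # the output must vanish
        primary = np.linspace(-1, 1, 260)
        target = primary**2
        out = detrend_segments(primary, target, 26)
        edges = np.linspace(-1, 1, 27)
        idx = np.clip(np.searchsorted(edges, primary, "right") - 1, 0, 25)
        for s in range(26):
            assert abs(out[idx == s].mean()) < 1e-10


@pytest.fixture(scope="module")
def gradient_result():
    mat = transform_cover(gradient_matrix(50, 20))
    return mat, dca(mat, n_axes=2)


class TestDCA:

    def test_axis1_recovers_gradient_ranks(self, gradient_result):
        _, res = gradient_result
        rho = spearmanr(
            res.site_scores["DCA1"], np.arange(len(res.site_scores))
        ).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_axis2_segment_means_vanish(self, gradient_result):
        _, res = gradient_result
        ax1 = res.site_scores["DCA1"].to_numpy()
        ax2 = res.site_scores["DCA2"].to_numpy()
        assert np.max(np.abs(ax2 - detrend_segments(ax1, ax2, 26))) < 1e-10

    def test_row_permutation_equivariance(self, gradient_result):
        mat, res = gradient_result
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(mat))
        res_p = dca(mat.iloc[perm], n_axes=2)
        np.testing.assert_allclose(res_p.eigenvalues, res.eigenvalues, atol=1e-9)
        realigned = res_p.site_scores.loc[res.site_scores.index]
        for k in range(2):
            a = res.site_scores.iloc[:, k].to_numpy()
            b = realigned.iloc[:, k].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-7

    def test_eigenvalues_bounded(self, gradient_result):
        _, res = gradient_result
        assert np.all(res.eigenvalues > 0) and np.all(res.eigenvalues <= 1)

    def test_two_cluster_axis1_separates(self):
        rng = np.random.default_rng(11)
        A = np.zeros((12, 10))
        A[:6, :5] = rng.uniform(1, 10, (6, 5))
        A[6:, 5:] = rng.uniform(1, 10, (6, 5))
        res = dca(_df(A), n_axes=1)
        signs = np.sign(res.site_scores["DCA1"].to_numpy())
        assert len(set(signs[:6])) == 1 and len(set(signs[6:])) == 1
        assert signs[0] != signs[-1]


class TestEIV:
    def test_cwm_examples(self):
        eiv = pd.DataFrame(
            {"F": [4.0, 6.0, 8.0]}, index=["Sp a", "Sp b", "Sp c"]
        )
        assert cwm_eiv(make_releve({"Sp a": 50, "Sp b": 50}), eiv, "F") == 5.0
        assert cwm_eiv(make_releve({"Sp c": 30}), eiv, "F") == 8.0
        assert cwm_eiv(make_releve({"Sp a": 75, "Sp c": 25}), eiv, "F") == 5.0

    def test_missing_values_excluded_and_undefined(self):
        eiv = pd.DataFrame({"F": [4.0, np.nan]}, index=["Sp a", "Sp b"])
        assert cwm_eiv(make_releve({"Sp a": 10, "Sp b": 90}), eiv, "F") == 4.0
        assert cwm_eiv(make_releve({"Sp b": 90}), eiv, "F") is None

    def test_cwm_within_contributing_range(self):
        eiv = load_eiv()
        rel = make_releve({"Cyperus fuscus": 40, "Juncus bufonius": 10})
        for ind in eiv.columns:
            v = cwm_eiv(rel, eiv, ind)
            lo = min(eiv.at["Cyperus fuscus", ind], eiv.at["Juncus bufonius", ind])
            hi = max(eiv.at["Cyperus fuscus", ind], eiv.at["Juncus bufonius", ind])
            assert lo <= v <= hi


@pytest.fixture(scope="module")
def supp_result():
    return dca(transform_cover(gradient_matrix(40, 15)), n_axes=2)


class TestSupplementaryFit:

    def test_indicator_equal_to_axis1(self, supp_result):
        vals = pd.DataFrame({"X": supp_result.site_scores["DCA1"]})
        fit = fit_supplementary(supp_result, vals, n_permutations=99, seed=0)
        assert fit.r2["X"] == pytest.approx(1.0)
        assert abs(fit.directions.at["X", "DCA1"]) == pytest.approx(1.0, abs=1e-6)
        assert fit.p["X"] <= 0.05

    def test_constant_indicator(self, supp_result):
        vals = pd.DataFrame({"C": np.ones(len(supp_result.site_scores))},
                            index=supp_result.site_scores.index)
        fit = fit_supplementary(supp_result, vals, n_permutations=99, seed=0)
        assert fit.r2["C"] == 0.0 and fit.p["C"] == 1.0

    def test_noise_indicator_p_uniformish(self, supp_result):
        rng = np.random.default_rng(123)
        ps = []
        for rep in range(20):
            vals = pd.DataFrame(
                {"Z": rng.normal(size=len(supp_result.site_scores))},
                index=supp_result.site_scores.index,
            )
            fit = fit_supplementary(supp_result, vals, n_permutations=99, seed=rep)
            ps.append(fit.p["Z"])
        assert 0.15 <= float(np.median(ps)) <= 0.85


def test_community_matrix_prunes_and_scales():
    rels = [
        make_releve({"Sp a": 50, "Sp b": 10}, "p1"),
        make_releve({"Sp a": 20}, "p2"),
        make_releve({}, "p3"),  # empty plot pruned
    ]
    mat = community_matrix(ReleveTable(rels))
    assert list(mat.index) == ["p1", "p2"]
    assert mat.at["p1", "Sp a"] == pytest.approx(50.0)
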
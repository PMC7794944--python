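"""Rank fusion and kernel PCA: worked mean-rank values, oracle equivalences."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from pupglearn import hfsr
from pupglearn.synth import ConfigurationError


def _two_class(rng, n_per_class=20, n_features=6, shift=0.0):
    X = rng.standard_normal((2 * n_per_class, n_features))
    X[n_per_class:, 0] += shift
    y = np.array(["normal"] * n_per_class + ["hypertension"] * n_per_class)
    return X, y


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", hfsr.RANK_METHODS)
def test_informative_feature_outranks_noise(method, rng):
    X, y = _two_class(rng, n_per_class=30, shift=3.0)
    scores = hfsr.score_features(X, y, method)
    assert np.argmax(scores) == 0


def test_identical_class_distributions_score_near_zero():
    x = np.arange(12, dtype=float)
    X = np.column_stack([np.r_[x[:6], x[:6]]])
    y = np.array(["a"] * 6 + ["b"] * 6)
    assert hfsr.score_features(X, y, "ROC")[0] == pytest.approx(0.0, abs=1e-12)
    assert hfsr.score_features(X, y, "TT")[0] == pytest.approx(0.0, abs=1e-12)


def test_perfect_separation_gives_half_auc_distance():
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    y = np.array(["a"] * 3 + ["b"] * 3)
    assert hfsr.score_features(X, y, "ROC")[0] == pytest.approx(0.5)


def test_roc_score_equals_exhaustive_pair_counting(rng):
    for _ in range(20):
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(3, 7))
        x = rng.integers(0, 5, n1 + n2).astype(float)  # ties on purpose
        y = np.array(["a"] * n1 + ["b"] * n2)
        wins = sum(
            (1.0 if bb > aa else 0.5 if bb == aa else 0.0)
            for aa in x[:n1] for bb in x[n1:]
        )
        auc = wins / (n1 * n2)
        got = hfsr.score_features(x[:, None], y, "ROC")[0]
        assert got == pytest.approx(abs(auc - 0.5), abs=1e-12)


def test_single_class_input_rejected():
    with pytest.raises(ValueError):
        hfsr.score_features(np.random.rand(6, 2), np.zeros(6), "TT")


def test_zero_variance_feature_scores_zero(rng):
    X, y = _two_class(rng, shift=2.0)
    X[:, 3] = 7.0
    with pytest.warns(UserWarning, match="zero-variance"):
        scores = hfsr.score_features(X, y, "KLD")
    assert scores[3] == 0.0


# ---------------------------------------------------------------------------
# Ranks and fusion
# ---------------------------------------------------------------------------

def test_scores_to_ranks_ordering_ties_and_invariance():
    np.testing.assert_array_equal(hfsr.scores_to_ranks([0.1, 0.9, 0.5]), [1, 3, 2])
    np.testing.assert_array_equal(hfsr.scores_to_ranks([1.0] * 4), [3, 3, 3, 3])
    s = np.array([0.3, 2.0, 0.7, 1.1])
    np.testing.assert_array_equal(
        hfsr.scores_to_ranks(s), hfsr.scores_to_ranks(np.exp(s))
    )


@pytest.mark.parametrize(
    "ranks, expected",
    [
        ((53, 49, 52, 99, 18, 58, 72), 57.29),
        ((12, 93, 93, 83, 32, 102, 98), 73.29),
        ((100, 98, 98, 26, 96, 97, 55), 81.43),
        ((89, 96, 76, 73, 85, 52, 96), 81.00),
        ((93, 64, 64, 67, 68, 91, 95), 77.43),
    ],
)
def test_mean_rank_worked_examples(ranks, expected):
    assert hfsr.mean_rank(np.array(ranks)) == pytest.approx(expected, abs=0.005)


def test_mean_rank_of_constant_ranks_is_that_rank():
    assert hfsr.mean_rank(np.full(7, 42)) == 42.0


def test_rank_sum_conservation_without_ties(rng):
    scores = rng.permutation(102).astype(float)
    table = pd.DataFrame(
        {m: hfsr.scores_to_ranks(rng.permutation(102).astype(float))
         for m in hfsr.RANK_METHODS}
    )
    mr = hfsr.mean_rank(table)
    assert mr.mean() == pytest.approx((102 + 1) / 2, abs=1e-9)
    assert np.all((1 <= mr) & (mr <= 102))
    del scores


def test_select_top_size_ties_and_errors():
    mr = np.array([5.0, 9.0, 9.0, 1.0])
    sel = hfsr.select_top(mr, 2)
    np.testing.assert_array_equal(sel, [1, 2])  # tie broken by registry order
    assert len(hfsr.select_top(mr, 4)) == 4
    with pytest.raises(ConfigurationError):
        hfsr.select_top(mr, 0)


def test_outlier_praise_from_one_method_is_not_selected():
    """A feature ranked best by a single method but mid-table by the other
    six cannot enter the top-24 of a 102-feature fusion."""
    F = 102
    rng = np.random.default_rng(5)
    table = np.zeros((F, 7))
    for m in range(7):
        table[:, m] = rng.permutation(F) + 1
    # feature 0: top mark from method 0, at/below median elsewhere
    table[0, 0] = F
    table[0, 1:] = 40
    mr = hfsr.mean_rank(table)
    selected = hfsr.select_top(mr, 24)
    assert mr[0] <= (F + 6 * 51) / 7
    assert 0 not in selected


def test_rank_table_layout(rng):
    X, y = _two_class(rng, n_per_class=10, shift=2.0)
    table = hfsr.rank_table(X, y, feature_names=[f"feat{i}" for i in range(6)])
    assert list(table.columns) == [*hfsr.RANK_METHODS, "MR"]
    assert table.loc["feat0", "MR"] == table["MR"].max()


# ---------------------------------------------------------------------------
# Kernel PCA
# ---------------------------------------------------------------------------

def test_linear_kernel_matches_pca_up_to_sign(rng):
    for _ in range(5):
        X = rng.standard_normal((20, 6))
        model = hfsr.kpca_fit(X, kernel="linear", n_components=4)
        Z = hfsr.kpca_transform(model, X)
        Xs = model.standardize(X)
        P = PCA(n_components=4).fit_transform(Xs)
        for j in range(4):
            assert min(
                np.abs(Z[:, j] - P[:, j]).max(), np.abs(Z[:, j] + P[:, j]).max()
            ) <= 1e-8


def test_rbf_projection_matches_dense_eigendecomposition(rng):
    X = rng.standard_normal((5, 3))
    gamma = 0.7
    model = hfsr.kpca_fit(X, kernel="rbf", gamma=gamma, n_components=2)
    Z = hfsr.kpca_transform(model, X)

    Xs = model.standardize(X)
    sq = np.sum(Xs**2, axis=1)
    K = np.exp(-gamma * (sq[:, None] + sq[None, :] - 2 * Xs @ Xs.T))
    n = K.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K @ J
    w, v = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1][:2]
    expected = v[:, order] * np.sqrt(np.abs(w[order]))
    for j in range(2):
        assert min(
            np.abs(Z[:, j] - expected[:, j]).max(),
            np.abs(Z[:, j] + expected[:, j]).max(),
        ) <= 1e-8


def test_kpca_eigenvalues_non_negative_and_sorted(rng):
    X = rng.standard_normal((30, 8))
    model = hfsr.kpca_fit(X, n_components=6)
    ev = model.eigenvalues
    assert np.all(ev >= -1e-10)
    assert np.all(np.diff(ev) <= 1e-12)


def test_duplicate_rows_project_identically(rng):
    X = rng.standard_normal((10, 4))
    X[5] = X[2]
    model = hfsr.kpca_fit(X, n_components=3)
    Z = hfsr.kpca_transform(model, X)
    np.testing.assert_allclose(Z[5], Z[2], atol=1e-10)


def test_transform_of_training_data_reproduces_fit_scores(rng):
    X = rng.standard_normal((15, 5))
    model = hfsr.kpca_fit(X, n_components=4)
    Z1 = hfsr.kpca_transform(model, X)
    Z2 = hfsr.kpca_transform(model, X)
    np.testing.assert_allclose(Z1, Z2, atol=1e-12)
    fitted = model._kpca.transform(model.standardize(X))
    np.testing.assert_allclose(Z1, fitted, atol=1e-8)


def test_component_presets_and_edge_cases(rng):
    assert hfsr.COMPONENT_PRESETS["S1"] == 5
    X = rng.standard_normal((12, 30))
    model = hfsr.kpca_fit(X, n_components=hfsr.COMPONENT_PRESETS["S1"])
    assert hfsr.kpca_transform(model, X).shape == (12, 5)
    assert hfsr.kpca_transform(model, np.empty((0, 30))).shape == (0, 5)
    with pytest.raises(ConfigurationError):
        hfsr.kpca_fit(X, n_components=13)
    with pytest.raises(ConfigurationError):
        hfsr.kpca_fit(X, n_components=0)
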
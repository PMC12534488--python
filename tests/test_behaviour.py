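"""Behavioural-analytics tests: each statistic against an independent
direct-formula oracle plus its boundary conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from revis import behaviour, synthetic
from revis.behaviour import (
    AnalysisError,
    ConditionProfile,
    ConfusionMatrix,
    UndefinedCorrelationError,
    accuracy_profile,
    compare_groups,
    condition_ranking_consistency,
    confusion_correlation,
    confusion_matrix,
    consistency,
    easy_hard_split,
    exclude_participants,
    masking_effect,
    pearson,
    size_effect_regression,
    split_half_reliability,
    summarize_seeds,
)
from revis.stimuli import condition_labels


def _table(rows):
    return pd.DataFrame(rows, columns=["subject", "condition", "masked",
                                       "true", "response", "rt", "correct"])


def _uniform_trials(subjects, acc_by_subject, n=20):
    rows = []
    conds = condition_labels()
    for s in subjects:
        p = acc_by_subject[s]
        k = int(round(p * n))
        for i in range(n):
            c = conds[i % len(conds)]
            ok = i < k
            rows.append([s, c, False, "cat", "cat" if ok else "bird",
                         0.5, ok])
    return _table(rows)


# ---------------------------------------------------------------------------
# Exclusion / profiles / split
# ---------------------------------------------------------------------------


def test_exclusion_boundary_and_identity():
    t = _uniform_trials(["a", "b", "c"], {"a": 0.7, "b": 0.9, "c": 0.5})
    kept, excluded = exclude_participants(t, 0.7)
    assert excluded == ["c"]
    assert set(kept["subject"]) == {"a", "b"}  # exactly 0.7 retained
    kept2, excl2 = exclude_participants(kept, 0.7)
    assert excl2 == [] and len(kept2) == len(kept)
    empty, none = exclude_participants(_table([]), 0.7)
    assert empty.empty and none == []


def test_accuracy_profile_values():
    conds = condition_labels()
    rows = []
    for c in conds:
        rows.append(["s", c, False, "cat", "cat", 0.4, True])
        rows.append(["s", c, False, "cat", "bird", 0.4, False])
    prof = accuracy_profile(_table(rows))
    assert np.allclose(prof.accuracy, 0.5)
    all_good = accuracy_profile(_table(
        [["s", c, False, "x", "x", 0.3, True] for c in conds]))
    assert np.allclose(all_good.accuracy, 1.0)
    # a condition with zero trials is flagged missing via NaN
    partial = accuracy_profile(_table([["s", conds[0], False, "x", "x", 0.3,
                                        True]]))
    assert np.isnan(partial.accuracy[1:]).all() and partial.n_trials[0] == 1


def test_masking_effect_recovery_and_zero():
    conds = condition_labels()
    rows = []
    for c in conds:
        for m in (False, True):
            for i in range(50):
                ok = i < 40 if not m else i < (20 if c == conds[3] else 40)
                rows.append(["s", c, m, "x", "x" if ok else "y", 0.2, ok])
    eff = masking_effect(_table(rows))
    assert eff.shape == (17,)
    assert np.isclose(eff[3], 0.4)
    assert np.allclose(np.delete(eff, 3), 0.0)


def test_easy_hard_split_boundary():
    conds = condition_labels()
    acc = np.full(17, 1.0)
    prof = ConditionProfile(conds, acc, np.full(17, 10))
    easy, hard = easy_hard_split(prof)
    assert len(easy) == 17 and hard == []
    acc2 = acc.copy()
    acc2[:8] = 0.9  # exactly at threshold -> hard (strict greater-than)
    easy2, hard2 = easy_hard_split(ConditionProfile(conds, acc2,
                                                    np.full(17, 10)))
    assert len(easy2) == 9 and len(hard2) == 8


# ---------------------------------------------------------------------------
# Pearson and consistency
# ---------------------------------------------------------------------------


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())


def test_pearson_extremes_and_oracle(rng):
    x = rng.standard_normal(17)
    assert np.isclose(pearson(x, 2 * x).r, 1.0)
    assert np.isclose(pearson(x, -x).r, -1.0)
    for _ in range(20):
        a, b = rng.standard_normal((2, 17))
        assert abs(pearson(a, b).r - _pearson_oracle(a, b)) < 1e-12
    with pytest.raises(UndefinedCorrelationError):
        pearson(np.ones(5), rng.standard_normal(5))
    with pytest.raises(AnalysisError):
        pearson([1, 2], [3, 4])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2 ** 31 - 1))
def test_pearson_bounded(seed):
    g = np.random.default_rng(seed)
    a, b = g.standard_normal((2, 9))
    r = pearson(a, b).r
    assert -1.0 <= r <= 1.0


def test_consistency_sign_and_identity():
    conds = condition_labels()
    h = ConditionProfile(conds, np.linspace(0.4, 1.0, 17), np.full(17, 10))
    assert np.isclose(consistency(h, h).r, 1.0)
    rev = ConditionProfile(conds, h.accuracy[::-1].copy(), h.n_trials)
    assert consistency(rev, h).r < 0
    other = ConditionProfile(conds[::-1], h.accuracy, h.n_trials)
    with pytest.raises(AnalysisError):
        consistency(other, h)


def test_summarize_seeds_shape():
    out = summarize_seeds(np.linspace(0, 1, 20))
    assert out["n_seeds"] == 20
    assert out["ci_low"] <= out["mean"] <= out["ci_high"]


# ---------------------------------------------------------------------------
# Confusions
# ---------------------------------------------------------------------------


def test_confusion_matrix_contracts():
    t = _table([["s", "control", False, "a", "a", 0.2, True],
                ["s", "control", False, "a", "b", 0.2, False],
                ["s", "control", False, "b", "b", 0.2, True]])
    cm = confusion_matrix(t, categories=["a", "b"])
    assert cm.counts.tolist() == [[1, 1], [0, 1]]
    assert cm.counts.sum(axis=1).tolist() == [2, 1]
    assert np.isclose(cm.accuracy, 2 / 3)
    with pytest.raises(AnalysisError):
        confusion_matrix(t, categories=["a"])


def test_confusion_correlation_diagonal_independence(rng):
    a = rng.integers(1, 50, size=(8, 8))
    b = rng.integers(1, 50, size=(8, 8))
    A, B = ConfusionMatrix(list("abcdefgh"), a), ConfusionMatrix(list("abcdefgh"), b)
    assert np.isclose(confusion_correlation(A, A).r, 1.0)
    base = confusion_correlation(A, B, proportions=False).r
    a2 = a.copy()
    np.fill_diagonal(a2, 999)
    # perturbing only the diagonal never changes the correlation
    assert np.isclose(
        confusion_correlation(ConfusionMatrix(list("abcdefgh"), a2), B,
                              proportions=False).r, base)
    # raw-count mode matches a direct 56-element oracle
    off = ~np.eye(8, dtype=bool)
    assert abs(base - _pearson_oracle(a[off], b[off])) < 1e-12


def test_confusion_correlation_degenerate():
    eye = ConfusionMatrix(list("abcdefgh"), np.eye(8, dtype=int) * 5)
    with pytest.raises(UndefinedCorrelationError):
        confusion_correlation(eye, eye)


def test_confusion_recovery_from_similarity_kernel(response_model):
    trials = synthetic.simulate_trials(response_model, 2, 200, seed=8)
    cm = confusion_matrix(trials, categories=list(response_model.categories))
    W = response_model.error_allocation()
    off = ~np.eye(8, dtype=bool)
    assert pearson(cm.proportions()[off], W[off]).r > 0.8


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def test_split_half_identical_groups():
    conds = condition_labels()
    rows = []
    for s in ("a", "b", "c", "d"):
        for i, c in enumerate(conds):
            ok = i % 3 != 0  # same deterministic pattern for everyone
            rows.append([s, c, False, "x", "x" if ok else "y", 0.2, ok])
    assert np.isclose(split_half_reliability(_table(rows), n_iter=10, seed=0),
                      1.0)
    with pytest.raises(AnalysisError):
        split_half_reliability(_table(rows[:17]), n_iter=2, seed=0)


def test_split_half_grows_with_trial_count(response_model):
    small = synthetic.simulate_trials(response_model, 6, 4, seed=2)
    large = synthetic.simulate_trials(response_model, 6, 120, seed=2)
    r_small = split_half_reliability(small, n_iter=20, seed=1)
    r_large = split_half_reliability(large, n_iter=20, seed=1)
    assert r_large > r_small
    assert r_large > 0.9
    assert split_half_reliability(large, n_iter=5, seed=3) == \
        split_half_reliability(large, n_iter=5, seed=3)


# ---------------------------------------------------------------------------
# Size/architecture regression and ranking consistency
# ---------------------------------------------------------------------------


def _ols_oracle(y, X):
    return np.linalg.solve(X.T @ X, X.T @ y)


def test_size_regression_constructed_fixture(rng):
    sizes = np.array([1e6, 3e6, 1e7, 3e7, 1e8, 3e8, 1e6, 3e6, 1e7, 3e7, 1e8, 3e8])
    recurrent = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
    acc = 0.3 + 0.08 * (np.log10(sizes) - 6)  # pure size effect
    df = pd.DataFrame({"accuracy": acc, "n_parameters": sizes,
                       "recurrent": recurrent.astype(bool)})
    res = size_effect_regression(df)
    assert res.params["log10_size"] > 0
    assert abs(res.params["recurrent"]) < 1e-10
    X = np.column_stack([np.ones(12), np.log10(sizes), recurrent])
    beta = _ols_oracle(acc, X)
    assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
    flat = df.assign(accuracy=0.5)
    res_flat = size_effect_regression(flat)
    assert abs(res_flat.params["log10_size"]) < 1e-10
    assert abs(res_flat.params["recurrent"]) < 1e-10


def test_size_regression_errors():
    df = pd.DataFrame({"accuracy": [0.1, 0.2, 0.3],
                       "n_parameters": [1e6, 1e7, 1e8],
                       "recurrent": [True, True, True]})
    with pytest.raises(AnalysisError):
        size_effect_regression(df)
    collinear = pd.DataFrame({
        "accuracy": [0.1, 0.2, 0.3, 0.4],
        "n_parameters": [1e6, 1e6, 1e7, 1e7],
        "recurrent": [False, False, True, True]})
    collinear["recurrent"] = [False, False, True, True]
    # size and architecture perfectly aligned -> still full rank here;
    # true rank deficiency: constant size
    degenerate = pd.DataFrame({
        "accuracy": [0.1, 0.2, 0.3, 0.4],
        "n_parameters": [1e6, 1e6, 1e6, 1e6],
        "recurrent": [False, False, True, True]})
    with pytest.raises(AnalysisError):
        size_effect_regression(degenerate)


def test_condition_ranking_consistency():
    conds = condition_labels()
    models_acc = np.linspace(0.3, 0.9, 6)
    grid = pd.DataFrame({f"m{i}": models_acc + 0.01 * i for i in range(6)}).T
    grid = pd.DataFrame(np.tile(models_acc, (17, 1)), index=conds,
                        columns=[f"m{i}" for i in range(6)])
    rs = condition_ranking_consistency(grid)
    assert len(rs) == 17
    assert np.allclose(rs.to_numpy(), 1.0)
    grid2 = grid.copy()
    grid2.iloc[5] = models_acc[::-1]
    rs2 = condition_ranking_consistency(grid2)
    assert rs2.iloc[5] < 0
    assert np.allclose(rs2.drop(rs2.index[5]).to_numpy(), 1.0, atol=0.05)


def test_compare_groups_identities(rng):
    a = rng.standard_normal(8)
    t, p = compare_groups(a, a.copy(), design="paired_t")
    assert (t, p) == (0.0, 1.0)
    g1, g2 = rng.standard_normal(6) + 0.5, rng.standard_normal(6)
    t2, p2 = compare_groups(g1, g2, design="independent_t")
    f, pf = compare_groups(None, None, design="anova", groups=[g1, g2])
    assert np.isclose(f, t2 ** 2)
    assert np.isclose(pf, p2)
    # hand-computable 3 + 3 sample
    x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
    t3, _ = compare_groups(x, y, design="independent_t")
    sp = np.sqrt(((x.var(ddof=1) + y.var(ddof=1)) / 2) * (2 / 3))
    assert np.isclose(t3, (x.mean() - y.mean()) / sp)
    with pytest.raises(AnalysisError):
        compare_groups(a, a, design="nonsense")
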
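import numpy as np
import pytest

from ml2motif import (
    FunctionScorer,
    TrainedWdSvm,
    exact_poim,
    instance_explanation,
    sample_gpoim,
)
from ml2motif._kmers import digit_matrix, window_codes


def enumeration_poim(model, k, centered=True):
    """Independent oracle: average s over all 4^L sequences grouped by (y, j)."""
    L = model.L
    codes_all = digit_matrix(L).astype(np.int8)
    scores = model.score_codes(codes_all)
    wc = window_codes(codes_all, k)
    n_pos = L - k + 1
    vals = np.zeros((4**k, n_pos))
    for j in range(n_pos):
        cnt = np.bincount(wc[:, j], minlength=4**k)
        vals[:, j] = np.bincount(wc[:, j], weights=scores, minlength=4**k) / cnt
    if centered:
        vals -= scores.mean()
    return vals


def test_constant_scorer_conditional_means():
    const = FunctionScorer(lambda x: 5.0, L=5, name="const")
    g = sample_gpoim(const, k=2, n=500, seed=0, centered=False)
    assert np.allclose(g.values[g.defined], 5.0)
    gc = sample_gpoim(const, k=2, n=500, seed=0, centered=True)
    assert np.allclose(gc.values[gc.defined], 0.0, atol=1e-12)


def test_count_scorer_linearity_of_expectation():
    # s(x) = #A; E[s | X_1 = A] = 1 + 2/4, E[s | X_1 = C] = 2/4
    count_a = FunctionScorer(lambda x: float(x.count("A")), L=3, name="countA")
    g = sample_gpoim(count_a, k=1, n=40000, seed=1, centered=False)
    assert g.values[0, 0] == pytest.approx(1.5, abs=0.05)
    assert g.values[1, 0] == pytest.approx(0.5, abs=0.05)


def test_exact_poim_single_weight_entry():
    # s(X) = 1{X_1 = A}: Q_{1,A,1} = 3/4, Q_{1,C,1} = -1/4, position 2 flat
    table = np.zeros((4, 2))
    table[0, 0] = 1.0
    model = TrainedWdSvm(
        ell_max=1, L=2, tables={1: table}, intercept=0.0,
        sv_codes=np.zeros((1, 2), dtype=np.int8), dual_coef=np.ones(1),
    )
    q = exact_poim(model, k=1, centered=True)
    assert q.values[0, 0] == pytest.approx(0.75)
    assert q.values[1, 0] == pytest.approx(-0.25)
    assert np.allclose(q.values[:, 1], 0.0)


def test_exact_poim_law_of_total_expectation(toy_svm):
    for k in (1, 2, 3):
        q = exact_poim(toy_svm, k=k, centered=True)
        assert np.abs(q.values.mean(axis=0)).max() < 1e-10


def test_exact_poim_matches_exhaustive_enumeration(toy_svm):
    for k in (1, 2):
        for centered in (True, False):
            q = exact_poim(toy_svm, k=k, centered=centered)
            oracle = enumeration_poim(toy_svm, k, centered=centered)
            assert np.abs(q.values - oracle).max() < 1e-8


def test_exact_poim_order_above_kernel_degree(toy_svm):
    # POIMs of higher order than the kernel are defined
    q = exact_poim(toy_svm, k=4, centered=True)
    oracle = enumeration_poim(toy_svm, 4)
    assert np.abs(q.values - oracle).max() < 1e-8


def test_exact_poim_enumeration_guard():
    table = np.zeros((4, 30))
    model = TrainedWdSvm(
        ell_max=1, L=30, tables={1: table}, intercept=0.0,
        sv_codes=np.zeros((1, 30), dtype=np.int8), dual_coef=np.ones(1),
    )
    with pytest.raises(ValueError, match="guard"):
        exact_poim(model, k=13)


def test_sampling_conservation(toy_svm):
    # uncentered: count-weighted mean of bin values = pool mean, per column
    g = sample_gpoim(toy_svm, k=2, n=3000, seed=4, centered=False)
    vals = np.where(g.defined, g.values, 0.0)
    col_means = (vals * g.counts).sum(axis=0) / g.n_samples
    assert np.abs(col_means - g.mean_score).max() < 1e-10


def test_bin_counts_partition_the_pool(toy_svm):
    g = sample_gpoim(toy_svm, k=2, n=1000, seed=5)
    assert np.all(g.counts.sum(axis=0) == g.n_samples)


def test_centering_invariant_under_score_bias(toy_svm):
    shifted = FunctionScorer(
        lambda x: toy_svm(x) + 100.0, L=8, name="shifted",
        batch_fn=lambda xs: toy_svm.score_batch(xs) + 100.0,
    )
    a = sample_gpoim(toy_svm, k=2, n=2000, seed=6, centered=True)
    b = sample_gpoim(shifted, k=2, n=2000, seed=6, centered=True)
    assert np.nanmax(np.abs(a.values - b.values)) < 1e-8
    ea = exact_poim(toy_svm, k=2, centered=True)
    shifted_model = TrainedWdSvm(
        ell_max=toy_svm.ell_max, L=toy_svm.L, tables=toy_svm.tables,
        intercept=toy_svm.intercept + 100.0, sv_codes=toy_svm.sv_codes,
        dual_coef=toy_svm.dual_coef,
    )
    eb = exact_poim(shifted_model, k=2, centered=True)
    assert np.abs(ea.values - eb.values).max() < 1e-12


def test_monotone_order_consistency_exact(toy_svm):
    # order-k cell = mean of its 4 order-(k+1) refinements sharing prefix y
    qk = exact_poim(toy_svm, k=2, centered=False)
    qk1 = exact_poim(toy_svm, k=3, centered=False)
    for j in range(qk1.values.shape[1]):
        refined = qk1.values[:, j].reshape(16, 4).mean(axis=1)
        assert np.abs(refined - qk.values[:, j]).max() < 1e-10


def test_sampling_error_shrinks_as_root_n(toy_svm):
    exact = exact_poim(toy_svm, k=2, centered=True)
    ratios = []
    for seed in range(10):
        errs = []
        for n in (1500, 6000):
            g = sample_gpoim(toy_svm, k=2, n=n, seed=seed, centered=True)
            errs.append(np.nanmax(np.abs(g.values - exact.values)))
        ratios.append(errs[0] / errs[1])
    mean_ratio = np.mean(ratios)
    # quadrupling n should halve the max error, within a factor 1.5
    assert 2 / 1.5 <= mean_ratio <= 2 * 1.5


def test_empty_bins_flagged_not_zero():
    const = FunctionScorer(lambda x: 1.0, L=6, name="const")
    with pytest.warns(UserWarning, match="empty"):
        g = sample_gpoim(const, k=3, n=20, seed=0)
    assert np.isnan(g.values[~g.defined]).all()
    assert (~g.defined).any()


def test_instance_explanation_constant_scorer():
    const = FunctionScorer(lambda x: 2.0, L=6, name="const")
    expl = instance_explanation(const, "ACGTAC", k=2, n=500, seed=0)
    defined = ~np.isnan(expl.position_scores)
    assert np.allclose(expl.position_scores[defined], 0.0, atol=1e-12)
    assert expl.score == 2.0


def test_instance_explanation_localizes_relevant_position():
    s = FunctionScorer(lambda x: 1.0 if x[0] == "A" else 0.0, L=5, name="first_a")
    expl = instance_explanation(s, "ACGTA", k=1, n=20000, seed=1)
    assert expl.position_scores[0] == pytest.approx(0.75, abs=0.05)
    assert np.abs(expl.position_scores[1:]).max() < 0.05


def test_instance_explanation_window_start_mode():
    s = FunctionScorer(lambda x: float(x.count("G")), L=6, name="countG")
    expl = instance_explanation(s, "GGGGGG", k=2, n=4000, seed=2,
                                aggregate="start")
    assert len(expl.window_scores) == 5
    assert np.isnan(expl.position_scores[-1])  # no window starts at L
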
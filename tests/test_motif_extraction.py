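import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ml2motif import (
    FitConfig,
    GPoim,
    MotifLocus,
    Ppm,
    compute_offset,
    fit_motifs,
    motif_weight,
    motifpoim_matrix,
    objective,
    sub_ppm,
    uniform_ppm,
)
from ml2motif.motif_extraction import _project_simplex_columns

from conftest import one_hot


def make_s(k, L, values, counts=None):
    return GPoim(k=k, L=L, values=values, counts=counts,
                 n_samples=0 if counts is None else int(counts.sum(axis=0)[0]),
                 centered=True)


# ------------------------------------------------------------- motif weight


def test_motif_weight_reference_values():
    assert motif_weight(uniform_ppm(3, 1), "ACG") == pytest.approx(1 / 64)
    hot = Ppm(one_hot("ACG"), 1)
    assert motif_weight(hot, "ACG") == 1.0
    assert motif_weight(hot, "ACT") == 0.0
    half = Ppm(np.array([[0.5, 0.5], [0.5, 0.5], [0, 0], [0, 0.0]]), 1)
    assert motif_weight(half, "AA") == pytest.approx(0.25)
    with pytest.raises(ValueError):
        motif_weight(hot, "AC")


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_motif_weights_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    p = Ppm(rng.dirichlet(np.ones(4), size=3).T, 1)
    total = sum(
        motif_weight(p, a + b + c)
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
    )
    assert total == pytest.approx(1.0)


# ------------------------------------------------------------------ sub_ppm


def test_sub_ppm_windows():
    p = Ppm(one_hot("ACGTA"), 3)
    full = sub_ppm(p, 0, 5)
    assert np.array_equal(full.r, p.r) and full.mu == p.mu
    win = sub_ppm(p, 1, 3)
    assert win.mu == 4
    assert win.argmax_sequence() == "CGT"
    u = uniform_ppm(5, 1)
    assert np.allclose(sub_ppm(u, 2, 2).r, 0.25)
    with pytest.raises(ValueError):
        sub_ppm(p, 3, 3)


# --------------------------------------------------------- motifPOIM matrix


def test_motifpoim_columns_sum_to_covering_motifs():
    rng = np.random.default_rng(2)
    p = Ppm(rng.dirichlet(np.ones(4), size=6).T, 4)
    R = motifpoim_matrix([p], 3, 12)
    sums = R.sum(axis=0)
    for i in range(10):  # columns 1..10 (1-based i+1)
        expected = 1.0 if 4 <= i + 1 <= 9 else 0.0
        assert sums[i] == pytest.approx(expected)


def test_motifpoim_one_hot_window():
    p = Ppm(one_hot("CCTATA"), 11)
    R = motifpoim_matrix([p], 3, 30, env_mode="complete")
    col = R[:, 10]  # i = 11
    from ml2motif._kmers import kmer_index

    assert col[kmer_index("CCT")] == 1.0
    assert col.sum() == 1.0


def test_motifpoim_empty_and_errors():
    assert np.all(motifpoim_matrix([], 3, 10) == 0.0)
    with pytest.raises(ValueError):
        motifpoim_matrix([uniform_ppm(4, 9)], 3, 10)  # overflows L
    with pytest.raises(ValueError):
        motifpoim_matrix([uniform_ppm(2, 1)], 3, 10)  # k_tilde > motif


# ------------------------------------------------------------------- offset


@pytest.mark.parametrize("s_min,expected", [(-2.0, 3.0), (1.5, 0.0), (0.0, 1.0)])
def test_compute_offset_rule(s_min, expected):
    values = np.full((4, 2), max(2.0, s_min))
    values[0, 0] = s_min
    S = GPoim(k=1, L=2, values=values, counts=None, n_samples=0, centered=True)
    assert compute_offset(S) == expected
    assert np.all(S.values + compute_offset(S) >= 1.0)


def test_compute_offset_all_missing_rejected():
    vals = np.full((4, 2), np.nan)
    S = GPoim(k=1, L=2, values=vals, counts=np.zeros((4, 2), dtype=int),
              n_samples=4, centered=True)
    with pytest.raises(ValueError):
        compute_offset(S)


# ---------------------------------------------------------------- objective


def test_objective_zero_when_reconstruction_matches():
    p = uniform_ppm(3, 2)
    c = 1.0
    R = motifpoim_matrix([p], 3, 8)
    values = R.copy()
    env = values.sum(axis=0) > 0
    values[:, env] -= c  # S = R - c in-environment, 0 elsewhere
    S = make_s(3, 8, values)
    assert objective([p], S, c, 3) == pytest.approx(0.0, abs=1e-16)


def test_objective_no_motifs_is_half_frobenius():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(16, 5))
    S = make_s(2, 6, values)
    assert objective([], S, 1.0, 2) == pytest.approx(0.5 * np.sum(values**2))


def test_objective_ignores_missing_entries():
    values = np.full((16, 5), np.nan)
    counts = np.zeros((16, 5), dtype=int)
    values[3, 2] = 0.5
    counts[3, 2] = 7
    S = GPoim(k=2, L=6, values=values, counts=counts, n_samples=7,
              centered=True)
    assert objective([], S, 1.0, 2) == pytest.approx(0.5 * 0.25)


# --------------------------------------------------------- simplex projection


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_simplex_projection_properties(seed):
    rng = np.random.default_rng(seed)
    r = rng.normal(scale=2.0, size=(4, 3))
    proj = _project_simplex_columns(r)
    assert np.all(proj >= 0)
    assert np.allclose(proj.sum(axis=0), 1.0, atol=1e-12)
    # idempotent and exact on feasible input
    again = _project_simplex_columns(proj)
    assert np.allclose(again, proj, atol=1e-12)
    feasible = rng.dirichlet(np.ones(4), size=3).T
    assert np.allclose(_project_simplex_columns(feasible), feasible, atol=1e-12)


# ------------------------------------------------------------------ fitting


@pytest.fixture(scope="module")
def synthetic_fit_problem():
    """Order-2 importance matrix generated from a known planted motif PWM."""
    truth = Ppm(one_hot("ACGT"), 3)
    c = 2.0
    R = motifpoim_matrix([truth], 2, 10)
    values = R.copy()
    env = values.sum(axis=0) > 0
    values[:, env] -= c
    return truth, make_s(2, 10, values)


def test_fit_recovers_planted_pwm(synthetic_fit_problem):
    truth, S = synthetic_fit_problem
    res = fit_motifs(S, [MotifLocus(3, 4, 0.0)], FitConfig(k_tilde=2))
    assert res.converged
    assert np.abs(res.ppms[0].r - truth.r).max() < 1e-4
    # descent contract: trace is non-increasing
    trace = np.asarray(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-12)
    # feasibility of the result
    assert np.all(res.ppms[0].r >= 0)
    assert np.allclose(res.ppms[0].r.sum(axis=0), 1.0, atol=1e-9)


def test_fit_offset_invariance_synthetic(synthetic_fit_problem):
    _, S = synthetic_fit_problem
    locus = [MotifLocus(3, 4, 0.0)]
    base = fit_motifs(S, locus, FitConfig(k_tilde=2))
    for dc in (1.0, 10.0):
        alt = fit_motifs(S, locus, FitConfig(k_tilde=2, c=base.c_used + dc))
        assert np.abs(alt.ppms[0].r - base.ppms[0].r).max() < 1e-4


def test_fit_random_inits_agree(synthetic_fit_problem):
    _, S = synthetic_fit_problem
    locus = [MotifLocus(3, 4, 0.0)]
    base = fit_motifs(S, locus, FitConfig(k_tilde=2))
    for seed in range(5):
        alt = fit_motifs(S, locus, FitConfig(k_tilde=2, init="random", seed=seed))
        assert abs(alt.objective_trace[-1] - base.objective_trace[-1]) < 1e-6


def test_fit_empty_loci_and_validation(synthetic_fit_problem):
    _, S = synthetic_fit_problem
    res = fit_motifs(S, [], FitConfig(k_tilde=2))
    assert res.ppms == [] and res.converged
    with pytest.raises(ValueError):
        fit_motifs(S, [MotifLocus(9, 4, 0.0)], FitConfig(k_tilde=2))
    with pytest.raises(ValueError):
        fit_motifs(S, [MotifLocus(1, 1, 0.0)], FitConfig(k_tilde=2))
    with pytest.raises(ValueError):
        fit_motifs(S, [MotifLocus(1, 4, 0.0)], FitConfig(k_tilde=3))


def test_ppm_validation():
    with pytest.raises(ValueError):
        Ppm(np.full((4, 2), 0.3), 1)
    with pytest.raises(ValueError):
        Ppm(np.full((3, 2), 1 / 3), 1)
    with pytest.raises(ValueError):
        Ppm(np.full((4, 2), 0.25), 0)
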
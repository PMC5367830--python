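"""Positional-oligomer importance matrices, sampled and exact.

The model-based importance of k-mer y at position j for a scorer s is the
conditional expected score under a uniform i.i.d. background X over Sigma^L,

    S_{k,y,j} = E[s(X) | X[j]^k = y]      (optionally centered by E[s(X)]).

``sample_gpoim`` estimates every entry from one shared Monte-Carlo pool:
each sampled sequence z contributes s(z) to bin (z[j]^k, j) for every
window j, so the estimate is the bin-restricted mean score.  Empty bins are
flagged as missing (NaN), never as zero — a zero would fabricate
importance.

``exact_poim`` evaluates the same quantity analytically for WD-kernel SVMs
from their positional-oligomer weight table: a stored weight w(z, i) of
length l contributes w(z,i) * P(X[i]^l = z | X[j]^k = y) under the uniform
background — zero if the overlapping letters conflict, else (1/4)^(free
positions) — while non-overlapping terms contribute their unconditional
mean and cancel under centering.

``instance_explanation`` reuses the same estimator to answer why one
specific sequence g received its score: it reads the bins (g[i]^k, i) of an
uncentered sampled matrix and aggregates them per position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kmers import seq_to_codes, window_codes
from .scorers import Scorer, TrainedWdSvm


@dataclass
class GPoim:
    """Importance values S_{k,y,j} with sampling metadata.

    ``values`` has shape (4**k, L-k+1) with NaN marking empty bins;
    ``counts`` holds bin occupancies (None for analytically computed
    matrices, where every entry is defined).
    """

    k: int
    L: int
    values: np.ndarray
    counts: "np.ndarray | None"
    n_samples: int
    centered: bool
    seed: "int | None" = None
    scorer_name: str = ""
    mean_score: float = 0.0

    def __post_init__(self) -> None:
        expected = (4**self.k, self.L - self.k + 1)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")

    @property
    def n_positions(self) -> int:
        return self.L - self.k + 1

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of defined (non-empty-bin) entries."""
        if self.counts is None:
            return np.ones_like(self.values, dtype=bool)
        return self.counts > 0


def _uniform_sampler(rng: np.random.Generator, n: int, L: int) -> np.ndarray:
    return rng.integers(0, 4, size=(n, L), dtype=np.int8)


def _pool_scores(scorer: Scorer, codes: np.ndarray) -> np.ndarray:
    if hasattr(scorer, "score_codes"):
        return np.asarray(scorer.score_codes(codes), dtype=float)
    from ._kmers import codes_to_seq

    return scorer.score_batch([codes_to_seq(row) for row in codes])


def sample_gpoim(scorer: Scorer, L: "int | None" = None, k: int = 2,
                 n: int = 1000, seed: int = 0, centered: bool = True,
                 background=None) -> GPoim:
    """Monte-Carlo estimate of the importance matrix from one sample pool.

    Draws ``n`` i.i.d. sequences (uniform over Sigma^L unless a
    ``background(rng, n, L) -> codes`` sampler is supplied), scores them
    once through the scorer contract, and bins the scores by every
    positional k-mer window.
    """
    L = L if L is not None else scorer.L
    if not 1 <= k <= L:
        raise ValueError("order k must satisfy 1 <= k <= L")
    if n < 1:
        raise ValueError("need at least one sample")
    if n < 4**k:
        warnings.warn(
            f"n={n} < 4^{k}={4**k}: many bins will be empty (flagged as missing)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    sampler = background if background is not None else _uniform_sampler
    codes = sampler(rng, n, L)
    scores = _pool_scores(scorer, codes)

    n_pos = L - k + 1
    sums = np.zeros((4**k, n_pos))
    counts = np.zeros((4**k, n_pos), dtype=np.int64)
    wc = window_codes(codes, k)
    for j in range(n_pos):
        counts[:, j] = np.bincount(wc[:, j], minlength=4**k)
        sums[:, j] = np.bincount(wc[:, j], weights=scores, minlength=4**k)
    with np.errstate(invalid="ignore"):
        values = sums / counts
    values[counts == 0] = np.nan
    mean_score = float(scores.mean())
    if centered:
        values[counts > 0] -= mean_score
    return GPoim(k=k, L=L, values=values, counts=counts, n_samples=n,
                 centered=centered, seed=seed, scorer_name=scorer.name,
                 mean_score=mean_score)


_MAX_EXACT_ENTRIES = 10**7


def exact_poim(m: TrainedWdSvm, k: int, centered: bool = True) -> GPoim:
    """Analytic importance matrix of a WD-SVM from its weight table.

    Exact conditional expectations under the uniform i.i.d. background;
    valid for any order k >= 1, including k above the kernel degree.
    """
    L = m.L
    if k < 1:
        raise ValueError("order k must be >= 1")
    n_pos = L - k + 1
    if n_pos < 1:
        raise ValueError("order k exceeds sequence length")
    if (4**k) * n_pos > _MAX_EXACT_ENTRIES:
        raise ValueError(
            f"exact enumeration of 4^{k} x {n_pos} entries exceeds the "
            f"{_MAX_EXACT_ENTRIES} guard"
        )
    values = np.zeros((4**k, n_pos))
    view = values.reshape((4,) * k + (n_pos,))
    total_mean = m.intercept
    for ell, table in m.tables.items():
        q = 0.25**ell
        col_sums = table.sum(axis=0)  # sum_z w(z, i)
        total_mean += float(col_sums.sum()) * q
        for i in range(table.shape[1]):  # 0-based weight window start
            col = table[:, i]
            if not np.any(col):
                continue
            W = col.reshape((4,) * ell)
            w_mean = col_sums[i] * q
            for j in range(max(0, i - k + 1), min(n_pos, i + ell)):
                a, b = max(i, j), min(i + ell, j + k)  # overlap [a, b)
                o = b - a
                keep = tuple(range(a - i, b - i))
                drop = tuple(ax for ax in range(ell) if ax not in keep)
                marg = W.sum(axis=drop) if drop else W
                shape = (1,) * (a - j) + (4,) * o + (1,) * (k - (b - j)) + (1,)
                contrib = marg.reshape(shape) * (0.25 ** (ell - o)) - w_mean
                view[..., j : j + 1] += contrib
    if not centered:
        values += total_mean
    return GPoim(k=k, L=L, values=values, counts=None, n_samples=0,
                 centered=centered, seed=None, scorer_name=m.name,
                 mean_score=total_mean)


@dataclass
class PositionImportance:
    """Instance-based explanation: why did sequence g get its score?"""

    sequence: str
    k: int
    position_scores: np.ndarray  # length L, NaN where no window is defined
    window_scores: np.ndarray  # length L-k+1, centered, NaN where bin empty
    score: float
    seed: "int | None" = None
    scorer_name: str = ""
    pool: "GPoim | None" = field(default=None, repr=False)


def default_explanation_order(scorer: Scorer) -> int:
    """ell_max - 2 capped at 6 for WD models; 3 for generic scorers."""
    ell_max = getattr(scorer, "ell_max", None)
    if ell_max is None:
        return 3
    return max(1, min(6, ell_max - 2))


def instance_explanation(scorer: Scorer, g: str, k: "int | None" = None,
                         n: int = 10000, seed: int = 0,
                         aggregate: str = "mean") -> PositionImportance:
    """Per-position importance of the k-mers of one sequence for its score.

    Samples one shared pool, reads the bins matching each window of ``g``,
    subtracts the pool's mean score so irrelevant positions sit near zero,
    and aggregates window scores per position (``mean`` over all covering
    windows, or ``start`` for window-start only).
    """
    L = len(g)
    if scorer.L and L != scorer.L:
        raise ValueError(f"expected sequence of length {scorer.L}, got {L}")
    if k is None:
        k = default_explanation_order(scorer)
    if not 1 <= k <= L:
        raise ValueError("order k must satisfy 1 <= k <= L")
    pool = sample_gpoim(scorer, L=L, k=k, n=n, seed=seed, centered=False)
    g_codes = window_codes(seq_to_codes(g), k)
    win = pool.values[g_codes, np.arange(pool.n_positions)] - pool.mean_score

    position_scores = np.full(L, np.nan)
    if aggregate == "start":
        position_scores[: pool.n_positions] = win
    elif aggregate == "mean":
        for p in range(L):
            lo, hi = max(0, p - k + 1), min(pool.n_positions - 1, p)
            vals = win[lo : hi + 1]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                position_scores[p] = vals.mean()
    else:
        raise ValueError("aggregate must be 'mean' or 'start'")
    return PositionImportance(
        sequence=g, k=k, position_scores=position_scores, window_scores=win,
        score=float(scorer(g)), seed=seed, scorer_name=scorer.name, pool=pool,
    )
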
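"""Weighted-degree string kernel, WD-SVM training, and the scorer contract.

The weighted-degree (WD) kernel compares two equal-length DNA sequences by
counting matching positional substrings of every length up to ``ell_max``:

    kappa(x, x') = sum_{l=1..ell_max} sum_{j=1..L-l+1} 1{x[j..j+l-1] = x'[j..j+l-1]}

The sum is unweighted across degrees (per-degree weights are available
behind the ``degree_weights`` flag, defaulting to all ones).  A WD-kernel
SVM's scoring function decomposes into a sum over positional-oligomer
weights,

    s(x) = sum_l sum_j w(x[j]^l, j) + b,

which this module materializes explicitly (the ``weight table``) so that
scoring is O(ell_max * L) per sequence and exact importance computations
are possible downstream.  The bias b is kept out of the table; it shifts
every conditional expectation equally and cancels in centered importance
matrices.

Any classifier can be explained through the generic :class:`Scorer`
contract — a deterministic callable on length-L ACGT strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from ._kmers import seq_to_codes, seqs_to_codes, window_codes, index_to_kmer


class Scorer:
    """Contract: a deterministic map from length-L ACGT strings to reals.

    Subclasses implement ``__call__``; ``score_batch`` loops by default and
    may be overridden for vectorized models.  ``score_codes`` (optional)
    accepts an (n, L) int8 code matrix for zero-copy batch scoring.
    """

    L: int = 0
    name: str = "scorer"

    def __call__(self, x: str) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def score_batch(self, xs) -> np.ndarray:
        return np.array([self(x) for x in xs], dtype=float)


class FunctionScorer(Scorer):
    """Wrap an arbitrary callable (e.g. an external network) as a Scorer."""

    def __init__(self, fn, L: int, name: str = "function", batch_fn=None):
        self.fn = fn
        self.L = L
        self.name = name
        self._batch_fn = batch_fn

    def __call__(self, x: str) -> float:
        if len(x) != self.L:
            raise ValueError(f"expected sequence of length {self.L}, got {len(x)}")
        return float(self.fn(x))

    def score_batch(self, xs) -> np.ndarray:
        if self._batch_fn is not None:
            return np.asarray(self._batch_fn(xs), dtype=float)
        return super().score_batch(xs)


def _check_pair(x: str, x2: str):
    if len(x) != len(x2):
        raise ValueError(f"sequences must have equal length ({len(x)} != {len(x2)})")
    return seq_to_codes(x), seq_to_codes(x2)


def _degree_cumsum(ell_max: int, degree_weights) -> np.ndarray:
    """cum[r] = sum of degree weights beta_1..beta_min(r, ell_max)."""
    if degree_weights is None:
        beta = np.ones(ell_max)
    else:
        beta = np.asarray(degree_weights, dtype=float)
        if beta.shape != (ell_max,):
            raise ValueError("degree_weights must have length ell_max")
    return np.concatenate([[0.0], np.cumsum(beta)])


def wd_kernel(x: str, x2: str, ell_max: int, degree_weights=None) -> float:
    """Weighted-degree kernel value between two equal-length sequences.

    With unit degree weights the result is the integer count of matching
    positional substrings up to length ``ell_max``.
    """
    a, b = _check_pair(x, x2)
    L = len(a)
    if not 1 <= ell_max <= L:
        raise ValueError("ell_max must satisfy 1 <= ell_max <= L")
    cum = _degree_cumsum(ell_max, degree_weights)
    # A maximal run of m consecutive matching positions contains
    # min(run-length-ending-here, ell_max) matching windows per endpoint.
    run = 0
    total = 0.0
    for j in range(L):
        run = run + 1 if a[j] == b[j] else 0
        total += cum[min(run, ell_max)]
    if degree_weights is None:
        return int(round(total))
    return float(total)


def wd_gram(codes_a: np.ndarray, codes_b: np.ndarray, ell_max: int,
            degree_weights=None, block: int = 2048) -> np.ndarray:
    """WD-kernel Gram matrix between code matrices (na, L) and (nb, L).

    Runs position-by-position with a running-match-length recurrence, so
    memory is O(block * nb) independent of ell_max.
    """
    codes_a = np.atleast_2d(codes_a)
    codes_b = np.atleast_2d(codes_b)
    L = codes_a.shape[1]
    if codes_b.shape[1] != L:
        raise ValueError("sequence length mismatch between the two sets")
    if not 1 <= ell_max <= L:
        raise ValueError("ell_max must satisfy 1 <= ell_max <= L")
    cum = _degree_cumsum(ell_max, degree_weights)
    na, nb = codes_a.shape[0], codes_b.shape[0]
    gram = np.empty((na, nb), dtype=float)
    for start in range(0, na, block):
        stop = min(start + block, na)
        ca = codes_a[start:stop]
        run = np.zeros((stop - start, nb), dtype=np.int32)
        acc = np.zeros((stop - start, nb), dtype=float)
        for j in range(L):
            eq = ca[:, j, None] == codes_b[None, :, j]
            run += 1
            run *= eq
            acc += cum[np.minimum(run, ell_max)]
        gram[start:stop] = acc
    return gram


class TrainedWdSvm(Scorer):
    """A trained WD-kernel SVM with an explicit positional-oligomer weight table.

    ``tables[l]`` is the dense array of weights w(y, j) for oligomer length
    ``l`` (shape (4**l, L-l+1)); ``sv_codes``/``dual_coef`` retain the
    support expansion so the kernel-expansion score remains available as an
    independent evaluation path.
    """

    def __init__(self, ell_max: int, L: int, tables: dict, intercept: float,
                 sv_codes: np.ndarray, dual_coef: np.ndarray,
                 degree_weights=None, meta=None, name: str = "wd_svm"):
        self.ell_max = ell_max
        self.L = L
        self.tables = tables
        self.intercept = intercept
        self.sv_codes = sv_codes
        self.dual_coef = dual_coef
        self.degree_weights = degree_weights
        self.meta = meta if meta is not None else {}
        self.name = name

    def __call__(self, x: str) -> float:
        return float(self.score_codes(seq_to_codes(x)[None, :])[0])

    def score_batch(self, xs) -> np.ndarray:
        return self.score_codes(seqs_to_codes(list(xs)))

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Weight-table evaluation of s for an (n, L) code matrix."""
        codes = np.atleast_2d(codes)
        if codes.shape[1] != self.L:
            raise ValueError(f"expected sequences of length {self.L}, got {codes.shape[1]}")
        out = np.full(codes.shape[0], self.intercept, dtype=float)
        for ell, table in self.tables.items():
            wc = window_codes(codes, ell)  # (n, L-ell+1)
            cols = np.arange(wc.shape[1])
            out += table[wc, cols].sum(axis=1)
        return out

    def score_kernel(self, x: str) -> float:
        """Support-expansion evaluation of s (independent of the table)."""
        codes = seq_to_codes(x)[None, :]
        k = wd_gram(self.sv_codes, codes, self.ell_max, self.degree_weights)[:, 0]
        return float(self.dual_coef @ k + self.intercept)

    def weight_table(self) -> dict:
        """Sparse view {(oligomer, 1-based position): weight} of nonzeros."""
        out = {}
        for ell, table in self.tables.items():
            ys, js = np.nonzero(table)
            for y, j in zip(ys, js):
                out[(index_to_kmer(int(y), ell), int(j) + 1)] = float(table[y, j])
        return out

    def save(self, path) -> None:
        arrays = {f"table_{ell}": tab for ell, tab in self.tables.items()}
        arrays["sv_codes"] = self.sv_codes
        arrays["dual_coef"] = self.dual_coef
        if self.degree_weights is not None:
            arrays["degree_weights"] = self.degree_weights
        header = {
            "ell_max": self.ell_max,
            "L": self.L,
            "intercept": self.intercept,
            "meta": self.meta,
            "name": self.name,
        }
        arrays["header_json"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedWdSvm":
        with np.load(path) as data:
            header = json.loads(bytes(data["header_json"]).decode())
            tables = {
                int(key.split("_")[1]): data[key]
                for key in data.files
                if key.startswith("table_")
            }
            return cls(
                ell_max=header["ell_max"],
                L=header["L"],
                tables=tables,
                intercept=header["intercept"],
                sv_codes=data["sv_codes"],
                dual_coef=data["dual_coef"],
                degree_weights=data["degree_weights"] if "degree_weights" in data.files else None,
                meta=header["meta"],
                name=header["name"],
            )


def score(scorer: Scorer, x: str) -> float:
    """Evaluate a scorer on a single sequence (length-checked plumbing)."""
    if scorer.L and len(x) != scorer.L:
        raise ValueError(f"expected sequence of length {scorer.L}, got {len(x)}")
    return float(scorer(x))


def _build_tables(sv_codes: np.ndarray, dual_coef: np.ndarray, ell_max: int,
                  L: int, degree_weights=None) -> dict:
    """Materialize w(y, j) = sum_i alpha_i y_i 1{x_i[j]^l = y} per length l."""
    beta = np.ones(ell_max) if degree_weights is None else np.asarray(degree_weights, float)
    tables = {}
    for ell in range(1, ell_max + 1):
        table = np.zeros((4**ell, L - ell + 1))
        wc = window_codes(sv_codes, ell)
        cols = np.broadcast_to(np.arange(wc.shape[1]), wc.shape)
        np.add.at(table, (wc.ravel(), cols.ravel()),
                  np.repeat(dual_coef * beta[ell - 1], wc.shape[1]))
        tables[ell] = table
    return tables


def train_wd_svm(data, ell_max: int = 8, C: float = 1.0, seed: int = 0,
                 test_fraction: float = 0.2, max_train: "int | None" = None,
                 degree_weights=None) -> TrainedWdSvm:
    """Train a soft-margin SVM with a precomputed WD Gram matrix.

    The data are split train/test (default 80/20) with ``seed``; the held-out
    accuracy estimate is recorded in ``meta``.  ``max_train`` optionally caps
    the training-set size (the Gram matrix is quadratic in it).
    """
    labels = np.asarray(data.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least one example of each label")
    codes = data.codes
    n = len(labels)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if max_train is not None:
        train_idx = train_idx[:max_train]
    if len(np.unique(labels[train_idx])) < 2:
        raise ValueError("degenerate split: training fold contains a single class")

    gram = wd_gram(codes[train_idx], codes[train_idx], ell_max, degree_weights)
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(gram, labels[train_idx])
    if not np.all(np.isfinite(clf.dual_coef_)):
        raise RuntimeError("SVM solver returned non-finite dual coefficients")

    sv_codes = codes[train_idx][clf.support_]
    dual_coef = clf.dual_coef_[0].astype(float)
    tables = _build_tables(sv_codes, dual_coef, ell_max, data.L, degree_weights)
    model = TrainedWdSvm(
        ell_max=ell_max,
        L=data.L,
        tables=tables,
        intercept=float(clf.intercept_[0]),
        sv_codes=sv_codes,
        dual_coef=dual_coef,
        degree_weights=None if degree_weights is None else np.asarray(degree_weights, float),
        meta={"C": C, "seed": seed, "n_train": int(len(train_idx)),
              "n_test": int(n_test), "n_sv": int(len(dual_coef))},
    )
    if n_test > 0:
        test_scores = model.score_codes(codes[test_idx])
        pred = np.where(test_scores >= 0, 1, -1)
        model.meta["test_accuracy"] = float(np.mean(pred == labels[test_idx]))
    else:
        model.meta["test_accuracy"] = None
    train_scores = model.score_codes(codes[train_idx])
    model.meta["train_accuracy"] = float(
        np.mean(np.where(train_scores >= 0, 1, -1) == labels[train_idx])
    )
    return model
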
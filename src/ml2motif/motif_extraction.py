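"""Convex PWM extraction by mimicking an importance matrix.

A probabilistic positional motif (PPM) is a pair (r, mu): a 4 x k
column-stochastic matrix r over {A, C, G, T} and a 1-based start position
mu.  The motif assigns every k-mer z the weight

    v_z(r) = prod_{l=1..k} r_{z_l, l},

and induces a reconstructed importance matrix ("motifPOIM")

    R_{z,i} = sum_motifs 1{i in U(m)} * v_z(SubPPM(m, i - mu, k_tilde)),

where the environment U(m) covers every start column inside the motif,
U = [mu, ..., mu+k-1]; windows running past the motif end are
right-truncated and padded with the uniform background so a motif can
explain the importance of its own suffix k-mers (essential when motifs
overlap).  Fitting minimizes

    f(r) = 1/2 sum_{z,i} (R_{z,i} - (S_{k_tilde,z,i} + c * 1{i in env}))^2

over the product of column simplices, where S is a (sampled or exact)
importance matrix and c is an offset constant, c = max(0, 1 - min S), so
that S + c >= 1 on every entry.  Every in-environment column of R sums to
a constant over the feasible set, so the fitted motif does not depend on
c — an exported, testable contract.

A note on convexity: the objective is convex in the induced k-mer weight
vectors v (it is a quadratic), and convex in each PWM column separately,
but it is NOT jointly convex in the PWM entries — v is multilinear, and
the set of product-form weight vectors is non-convex, regardless of c.
In practice the landscape is benign: uniform and random initializations
converge to the same solution on all reference problems, which the test
suite checks.

Missing S entries (empty sampling bins) are excluded from the objective
entirely, so sampling sparsity never injects gradient.

The solver is projected gradient descent: analytic gradients of the
product terms, exact Euclidean projection of every column onto the
probability simplex, and Armijo backtracking line search (monotone
descent).  Simplex reparameterizations (e.g. softmax) are avoided to
keep the per-column quadratic structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import ALPHABET, digit_matrix, index_to_kmer
from .gpoim import GPoim


@dataclass
class Ppm:
    """A probabilistic positional motif: column-stochastic r plus start mu."""

    r: np.ndarray
    mu: int
    name: str = ""

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != 4:
            raise ValueError("r must be a 4 x k matrix (rows ordered A, C, G, T)")
        if np.any(self.r < -1e-12) or np.any(self.r > 1 + 1e-12):
            raise ValueError("PWM entries must lie in [0, 1]")
        if np.any(np.abs(self.r.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("every PWM column must sum to 1")
        if self.mu < 1:
            raise ValueError("start position mu must be >= 1")

    @property
    def k(self) -> int:
        return self.r.shape[1]

    @property
    def end(self) -> int:
        return self.mu + self.k - 1

    def argmax_sequence(self) -> str:
        """The highest-probability sequence of the motif."""
        return "".join(ALPHABET[i] for i in np.argmax(self.r, axis=0))


def uniform_ppm(k: int, mu: int, name: str = "") -> Ppm:
    return Ppm(np.full((4, k), 0.25), mu, name)


def motif_weight(p: Ppm, z: str) -> float:
    """v_z = product of PWM entries along z; sums to 1 over all z in Sigma^k."""
    if len(z) != p.k:
        raise ValueError(f"k-mer length {len(z)} != motif length {p.k}")
    idx = [ALPHABET.index(c) for c in z]
    return float(np.prod(p.r[idx, np.arange(p.k)]))


def sub_ppm(p: Ppm, offset: int, k_tilde: int) -> Ppm:
    """The length-k_tilde column window of p starting at column offset.

    ``offset`` is 0-based; the SubPPM starts at sequence position
    mu + offset.
    """
    if not 0 <= offset <= p.k - k_tilde:
        raise ValueError(
            f"SubPPM window (offset {offset}, length {k_tilde}) exceeds the "
            f"length-{p.k} PWM"
        )
    return Ppm(p.r[:, offset : offset + k_tilde].copy(), p.mu + offset, p.name)


def environment_columns(p: Ppm, k_tilde: int, L: "int | None" = None,
                        env_mode: str = "padded"):
    """1-based start columns i of the motif environment U.

    ``padded`` (default): every start position inside the motif,
    U = [mu, ..., mu + k - 1], clipped to valid matrix columns; windows
    running past the motif end are right-truncated and padded with the
    uniform background (1/4 per uncovered position), so the motif can
    explain the importance of its own suffix k-mers.  ``complete``:
    only offsets admitting a full k_tilde window, U = [mu, ..., mu+k-k_tilde].
    """
    if k_tilde > p.k:
        return range(0)
    if env_mode == "complete":
        return range(p.mu, p.mu + p.k - k_tilde + 1)
    if env_mode != "padded":
        raise ValueError("env_mode must be 'padded' or 'complete'")
    last = p.mu + p.k - 1
    if L is not None:
        last = min(last, L - k_tilde + 1)
    return range(p.mu, last + 1)


def _window_values(r_window: np.ndarray, digits: np.ndarray) -> np.ndarray:
    """v_z for all 4**k_tilde k-mers z of one SubPPM window."""
    k_tilde = r_window.shape[1]
    return np.prod(r_window[digits, np.arange(k_tilde)], axis=1)


def motifpoim_matrix(ppms, k_tilde: int, L: int,
                     env_mode: str = "padded") -> np.ndarray:
    """Reconstructed importance matrix R of shape (4**k_tilde, L-k_tilde+1).

    Every in-environment column of R sums to the number of motifs covering
    it (each window's weights sum to 1, including background-padded ones).
    """
    n_pos = L - k_tilde + 1
    if n_pos < 1:
        raise ValueError("k_tilde exceeds sequence length")
    R = np.zeros((4**k_tilde, n_pos))
    digits = digit_matrix(k_tilde)
    for p in ppms:
        if p.end > L:
            raise ValueError(f"motif at mu={p.mu} (length {p.k}) does not fit in L={L}")
        if k_tilde > p.k:
            raise ValueError("k_tilde must not exceed the motif length")
        for i in environment_columns(p, k_tilde, L, env_mode):
            off = i - p.mu
            keff = min(k_tilde, p.k - off)
            vals = _window_values(p.r[:, off : off + keff], digits[:, :keff])
            R[:, i - 1] += vals * 0.25 ** (k_tilde - keff)
    return R


def compute_offset(S: GPoim) -> float:
    """Offset c = max(0, 1 - min S) so that S + c >= 1 on every defined entry."""
    defined = S.values[S.defined]
    if defined.size == 0:
        raise ValueError("importance matrix has no defined entries")
    return float(max(0.0, 1.0 - defined.min()))


def _env_mask(ppms, k_tilde: int, L: int, env_mode: str = "padded") -> np.ndarray:
    mask = np.zeros(L - k_tilde + 1, dtype=bool)
    for p in ppms:
        for i in environment_columns(p, k_tilde, L, env_mode):
            mask[i - 1] = True
    return mask


def objective(ppms, S: GPoim, c: float, k_tilde: int,
              env_mode: str = "padded") -> float:
    """f = 1/2 sum over defined S entries of (R - (S + c * in_env))^2.

    The offset is applied only inside motif environments; out-of-environment
    residuals are the unshifted -S entries (constant with respect to r).
    """
    if S.k != k_tilde:
        raise ValueError(f"S has order {S.k}, expected k_tilde={k_tilde}")
    R = motifpoim_matrix(ppms, k_tilde, S.L, env_mode)
    target = np.where(S.defined, S.values, 0.0).copy()
    env = _env_mask(ppms, k_tilde, S.L, env_mode)
    target[:, env] += c
    resid = np.where(S.defined, R - target, 0.0)
    return float(0.5 * np.sum(resid**2))


@dataclass
class FitConfig:
    """Optimizer settings for PWM fitting.

    ``k_tilde`` is the SubPPM window length (must not exceed the order of
    the supplied importance matrix); ``c`` is the convexity offset
    ("auto" = compute_offset).  ``motifs_per_locus`` (T) stacks several
    PPMs at one locus; the summed reconstruction keeps the joint problem
    convex.
    """

    k_tilde: int = 6
    c: "float | str" = "auto"
    env_mode: str = "padded"
    motifs_per_locus: int = 1
    tol: float = 1e-14
    max_iters: int = 10000
    init: str = "uniform"  # or "random"
    seed: "int | None" = None
    armijo_sigma: float = 1e-4
    armijo_beta: float = 0.5


@dataclass
class FitResult:
    ppms: list
    objective_trace: list
    converged: bool
    c_used: float
    config: FitConfig = field(repr=False, default=None)


def _project_simplex_columns(r: np.ndarray) -> np.ndarray:
    """Euclidean projection of every column onto the probability simplex."""
    u = np.sort(r, axis=0)[::-1]
    css = np.cumsum(u, axis=0) - 1.0
    rho_idx = np.arange(1, r.shape[0] + 1)[:, None]
    cond = u - css / rho_idx > 0
    rho = np.sum(cond, axis=0)
    theta = css[rho - 1, np.arange(r.shape[1])] / rho
    return np.maximum(r - theta, 0.0)


class _FitProblem:
    """Precomputed structure for objective/gradient evaluation."""

    def __init__(self, S: GPoim, loci, cfg: FitConfig):
        self.k_tilde = cfg.k_tilde
        self.L = S.L
        self.n_pos = S.n_positions
        self.digits = digit_matrix(self.k_tilde)
        self.defined = S.defined
        # (mu, k) per PPM, flattened over loci x motifs_per_locus
        self.slots = []
        for locus in loci:
            if locus.position + locus.length - 1 > S.L:
                raise ValueError(
                    f"locus at {locus.position} (length {locus.length}) exceeds L={S.L}"
                )
            if locus.length < self.k_tilde:
                raise ValueError(
                    f"locus length {locus.length} is below k_tilde={self.k_tilde}"
                )
            for _ in range(cfg.motifs_per_locus):
                self.slots.append((locus.position, locus.length))
        # per-column list of (slot index, offset, effective window length)
        self.col_windows = [[] for _ in range(self.n_pos)]
        env = np.zeros(self.n_pos, dtype=bool)
        for s, (mu, k) in enumerate(self.slots):
            p = Ppm(np.full((4, k), 0.25), mu)
            for i in environment_columns(p, self.k_tilde, self.L, cfg.env_mode):
                off = i - mu
                self.col_windows[i - 1].append((s, off, min(self.k_tilde, k - off)))
                env[i - 1] = True
        self.env_cols = np.nonzero(env)[0]
        # constant part: defined out-of-environment cells contribute 1/2 S^2
        out_env = ~env
        vals = np.where(self.defined, S.values, 0.0)
        self.const = float(0.5 * np.sum(vals[:, out_env] ** 2))
        self.S_vals = S.values

    def targets(self, c: float):
        """Per environment column: defined z indices and S + c targets."""
        tg = {}
        for col in self.env_cols:
            defz = np.nonzero(self.defined[:, col])[0]
            tg[col] = (defz, self.S_vals[defz, col] + c)
        return tg

    def value_and_grad(self, rs, targets):
        k_t = self.k_tilde
        f = self.const
        grads = [np.zeros_like(r) for r in rs]
        for col in self.env_cols:
            defz, t = targets[col]
            if defz.size == 0:
                continue
            D = self.digits[defz]  # (nz, k_tilde)
            windows = self.col_windows[col]
            # per-window entry products P[w][z, l] = r_w[D[z,l], off+l];
            # windows truncated at the motif end carry a uniform-background
            # factor (1/4) per uncovered position
            prods = []
            vals = []
            for s, off, keff in windows:
                P = rs[s][D[:, :keff], np.arange(off, off + keff)]
                prods.append(P)
                vals.append(np.prod(P, axis=1) * 0.25 ** (k_t - keff))
            resid = np.sum(vals, axis=0) - t if windows else -t
            f += 0.5 * float(resid @ resid)
            for (s, off, keff), P in zip(windows, prods):
                # prefix/suffix products exclude one factor at a time
                pre = np.ones_like(P)
                if keff > 1:
                    pre[:, 1:] = np.cumprod(P[:, :-1], axis=1)
                suf = np.ones_like(P)
                if keff > 1:
                    suf[:, :-1] = np.cumprod(P[:, ::-1], axis=1)[:, ::-1][:, 1:]
                partial = pre * suf * resid[:, None] * 0.25 ** (k_t - keff)
                for l in range(keff):
                    np.add.at(grads[s][:, off + l], D[:, l], partial[:, l])
        return f, grads


def fit_motifs(S: GPoim, loci, cfg: "FitConfig | None" = None) -> FitResult:
    """Fit PWMs at the given loci to mimic the importance matrix S.

    Minimizes the offset objective by projected gradient descent with
    Armijo backtracking; initialization is uniform (1/4 everywhere) or
    random points on the column simplices (``cfg.init='random'`` with
    ``cfg.seed``).  Returns fitted PPMs, the per-iteration objective
    trace (non-increasing), and the offset actually used.
    """
    cfg = cfg or FitConfig()
    if not loci:
        return FitResult(ppms=[], objective_trace=[], converged=True,
                         c_used=0.0, config=cfg)
    if S.k != cfg.k_tilde:
        raise ValueError(f"S has order {S.k}, expected k_tilde={cfg.k_tilde}")
    c = compute_offset(S) if cfg.c == "auto" else float(cfg.c)
    problem = _FitProblem(S, loci, cfg)
    targets = problem.targets(c)

    if cfg.init == "uniform":
        rs = [np.full((4, k), 0.25) for (_, k) in problem.slots]
    elif cfg.init == "random":
        rng = np.random.default_rng(cfg.seed)
        rs = [rng.dirichlet(np.ones(4), size=k).T for (_, k) in problem.slots]
    else:
        raise ValueError("init must be 'uniform' or 'random'")

    f, grads = problem.value_and_grad(rs, targets)
    trace = [f]
    step = 1.0
    converged = False
    for _ in range(cfg.max_iters):
        if not all(np.all(np.isfinite(g)) for g in grads):
            raise RuntimeError("non-finite gradient encountered during fitting")
        accepted = False
        while step > 1e-18:
            new_rs = [
                _project_simplex_columns(r - step * g) for r, g in zip(rs, grads)
            ]
            delta = sum(
                float(np.sum(g * (nr - r)))
                for g, nr, r in zip(grads, new_rs, rs)
            )
            f_new, grads_new = problem.value_and_grad(new_rs, targets)
            if f_new <= f + cfg.armijo_sigma * delta:
                accepted = True
                break
            step *= cfg.armijo_beta
        if not accepted:
            converged = True
            break
        drop = f - f_new
        rs, f, grads = new_rs, f_new, grads_new
        trace.append(f)
        step /= cfg.armijo_beta  # allow the step to grow again
        if drop <= cfg.tol * max(1.0, abs(f)):
            converged = True
            break

    ppms = [
        Ppm(r, mu, name=f"motif_{idx}")
        for idx, (r, (mu, _)) in enumerate(zip(rs, problem.slots), start=1)
    ]
    return FitResult(ppms=ppms, objective_trace=trace, converged=converged,
                     c_used=c, config=cfg)
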
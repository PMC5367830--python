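"""Differential POIM: aggregate importances across orders; estimate loci.

The differential POIM Omega is a k_max x L matrix summarizing a stack of
centered importance matrices Q_1..Q_{k_max}: with
q_max^{l,j} = max_y |Q_{l,y,j}|,

    Omega_{l,j} = q_max^{l,j} - max(q_max^{l-1,j}, q_max^{l-1,j+1})   for l >= 2,
    Omega_{1,j} = 0.

A large Omega_{l,j} indicates that some oligomer of length l starting at
position j explains importance not already accounted for by shorter
oligomers at the same or the next position — which is exactly what a
planted motif of that length and start looks like.  Motif loci are read
off greedily from the largest remaining entries with overlap suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiffPoim:
    """Omega matrix indexed (l, j), both 1-based in the accessors."""

    omega: np.ndarray  # shape (k_max, L); row l-1 is order l
    k_max: int
    L: int

    def entry(self, l: int, j: int) -> float:
        """Omega_{l,j} with 1-based l and j."""
        return float(self.omega[l - 1, j - 1])

    def argmax(self) -> tuple:
        """(l, j) of the largest entry, 1-based; ties toward smaller j then l."""
        best = None
        for l in range(1, self.k_max + 1):
            for j in range(1, self.L - l + 2):
                key = (-self.omega[l - 1, j - 1], j, l)
                if best is None or key < best:
                    best = key
        return best[2], best[1]


@dataclass
class MotifLocus:
    """An estimated motif start position and length, 1-based inclusive."""

    position: int
    length: int
    score: float

    @property
    def end(self) -> int:
        return self.position + self.length - 1


def differential_poim(poims) -> DiffPoim:
    """Build Omega from centered importance matrices of orders 1..k_max.

    ``poims`` must cover every order 1..k_max on a common L, all centered.
    Missing (empty-bin) entries are skipped in the per-column max; a column
    with no defined entry yields q_max = 0.
    """
    if not poims:
        raise ValueError("no importance matrices supplied")
    by_order = {p.k: p for p in poims}
    k_max = max(by_order)
    L = poims[0].L
    for k in range(1, k_max + 1):
        if k not in by_order:
            raise ValueError(f"gap in the order range: no matrix of order {k}")
    if any(p.L != L for p in poims):
        raise ValueError("importance matrices have mixed sequence lengths")
    if any(not p.centered for p in poims):
        raise ValueError("differential POIM requires centered matrices")

    # q[l-1, j-1] = max_y |Q_{l,y,j}|, 0 where the column is out of range
    q = np.zeros((k_max, L))
    for l in range(1, k_max + 1):
        vals = np.abs(by_order[l].values)
        with np.errstate(all="ignore"):
            colmax = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=0)
        colmax[~np.isfinite(colmax)] = 0.0
        q[l - 1, : L - l + 1] = colmax

    omega = np.zeros((k_max, L))
    for l in range(2, k_max + 1):
        for j in range(1, L - l + 2):
            competitors = [q[l - 2, j - 1]]
            if j + 1 <= L - (l - 1) + 1:
                competitors.append(q[l - 2, j])
            omega[l - 1, j - 1] = q[l - 1, j - 1] - max(competitors)
    return DiffPoim(omega=omega, k_max=k_max, L=L)


def _overlap(pos_a: int, len_a: int, pos_b: int, len_b: int) -> int:
    return max(0, min(pos_a + len_a, pos_b + len_b) - max(pos_a, pos_b))


def estimate_motif_loci(d: DiffPoim, max_motifs: int,
                        min_rel_score: float = 0.05,
                        max_overlap_frac: float = 0.5,
                        block_frac: float = 0.5):
    """Greedy locus calls from Omega with block expansion and overlap suppression.

    A motif of length l0 <= k_max concentrates in a single Omega cell
    (l0, start); a motif longer than k_max saturates a contiguous run of
    cells at l = k_max covering its interior, whose left edge is the motif
    start and whose width w gives the length as w + l - 1.  The estimator
    therefore repeatedly takes the largest remaining cell (ties toward
    smaller j, then smaller l), expands it left and right over contiguous
    same-order cells with Omega >= ``block_frac`` of the peak, and emits
    the locus (block start, block width + l - 1).  Candidates whose span
    overlaps an accepted span by more than ``max_overlap_frac`` of the
    shorter length are suppressed; calling stops after ``max_motifs`` loci
    or when the next peak drops below ``min_rel_score`` of the first.
    """
    if max_motifs < 1:
        raise ValueError("max_motifs must be >= 1")
    cells = []
    for l in range(2, d.k_max + 1):
        for j in range(1, d.L - l + 2):
            cells.append((-d.omega[l - 1, j - 1], j, l))
    cells.sort()
    loci = []
    consumed = set()
    first_score = None
    for neg_score, j, l in cells:
        score = -neg_score
        if score <= 0:
            break
        if first_score is None:
            first_score = score
        elif score < min_rel_score * first_score:
            break
        if (l, j) in consumed:
            continue
        lo = hi = j
        while lo > 1 and d.omega[l - 1, lo - 2] >= block_frac * score:
            lo -= 1
        while hi < d.L - l + 1 and d.omega[l - 1, hi] >= block_frac * score:
            hi += 1
        length = hi - lo + l
        for jj in range(lo, hi + 1):
            consumed.add((l, jj))
        if any(
            _overlap(lo, length, acc.position, acc.length)
            > max_overlap_frac * min(length, acc.length)
            for acc in loci
        ):
            continue
        loci.append(MotifLocus(position=lo, length=length, score=score))
        if len(loci) >= max_motifs:
            break
    return loci
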
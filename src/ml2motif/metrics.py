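"""Evaluation metrics: motif reconstruction quality, matrix distances, accuracy.

Motif reconstruction quality (MRQ) compares a ground-truth PWM t with a
predicted PWM r of equal length k column by column:

    MRQ = sum_{p=1..k} [ 1/k - (1/(2k)) * sum_{c in ACGT} (t_{c,p} - r_{c,p})^2 ]

MRQ lies in [0, 1], equals 1 iff the PWMs are identical, and is reported
as a percentage in all tables and command-line output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_pwm(p) -> np.ndarray:
    r = p.r if hasattr(p, "r") else np.asarray(p, dtype=float)
    if r.ndim != 2 or r.shape[0] != 4:
        raise ValueError("PWM must be a 4 x k matrix")
    if np.any(np.abs(r.sum(axis=0) - 1.0) > 1e-6):
        raise ValueError("PWM columns must sum to 1")
    return np.asarray(r, dtype=float)


@dataclass
class MrqScore:
    value: float  # in [0, 1]
    k: int
    offset: int = 0  # alignment offset used (sliding comparisons only)

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def mrq(t, r) -> MrqScore:
    """Motif reconstruction quality of equal-length PWMs (no auto-alignment)."""
    t, r = _as_pwm(t), _as_pwm(r)
    if t.shape[1] != r.shape[1]:
        raise ValueError(
            f"PWM length mismatch ({t.shape[1]} != {r.shape[1]}); align via the "
            "locus or use mrq_aligned"
        )
    k = t.shape[1]
    value = 1.0 - np.sum((t - r) ** 2) / (2 * k)
    return MrqScore(value=float(value), k=k)


def mrq_aligned(t, r) -> MrqScore:
    """MRQ with the shorter PWM slid over the longer; best offset reported.

    The benevolent convention for unequal predicted/true lengths: the score
    is the maximum equal-length MRQ over all placements of the shorter
    matrix within the longer, and the offset used is recorded.
    """
    t, r = _as_pwm(t), _as_pwm(r)
    if t.shape[1] == r.shape[1]:
        return mrq(t, r)
    short, long_, swapped = (t, r, False) if t.shape[1] < r.shape[1] else (r, t, True)
    k = short.shape[1]
    best = None
    for off in range(long_.shape[1] - k + 1):
        window = long_[:, off : off + k]
        score = mrq(short, window)
        if best is None or score.value > best.value:
            best = MrqScore(value=score.value, k=k, offset=off)
    return best


def frobenius_distance(A, B, normalize: bool = False) -> float:
    """Frobenius distance between importance matrices over shared defined entries.

    With ``normalize``, both matrices are first centered (mean over the
    shared defined entries subtracted) and scaled to unit maximum absolute
    entry — removing the arbitrary scale of classifier scores.
    """
    if A.k != B.k or A.L != B.L:
        raise ValueError("importance matrices must share order k and length L")
    shared = A.defined & B.defined
    if not np.any(shared):
        raise ValueError("no shared defined entries")
    a = A.values[shared].astype(float)
    b = B.values[shared].astype(float)
    if normalize:
        a = a - a.mean()
        b = b - b.mean()
        amax, bmax = np.max(np.abs(a)), np.max(np.abs(b))
        if amax > 0:
            a = a / amax
        if bmax > 0:
            b = b / bmax
    return float(np.sqrt(np.sum((a - b) ** 2)))


def classification_accuracy(scorer, data) -> float:
    """Fraction of examples with sign(s(x)) equal to the label.

    Tie rule: a score of exactly zero counts as +1.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    if hasattr(scorer, "score_codes"):
        scores = np.asarray(scorer.score_codes(data.codes), dtype=float)
    else:
        scores = scorer.score_batch(data.sequences)
    pred = np.where(scores >= 0, 1, -1)
    return float(np.mean(pred == np.asarray(data.labels)))
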
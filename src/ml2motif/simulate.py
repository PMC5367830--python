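"""Synthetic labeled DNA datasets with planted, optionally mutated motifs.

Positive-class sequences carry every planted motif at a fixed, known
position; the remaining positions (and all negative sequences) are i.i.d.
uniform over {A, C, G, T}.  Noise is modeled by mutating each planted
nucleotide independently with probability ``mutation_rate``, where a
mutation event redraws the nucleotide uniformly over all four letters —
so the effective per-position mismatch rate is ``3/4 * mutation_rate``
(a redraw reproduces the original letter with probability 1/4).

Positions are 1-based and inclusive in all public metadata, matching the
usual motif-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import ALPHABET, codes_to_seq, seqs_to_codes


@dataclass
class MotifSpec:
    """A motif planted at a fixed 1-based start position.

    ``pattern`` is either an exact string over {A,C,G,T} or a 4 x k
    column-stochastic matrix (rows ordered A, C, G, T) sampled column-wise
    when planting.
    """

    pattern: "str | np.ndarray"
    position: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"motif {self.name or self.pattern!r}: position must be >= 1")
        if isinstance(self.pattern, str):
            if len(self.pattern) < 1:
                raise ValueError("motif pattern must have length >= 1")
            bad = set(self.pattern) - set(ALPHABET)
            if bad:
                raise ValueError(f"motif {self.name or self.pattern!r}: non-ACGT characters {bad}")
        else:
            self.pattern = np.asarray(self.pattern, dtype=float)
            if self.pattern.ndim != 2 or self.pattern.shape[0] != 4 or self.pattern.shape[1] < 1:
                raise ValueError("PWM motif pattern must be a 4 x k matrix")
            if np.any(self.pattern < 0) or np.any(self.pattern > 1):
                raise ValueError("PWM entries must lie in [0, 1]")
            colsums = self.pattern.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-9):
                raise ValueError("PWM columns must each sum to 1")

    @property
    def is_pwm(self) -> bool:
        return not isinstance(self.pattern, str)

    @property
    def length(self) -> int:
        return self.pattern.shape[1] if self.is_pwm else len(self.pattern)

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.position + self.length - 1


@dataclass
class SequenceDataset:
    """Labeled fixed-length DNA sequences plus planted-motif metadata."""

    sequences: list
    labels: np.ndarray
    L: int
    planted: list = field(default_factory=list)
    positive_fraction: float = 0.0
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels length mismatch")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def codes(self) -> np.ndarray:
        """(n, L) int8 code matrix (A=0, C=1, G=2, T=3)."""
        return seqs_to_codes(self.sequences)

    def subset(self, idx) -> "SequenceDataset":
        idx = np.asarray(idx)
        return SequenceDataset(
            [self.sequences[i] for i in idx],
            self.labels[idx],
            self.L,
            planted=self.planted,
            positive_fraction=self.positive_fraction,
            mutation_rate=self.mutation_rate,
            seed=self.seed,
        )

    @staticmethod
    def concat(datasets, seed: "int | None" = None) -> "SequenceDataset":
        """Concatenate datasets of equal L, optionally reshuffling.

        Used e.g. for experiments where different positive subpopulations
        carry different (possibly mutually exclusive) motifs.
        """
        if not datasets:
            raise ValueError("no datasets to concatenate")
        L = datasets[0].L
        if any(d.L != L for d in datasets):
            raise ValueError("cannot concatenate datasets of differing sequence length")
        seqs = [s for d in datasets for s in d.sequences]
        labels = np.concatenate([d.labels for d in datasets])
        if seed is not None:
            perm = np.random.default_rng(seed).permutation(len(seqs))
            seqs = [seqs[i] for i in perm]
            labels = labels[perm]
        planted = [m for d in datasets for m in d.planted]
        n_pos = int(np.sum(labels == 1))
        return SequenceDataset(
            seqs,
            labels,
            L,
            planted=planted,
            positive_fraction=n_pos / len(seqs),
            mutation_rate=datasets[0].mutation_rate,
            seed=datasets[0].seed if seed is None else seed,
        )


def generate_dataset(
    n: int,
    L: int,
    motifs,
    positive_fraction: float,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> SequenceDataset:
    """Generate ``n`` uniform random length-``L`` sequences with planted motifs.

    Exactly ``round(n * positive_fraction)`` sequences are labeled +1 and
    carry every motif in ``motifs`` (exact strings copied verbatim, PWM
    motifs sampled column-wise per sequence), after which each planted
    nucleotide is independently redrawn uniformly with probability
    ``mutation_rate``.  Everything else is i.i.d. uniform background.
    Fully reproducible from ``seed``.
    """
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must lie strictly in (0, 1)")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    motifs = [m if isinstance(m, MotifSpec) else MotifSpec(*m) for m in motifs]
    for m in motifs:
        if m.end > L:
            raise ValueError(
                f"motif {m.name or str(m.pattern)!r} at position {m.position} "
                f"(length {m.length}) overflows sequence length L={L}"
            )

    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, L), dtype=np.int8)
    n_pos = int(round(n * positive_fraction))
    labels = np.full(n, -1, dtype=int)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    labels[pos_idx] = 1

    for m in motifs:
        start = m.position - 1
        if m.is_pwm:
            planted = np.empty((n_pos, m.length), dtype=np.int8)
            for col in range(m.length):
                planted[:, col] = rng.choice(4, size=n_pos, p=m.pattern[:, col])
        else:
            planted = np.tile(seqs_to_codes([m.pattern])[0], (n_pos, 1))
        if mutation_rate > 0:
            mut = rng.random((n_pos, m.length)) < mutation_rate
            redraw = rng.integers(0, 4, size=(n_pos, m.length), dtype=np.int8)
            planted = np.where(mut, redraw, planted)
        codes[pos_idx, start : start + m.length] = planted

    sequences = [codes_to_seq(row) for row in codes]
    return SequenceDataset(
        sequences,
        labels,
        L,
        planted=motifs,
        positive_fraction=positive_fraction,
        mutation_rate=mutation_rate,
        seed=seed,
    )
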
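"""Synthetic labelled protein corpora with a plantable dipeptide signal.

Real bioluminescent proteins are reported to be enriched in charged
residues and in dipeptides involving A, R, P and G relative to
non-bioluminescent proteins.  The generator emulates that kind of
class-discriminating compositional signal in a controlled way: negatives
are drawn residue-wise from a background distribution, while positives
are drawn from a first-order chain in which, at a configurable offset
``gap + 1``, favoured-residue pairs have their probability multiplied by
``dipeptide_boost`` (renormalized).  ``dipeptide_boost = 1`` makes the two
classes exchangeable, so a trained classifier should sit at chance; the
planted offset makes gap recovery by grid search testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lumiprot.seqio import ALPHABET, LabeledDataset, ProteinSequence

#: Approximate natural amino-acid abundances (UniProt-like, alphabetical
#: ACDEFGHIKLMNPQRSTVWY order, normalized at load).
NATURAL_BACKGROUND = np.array(
    [8.3, 1.4, 5.5, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
NATURAL_BACKGROUND /= NATURAL_BACKGROUND.sum()


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the planted class signal.

    favored_residues
        Residues whose ordered pairs are boosted in the positive class.
    dipeptide_boost
        Multiplier (>= 1) applied to favoured-pair probabilities at the
        planted offset; 1 means no signal.
    gap
        The g of the planted g-gap pair: the correlated residues sit at
        positions (i, i + gap + 1).
    length_range
        Inclusive (min, max) sequence lengths, uniform.
    background
        "uniform", "natural", or an explicit length-20 probability vector
        in alphabetical residue order.
    """

    favored_residues: tuple[str, ...] = ("A", "R", "P", "G")
    dipeptide_boost: float = 1.0
    gap: int = 0
    length_range: tuple[int, int] = (50, 100)
    background: object = "uniform"

    def __post_init__(self) -> None:
        if self.dipeptide_boost < 1:
            raise ValueError(f"dipeptide_boost must be >= 1, got {self.dipeptide_boost}")
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if lo < self.gap + 2:
            raise ValueError(
                f"minimum length {lo} too short for planted gap {self.gap} "
                f"(need >= {self.gap + 2})"
            )
        bad = set(self.favored_residues) - set(ALPHABET)
        if bad:
            raise ValueError(f"favored residues not in alphabet: {sorted(bad)}")

    def background_probs(self) -> np.ndarray:
        if isinstance(self.background, str):
            if self.background == "uniform":
                return np.full(20, 1 / 20)
            if self.background == "natural":
                return NATURAL_BACKGROUND.copy()
            raise ValueError(f"unknown background {self.background!r}")
        p = np.asarray(self.background, dtype=float)
        if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("background must be a length-20 probability vector")
        return p / p.sum()


def _draw_negative(rng: np.random.Generator, L: int, bg: np.ndarray) -> str:
    idx = np.searchsorted(np.cumsum(bg), rng.random(L), side="right")
    idx = np.minimum(idx, 19)
    return "".join(ALPHABET[i] for i in idx)


def _draw_positive(
    rng: np.random.Generator, L: int, bg: np.ndarray, spec: SignalSpec
) -> str:
    fav = np.array([a in spec.favored_residues for a in ALPHABET])
    boosted = bg.copy()
    boosted[fav] *= spec.dipeptide_boost
    boosted /= boosted.sum()
    cum_bg, cum_boost = np.cumsum(bg), np.cumsum(boosted)
    step = spec.gap + 1
    u = rng.random(L)
    out = np.empty(L, dtype=np.int64)
    for i in range(L):
        cum = cum_boost if i >= step and fav[out[i - step]] else cum_bg
        out[i] = min(int(np.searchsorted(cum, u[i], side="right")), 19)
    return "".join(ALPHABET[i] for i in out)


def generate_dataset(
    n_pos: int, n_neg: int, spec: SignalSpec | None = None, seed: int = 0
) -> LabeledDataset:
    """Generate ``n_pos`` positive and ``n_neg`` negative sequences.

    Fully reproducible from ``seed``; positives come first.  Sequence ids
    are ``pos_0001`` ... / ``neg_0001`` ....
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be >= 0")
    spec = spec or SignalSpec()
    rng = np.random.default_rng(seed)
    bg = spec.background_probs()
    lo, hi = spec.length_range
    sequences: list[ProteinSequence] = []
    labels: list[int] = []
    for i in range(n_pos):
        L = int(rng.integers(lo, hi + 1))
        sequences.append(ProteinSequence(f"pos_{i + 1:04d}", _draw_positive(rng, L, bg, spec)))
        labels.append(1)
    for i in range(n_neg):
        L = int(rng.integers(lo, hi + 1))
        sequences.append(ProteinSequence(f"neg_{i + 1:04d}", _draw_negative(rng, L, bg)))
        labels.append(0)
    return LabeledDataset(sequences=sequences, labels=labels)


def worked_example() -> ProteinSequence:
    """The short reference peptide used throughout the encoder unit tests."""
    return ProteinSequence("worked_example", "MCRAACGECFR")
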
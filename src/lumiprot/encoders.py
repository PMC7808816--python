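"""Alignment-free feature encoders for protein sequences.

Four encoders map a validated sequence to a fixed-length numeric vector:

natural vector (NV), 60 values
    Per amino acid: occurrence count, mean position offset, and second
    normalized central moment of the position distribution.  Positions are
    measured as offsets from the first residue (the first residue is the
    origin, offset 0).

CTD, 273 values
    Composition / transition / distribution descriptors after mapping
    residues into three groups under each of 13 physicochemical
    attributes: 3 + 3 + 15 descriptors per attribute, 13 attributes.

g-gap dipeptide composition, 400 values
    Frequencies of ordered residue pairs separated by exactly ``g``
    intervening residues; ``g = 0`` recovers adjacent dipeptides.

type-II pseudo amino acid composition, 400 + 9*lambda values
    Adjacent dipeptide frequencies plus tiered sequence-correlation
    factors of nine z-standardized physicochemical properties, mixed by a
    weight ``omega`` over ``lambda`` tiers.

:func:`fuse_features` concatenates the enabled blocks in the fixed order
NV, CTD, GGAP, PSEAAC with prefixed, deterministic column names, and
:func:`encode_dataset` builds the full feature matrix for a labelled
dataset (with per-block caching so grid searches do not re-encode
unchanged blocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lumiprot import data as _pkgdata
from lumiprot.seqio import ALPHABET, LabeledDataset, ProteinSequence

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Ordered dipeptides AA, AC, ..., YY (lexicographic over the alphabet).
DIPEPTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

BLOCKS = ("NV", "CTD", "GGAP", "PSEAAC")


class EncodingError(ValueError):
    """Raised when a sequence violates an encoder precondition."""


def _check_canonical(seq: ProteinSequence) -> np.ndarray:
    """Return residue indices, rejecting non-canonical letters."""
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq.residues), dtype=np.int64)
    except KeyError as exc:
        raise EncodingError(
            f"sequence {seq.id!r} contains non-canonical residue {exc.args[0]!r}; "
            "run seqio.validate_sequence first"
        ) from None


# ---------------------------------------------------------------------------
# natural vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NVComponents:
    """Natural-vector components, in alphabetical amino-acid order.

    ``counts[k]`` is the number of occurrences of amino acid ``k``;
    ``mu[k]`` the mean offset of those occurrences from the first residue
    (0 when absent); ``d2[k]`` the second normalized central moment
    ``sum((s - mu)^2) / (n_k * L)`` (0 when absent).  The total distance
    ``T_k`` of the method equals ``counts[k] * mu[k]``.
    """

    counts: np.ndarray
    mu: np.ndarray
    d2: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        """Interleaved 60-vector (n_A, mu_A, D2_A, ..., n_Y, mu_Y, D2_Y)."""
        out = np.empty(60)
        out[0::3] = self.counts
        out[1::3] = self.mu
        out[2::3] = self.d2
        return out

    def total_distance(self, aa: str) -> float:
        """T_k: the sum of offsets of amino acid ``aa`` from the origin."""
        k = _AA_INDEX[aa]
        return float(self.counts[k] * self.mu[k])


def nv_feature_names() -> list[str]:
    return [f"nv:{part}_{a}" for a in ALPHABET for part in ("n", "mu", "D2")]


def encode_nv(seq: ProteinSequence) -> NVComponents:
    """Encode the 60-dimensional natural vector.

    Offsets are measured from the first residue: the residue at 1-based
    position ``p`` contributes offset ``p - 1``.  For each amino acid the
    count, the mean offset, and the second normalized central moment
    ``sum((s - mu)^2) / (n_k * L)`` are reported; absent residues give
    (0, 0, 0).
    """
    idx = _check_canonical(seq)
    L = len(idx)
    offsets = np.arange(L, dtype=float)
    counts = np.bincount(idx, minlength=20).astype(float)
    sums = np.bincount(idx, weights=offsets, minlength=20)
    present = counts > 0
    mu = np.zeros(20)
    mu[present] = sums[present] / counts[present]
    sq = np.bincount(idx, weights=(offsets - mu[idx]) ** 2, minlength=20)
    d2 = np.zeros(20)
    d2[present] = sq[present] / (counts[present] * L)
    return NVComponents(counts=counts, mu=mu, d2=d2)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AminoAcidGroups:
    """13 physicochemical attributes, each splitting the alphabet into
    three disjoint groups."""

    attributes: tuple[str, ...]
    groups: Mapping[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for attr in self.attributes:
            g1, g2, g3 = self.groups[attr]
            merged = g1 + g2 + g3
            if sorted(merged) != sorted(ALPHABET):
                raise ValueError(
                    f"attribute {attr!r}: groups must partition the 20 amino acids"
                )

    def group_index(self, attr: str) -> np.ndarray:
        """Residue index -> group number (0, 1, 2) for one attribute."""
        gi = np.empty(20, dtype=np.int64)
        for g, members in enumerate(self.groups[attr]):
            for aa in members:
                gi[_AA_INDEX[aa]] = g
        return gi


_GROUPS_CACHE: AminoAcidGroups | None = None


def load_ctd_groups() -> AminoAcidGroups:
    """Load the packaged 13-attribute grouping table (checksummed)."""
    global _GROUPS_CACHE
    if _GROUPS_CACHE is None:
        rows = [
            line.split("\t")
            for line in _pkgdata.read_ctd_groups_text().strip().splitlines()[1:]
        ]
        _GROUPS_CACHE = AminoAcidGroups(
            attributes=tuple(r[0] for r in rows),
            groups={r[0]: (r[1], r[2], r[3]) for r in rows},
        )
    return _GROUPS_CACHE


_QUANTILES = (25, 50, 75)
_TRANSITION_PAIRS = ((0, 1), (0, 2), (1, 2))


def ctd_feature_names(groups: AminoAcidGroups | None = None) -> list[str]:
    groups = groups or load_ctd_groups()
    names: list[str] = []
    roman = ("I", "II", "III")
    for attr in groups.attributes:
        names += [f"ctd:{attr}:C_{g}" for g in roman]
        names += [f"ctd:{attr}:T_{roman[a]}.{roman[b]}" for a, b in _TRANSITION_PAIRS]
        for g in roman:
            names += [f"ctd:{attr}:D_{g}_{q}" for q in ("first", "25", "50", "75", "last")]
    return names


def encode_ctd(
    seq: ProteinSequence, groups: AminoAcidGroups | None = None
) -> np.ndarray:
    """Encode the 273 CTD descriptors.

    Per attribute: 3 composition fractions; 3 transition frequencies
    (adjacent pairs crossing two different groups, either order, divided
    by L - 1); and, per group, the 1-based positions of the first,
    ceil(25%)-th, ceil(50%)-th, ceil(75%)-th and last occurrence, scaled
    to percent of chain length (zeroes when a group is absent).
    """
    groups = groups or load_ctd_groups()
    idx = _check_canonical(seq)
    L = len(idx)
    if L < 2:
        raise EncodingError(
            f"sequence {seq.id!r}: CTD transitions need L >= 2, got L={L}"
        )
    out: list[float] = []
    for attr in groups.attributes:
        gseq = groups.group_index(attr)[idx]
        # composition
        comp = np.bincount(gseq, minlength=3) / L
        out += comp.tolist()
        # transition
        a, b = gseq[:-1], gseq[1:]
        for g1, g2 in _TRANSITION_PAIRS:
            crossings = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
            out.append(crossings / (L - 1))
        # distribution
        for g in range(3):
            pos = np.flatnonzero(gseq == g) + 1  # 1-based
            n = len(pos)
            if n == 0:
                out += [0.0] * 5
                continue
            picks = [pos[0]] + [pos[math.ceil(q / 100 * n) - 1] for q in _QUANTILES] + [pos[-1]]
            out += [100.0 * p / L for p in picks]
    return np.asarray(out)


# ---------------------------------------------------------------------------
# g-gap dipeptide composition
# ---------------------------------------------------------------------------

def ggap_feature_names(g: int) -> list[str]:
    return [f"ggap:g{g}:{d}" for d in DIPEPTIDES]


def encode_ggap(seq: ProteinSequence, g: int) -> np.ndarray:
    """Encode the 400 g-gap dipeptide frequencies.

    A g-gap dipeptide is the ordered pair of residues at positions
    ``(i, i + g + 1)``.  There are ``L - g - 1`` such pairs; frequencies
    are counts over that denominator and therefore sum to one.
    """
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    idx = _check_canonical(seq)
    L = len(idx)
    if L < g + 2:
        raise EncodingError(
            f"sequence {seq.id!r}: g-gap with g={g} needs L >= {g + 2}, got L={L}"
        )
    first = idx[: L - g - 1]
    second = idx[g + 1 :]
    counts = np.bincount(first * 20 + second, minlength=400).astype(float)
    return counts / (L - g - 1)


# ---------------------------------------------------------------------------
# type-II PseAAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyTable:
    """Nine residue properties, raw and z-standardized over the alphabet.

    Standardization is per property: subtract the 20-residue mean, divide
    by the 20-residue population standard deviation.
    """

    properties: tuple[str, ...]
    raw: np.ndarray          # (9, 20) in alphabetical residue order
    standardized: np.ndarray  # (9, 20)


_PROPS_CACHE: PropertyTable | None = None


def load_pseaac_properties() -> PropertyTable:
    """Load the packaged 9 x 20 property table (checksummed)."""
    global _PROPS_CACHE
    if _PROPS_CACHE is None:
        lines = _pkgdata.read_pseaac_properties_text().strip().splitlines()
        header = lines[0].split("\t")
        if tuple(header[1:]) != tuple(ALPHABET):
            raise RuntimeError("property table columns must be the alphabet in order")
        names, rows = [], []
        for line in lines[1:]:
            parts = line.split("\t")
            names.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        raw = np.asarray(rows)
        std = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
        _PROPS_CACHE = PropertyTable(tuple(names), raw, std)
    return _PROPS_CACHE


def pseaac_feature_names(lambda_: int, props: PropertyTable | None = None) -> list[str]:
    props = props or load_pseaac_properties()
    names = [f"pseaac:f_{d}" for d in DIPEPTIDES]
    for k in range(1, lambda_ + 1):
        names += [f"pseaac:phi_k{k}_{p}" for p in props.properties]
    return names


def encode_pseaac(
    seq: ProteinSequence,
    lambda_: int,
    omega: float,
    props: PropertyTable | None = None,
) -> np.ndarray:
    """Encode the type-II pseudo amino acid composition.

    The first 400 entries are adjacent dipeptide frequencies f_u
    (counts / (L - 1)); then, for tier k = 1..lambda and property p =
    1..9, the sequence-correlation factor

        phi_{9(k-1)+p} = (1 / (L - k)) * sum_i (h_p(R_i) - h_p(R_{i+k}))^2

    of the z-standardized property values h_p — one separate factor per
    (tier, property) pair, using the squared-difference correlation
    function standard in pseudo amino acid composition (non-negative, so
    the normalizer below is always positive).  All components are
    normalized by Z = sum(f) + omega * sum(phi), so the vector sums to 1.
    """
    if lambda_ < 1:
        raise ValueError(f"lambda_ must be >= 1, got {lambda_}")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    props = props or load_pseaac_properties()
    idx = _check_canonical(seq)
    L = len(idx)
    if L < 2:
        raise EncodingError(f"sequence {seq.id!r}: PseAAC needs L >= 2, got L={L}")
    if L <= lambda_:
        raise EncodingError(
            f"sequence {seq.id!r}: PseAAC with lambda={lambda_} needs L >= {lambda_ + 1}, "
            f"got L={L}"
        )
    f = np.bincount(idx[:-1] * 20 + idx[1:], minlength=400).astype(float) / (L - 1)
    h = props.standardized[:, idx]  # (9, L)
    phi = np.empty(9 * lambda_)
    for k in range(1, lambda_ + 1):
        phi[9 * (k - 1) : 9 * k] = ((h[:, : L - k] - h[:, k:]) ** 2).sum(axis=1) / (L - k)
    z = f.sum() + omega * phi.sum()
    if z <= 0:
        raise EncodingError(
            f"sequence {seq.id!r}: degenerate PseAAC normalizer Z={z:.6g} "
            f"(sum of correlation factors {phi.sum():.6g})"
        )
    return np.concatenate([f, omega * phi]) / z


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderConfig:
    """Which encoder blocks are active, and their parameters.

    ``enabled`` is a subset of {NV, CTD, GGAP, PSEAAC}; ``g`` the gap of
    the g-gap block; ``lambda_`` and ``omega`` the tier count and weight
    of the PseAAC block; ``species`` a bookkeeping tag.
    """

    enabled: tuple[str, ...] = BLOCKS
    g: int = 3
    lambda_: int = 18
    omega: float = 0.2
    species: str = "general"

    def __post_init__(self) -> None:
        unknown = set(self.enabled) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown encoder blocks {sorted(unknown)}")
        if not self.enabled:
            raise ValueError("at least one encoder block must be enabled")
        # keep the canonical block order regardless of input order
        object.__setattr__(
            self, "enabled", tuple(b for b in BLOCKS if b in set(self.enabled))
        )
        if "GGAP" in self.enabled and not (0 <= self.g <= 9):
            raise ValueError(f"g must be in [0, 9], got {self.g}")
        if "PSEAAC" in self.enabled:
            if self.lambda_ < 1:
                raise ValueError(f"lambda_ must be >= 1, got {self.lambda_}")
            if not (0 < self.omega <= 1):
                raise ValueError(f"omega must be in (0, 1], got {self.omega}")

    @property
    def n_features(self) -> int:
        n = 0
        if "NV" in self.enabled:
            n += 60
        if "CTD" in self.enabled:
            n += 273
        if "GGAP" in self.enabled:
            n += 400
        if "PSEAAC" in self.enabled:
            n += 400 + 9 * self.lambda_
        return n

    def min_sequence_length(self) -> int:
        """Shortest sequence every enabled encoder can accept."""
        m = 1
        if "CTD" in self.enabled or "PSEAAC" in self.enabled:
            m = max(m, 2)
        if "GGAP" in self.enabled:
            m = max(m, self.g + 2)
        if "PSEAAC" in self.enabled:
            m = max(m, self.lambda_ + 1)
        return m


def feature_names(config: EncoderConfig) -> list[str]:
    """Deterministic fused column layout for a config."""
    names: list[str] = []
    if "NV" in config.enabled:
        names += nv_feature_names()
    if "CTD" in config.enabled:
        names += ctd_feature_names()
    if "GGAP" in config.enabled:
        names += ggap_feature_names(config.g)
    if "PSEAAC" in config.enabled:
        names += pseaac_feature_names(config.lambda_)
    return names


def _encode_block(seq: ProteinSequence, block: str, config: EncoderConfig) -> np.ndarray:
    if block == "NV":
        return encode_nv(seq).vector
    if block == "CTD":
        return encode_ctd(seq)
    if block == "GGAP":
        return encode_ggap(seq, config.g)
    if block == "PSEAAC":
        return encode_pseaac(seq, config.lambda_, config.omega)
    raise ValueError(block)


def fuse_features(seq: ProteinSequence, config: EncoderConfig) -> np.ndarray:
    """Concatenate the enabled blocks (fixed order NV, CTD, GGAP, PSEAAC)."""
    parts = []
    for block in config.enabled:
        try:
            parts.append(_encode_block(seq, block, config))
        except (EncodingError, ValueError) as exc:
            raise EncodingError(f"sequence {seq.id!r}, block {block}: {exc}") from exc
    return np.concatenate(parts)


class DatasetEncoder:
    """Encode a fixed set of sequences under varying configs.

    Caches each encoder block by its parameters so that a grid search
    over (g, lambda, omega) re-encodes only the block that changed.
    """

    def __init__(self, sequences: Sequence[ProteinSequence]):
        self.sequences = list(sequences)
        self._cache: dict[tuple, np.ndarray] = {}

    def _block_matrix(self, block: str, config: EncoderConfig) -> np.ndarray:
        if block == "GGAP":
            key = (block, config.g)
        elif block == "PSEAAC":
            key = (block, config.lambda_, config.omega)
        else:
            key = (block,)
        if key not in self._cache:
            self._cache[key] = np.vstack(
                [_encode_block(s, block, config) for s in self.sequences]
            )
        return self._cache[key]

    def encode(self, config: EncoderConfig) -> pd.DataFrame:
        too_short = [
            s.id for s in self.sequences if len(s) < config.min_sequence_length()
        ]
        if too_short:
            raise EncodingError(
                f"sequences too short for config (need L >= "
                f"{config.min_sequence_length()}): {too_short[:10]}"
                + ("..." if len(too_short) > 10 else "")
            )
        mat = np.hstack([self._block_matrix(b, config) for b in config.enabled])
        return pd.DataFrame(
            mat,
            index=pd.Index([s.id for s in self.sequences], name="id"),
            columns=feature_names(config),
        )


def encode_dataset(data: LabeledDataset, config: EncoderConfig) -> pd.DataFrame:
    """Feature matrix for a labelled dataset: one row per sequence, rows in
    dataset order, columns per :func:`feature_names`."""
    return DatasetEncoder(data.sequences).encode(config)
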
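"""Epiallele pattern encoding, per-locus count profiles, and the Delta entropy statistic.

A *locus* is a group of four adjacent CpG sites covered together by single
bisulfite-sequencing reads.  Each read phases the methylation states of the
four CpGs into one of 2**4 = 16 *epialleles*.  The methylation state of the
locus in a cell population is then a distribution over those 16 patterns.

Pattern codes are integers in [0, 15].  Bit convention (fixed, stated in every
serialized header): the 5'-most CpG on the processed strand is the most
significant bit, 1 = methylated.  Code 0 is the fully unmethylated epiallele,
code 15 the fully methylated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

N_CPG = 4
N_PATTERNS = 16  # 2 ** N_CPG

#: default entropy scale: sum(p*log2 p) has minimum -4 over 16 patterns, so a
#: scale of 36 maps the extreme entropy difference to -144.
DEFAULT_ENTROPY_SCALE = 36.0

#: header comment written into every serialized table.
BIT_CONVENTION = (
    "pattern code bit convention: 5'-most CpG = most significant bit, 1 = methylated; "
    "code 0 = all unmethylated, code 15 = all methylated"
)

METHYLATED_TOKENS = frozenset({"M", "m", "methylated", "Z", 1, True})
UNMETHYLATED_TOKENS = frozenset({"U", "u", "unmethylated", "z", 0, False})


class EpihetError(Exception):
    """Base class for errors raised by this package."""


class PatternError(EpihetError):
    """Invalid epiallele pattern specification."""


class EmptyLocusError(EpihetError):
    """Operation requires a profile with at least one read."""


class LocusMismatchError(EpihetError):
    """Two profiles do not refer to the same locus."""


def encode_pattern(states: Sequence) -> int:
    """Encode four per-CpG methylation calls as a pattern code in [0, 15].

    Parameters
    ----------
    states
        Exactly four calls; each may be ``'M'``/``'U'``, ``'Z'``/``'z'``
        (Bismark letters), ``'methylated'``/``'unmethylated'``, or a boolean.

    Returns
    -------
    int
        The pattern code under the MSB-first convention.
    """
    states = list(states)
    if len(states) != N_CPG:
        raise PatternError(f"expected exactly {N_CPG} CpG calls, got {len(states)}")
    code = 0
    for s in states:
        code <<= 1
        if s in METHYLATED_TOKENS:
            code |= 1
        elif s in UNMETHYLATED_TOKENS:
            pass
        else:
            raise PatternError(f"unknown methylation call: {s!r}")
    return code


def decode_pattern(code: int) -> tuple[bool, bool, bool, bool]:
    """Inverse of :func:`encode_pattern`; True = methylated, 5'-most first."""
    if not (0 <= int(code) < N_PATTERNS):
        raise PatternError(f"pattern code out of range [0, 15]: {code}")
    return tuple(bool((int(code) >> shift) & 1) for shift in (3, 2, 1, 0))


@dataclass(frozen=True, order=True)
class LocusKey:
    """Genomic identity of a 4-CpG locus.

    ``positions`` are the 0-based coordinates of the four CpG cytosines,
    strictly increasing along the reference.
    """

    chrom: str
    positions: tuple[int, int, int, int]
    strand: str = "+"

    def __post_init__(self):
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) != N_CPG:
            raise PatternError(f"a locus has exactly {N_CPG} CpG positions, got {len(pos)}")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise PatternError(f"CpG positions must be strictly increasing: {pos}")
        if self.strand not in ("+", "-"):
            raise PatternError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> int:
        """Distance between the first and fourth CpG."""
        return self.positions[3] - self.positions[0]

    @property
    def id(self) -> str:
        return f"{self.chrom}:{','.join(map(str, self.positions))}:{self.strand}"

    @classmethod
    def from_id(cls, locus_id: str) -> "LocusKey":
        chrom, pos, strand = locus_id.rsplit(":", 2)
        return cls(chrom, tuple(int(p) for p in pos.split(",")), strand)


@dataclass
class EpialleleProfile:
    """Per-locus epiallele counts for one sample.

    ``counts[i]`` is the number of reads showing pattern code ``i``;
    ``total`` is their sum (the locus read coverage).
    """

    locus: LocusKey
    counts: np.ndarray
    total: int = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_PATTERNS,):
            raise PatternError(f"counts must have shape ({N_PATTERNS},), got {counts.shape}")
        if (counts < 0).any():
            raise PatternError("counts must be non-negative")
        self.counts = counts
        self.total = int(counts.sum())

    def proportions(self) -> np.ndarray:
        """Fractions p_i of each epiallele pattern (sum to 1)."""
        if self.total == 0:
            raise EmptyLocusError(f"locus {self.locus.id} has zero reads")
        return self.counts / self.total


def proportions(profile: EpialleleProfile) -> np.ndarray:
    """Functional alias for :meth:`EpialleleProfile.proportions`."""
    return profile.proportions()


def _plogp(p: np.ndarray, log_base: float) -> np.ndarray:
    # 0 * log 0 := 0 (standard entropy convention)
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz]) / np.log(log_base)
    return out


def combinatorial_entropy(
    profile: EpialleleProfile,
    scale: float = DEFAULT_ENTROPY_SCALE,
    log_base: float = 2.0,
) -> float:
    """Scaled pattern entropy S = scale * sum_i p_i log(p_i) (non-positive).

    With the default scale of 36 and base 2, S lies in [-144, 0]: 0 for a
    clonal locus (all reads one pattern), -144 for the uniform distribution
    over all 16 patterns.
    """
    p = profile.proportions()
    return float(scale * _plogp(p, log_base).sum())


def delta_entropy(
    profile_baseline: EpialleleProfile,
    profile_comparison: EpialleleProfile,
    scale: float = DEFAULT_ENTROPY_SCALE,
    log_base: float = 2.0,
) -> float:
    """Epiallele compositional shift between two samples at one locus.

    Returns ``S(comparison) - S(baseline)``.  With defaults the value lies in
    [-144, +144]: 0 when the two proportion vectors are identical, negative
    when the comparison sample is more epiallele-diverse (e.g. -144 for a
    clonal baseline against a uniform comparison).
    """
    if profile_baseline.locus != profile_comparison.locus:
        raise LocusMismatchError(
            f"profiles refer to different loci: "
            f"{profile_baseline.locus.id} vs {profile_comparison.locus.id}"
        )
    s_base = combinatorial_entropy(profile_baseline, scale=scale, log_base=log_base)
    s_comp = combinatorial_entropy(profile_comparison, scale=scale, log_base=log_base)
    return s_comp - s_base


def profile_from_patterns(locus: LocusKey, patterns: Iterable[int]) -> EpialleleProfile:
    """Build a profile by tallying an iterable of pattern codes."""
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    for code in patterns:
        if not (0 <= code < N_PATTERNS):
            raise PatternError(f"pattern code out of range: {code}")
        counts[code] += 1
    return EpialleleProfile(locus, counts)
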
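"""Methylation-class (MC) profile arithmetic.

An *epilocus* is a genomic window holding four CpG sites.  Each sequencing
read spanning the window reports one *epiallele*: a 4-character arrangement
of methylated ('1') and unmethylated ('0') cytosines.  Grouping epialleles
by the number of methylated CpGs yields five methylation classes (MC 0–4);
the MC profile of an epilocus is the vector of relative abundances of those
five classes among the spanning reads.

This module provides the profile container and the primitives every other
layer builds on: profile construction from epiallele counts, average
methylation, MC counts, Kullback–Leibler divergence and the Jensen–Shannon
distance (both in bits), and unweighted profile averaging for consensus
building.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

# Number of CpG sites per epilocus.  A window of n CpGs has n + 1 possible
# methylation classes; only n = 4 is exercised but the constant is kept in
# one place.
N_CPG = 4
N_CLASSES = N_CPG + 1

#: All 16 valid epiallele patterns, ordered lexicographically.
ALL_PATTERNS: tuple[str, ...] = tuple(
    "".join(bits) for bits in product("01", repeat=N_CPG)
)

#: Patterns grouped by methylation class (number of '1's): sizes 1,4,6,4,1.
PATTERNS_BY_CLASS: tuple[tuple[str, ...], ...] = tuple(
    tuple(
        "".join("1" if i in meth else "0" for i in range(N_CPG))
        for meth in combinations(range(N_CPG), k)
    )
    for k in range(N_CLASSES)
)

_SUM_TOL = 1e-6  # absolute slack accepted before renormalization


class EmptyCountsError(ValueError):
    """Raised when an operation requires at least one supporting read."""


class InvalidProfileError(ValueError):
    """Raised when abundances are not a probability vector."""


class InfiniteDivergenceError(ValueError):
    """Raised when KL divergence is infinite (support(a) ⊄ support(b)).

    Inside the Jensen–Shannon construction the second argument is the
    pairwise average, which covers both supports, so this error signals
    misuse of :func:`kl_divergence` outside that construction.
    """


@dataclass(frozen=True)
class MCProfile:
    """Relative abundances of the five methylation classes at one epilocus.

    Parameters
    ----------
    abundances
        Five fractions indexed by methylation class k = number of
        methylated CpGs (0..4).  Must be non-negative and sum to 1 within
        a small tolerance; the vector is renormalized exactly on
        construction.
    n_reads
        Number of spanning reads supporting the profile.  Retained for
        coverage filtering; it does not weight any arithmetic.
    """

    abundances: tuple[float, ...]
    n_reads: int = 0

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.abundances)
        if len(a) != N_CLASSES:
            raise InvalidProfileError(
                f"expected {N_CLASSES} abundances, got {len(a)}"
            )
        if any(x < 0 or not math.isfinite(x) for x in a):
            raise InvalidProfileError(f"abundances must be finite and >= 0: {a}")
        total = sum(a)
        if abs(total - 1.0) > _SUM_TOL:
            raise InvalidProfileError(f"abundances sum to {total}, not 1")
        if total != 1.0:
            a = tuple(x / total for x in a)
        object.__setattr__(self, "abundances", a)
        if self.n_reads < 0:
            raise InvalidProfileError("n_reads must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances, dtype=float)

    def __iter__(self):
        return iter(self.abundances)


def _validate_counts(counts: Mapping[str, int]) -> int:
    total = 0
    for pattern, count in counts.items():
        if pattern not in _PATTERN_CLASS:
            raise ValueError(f"invalid epiallele pattern {pattern!r}")
        if count < 0:
            raise ValueError(f"negative count for pattern {pattern!r}")
        total += count
    return total


_PATTERN_CLASS: dict[str, int] = {p: p.count("1") for p in ALL_PATTERNS}


def profile_from_counts(counts: Mapping[str, int]) -> MCProfile:
    """Collapse an epiallele count table into an MC profile.

    Patterns are grouped by their number of methylated CpGs and each
    class abundance is the grouped count divided by the total.

    Raises
    ------
    EmptyCountsError
        If the table holds no reads (a NaN profile is never produced).
    """
    total = _validate_counts(counts)
    if total == 0:
        raise EmptyCountsError("cannot profile an epilocus with zero reads")
    class_counts = [0] * N_CLASSES
    for pattern, count in counts.items():
        class_counts[_PATTERN_CLASS[pattern]] += count
    return MCProfile(tuple(c / total for c in class_counts), n_reads=total)


def average_methylation(p: MCProfile) -> float:
    """Mean fraction of methylated CpGs implied by a profile: Σ k·p_k / n."""
    return sum(k * a for k, a in enumerate(p.abundances)) / N_CPG


def mc_count(counts: Mapping[str, int]) -> int:
    """Number of methylation classes supported by at least one read (0–5)."""
    total = _validate_counts(counts)
    if total == 0:
        raise EmptyCountsError("MC count undefined for zero reads")
    return len({_PATTERN_CLASS[p] for p, c in counts.items() if c > 0})


def kl_divergence(a: MCProfile | Sequence[float], b: MCProfile | Sequence[float]) -> float:
    """Kullback–Leibler divergence D(a‖b) = Σ a_i·log2(a_i/b_i), in bits.

    Terms with a_i = 0 contribute zero.  A term with a_i > 0 and b_i = 0
    raises :class:`InfiniteDivergenceError`.
    """
    av = np.asarray(tuple(a), dtype=float)
    bv = np.asarray(tuple(b), dtype=float)
    support = av > 0
    if np.any(bv[support] == 0):
        raise InfiniteDivergenceError(
            "support of a not contained in support of b"
        )
    d = float(np.sum(av[support] * np.log2(av[support] / bv[support])))
    return max(d, 0.0)


def jsd(p1: MCProfile | Sequence[float], p2: MCProfile | Sequence[float]) -> float:
    """Jensen–Shannon distance between two MC profiles.

    The square root of the mean KL divergence of the two profiles from
    their elementwise average, with base-2 logarithms, so the result is a
    metric bounded by 1 and always finite (the average covers both
    supports).
    """
    a1 = np.asarray(tuple(p1), dtype=float)
    a2 = np.asarray(tuple(p2), dtype=float)
    m = (a1 + a2) / 2.0
    d = (kl_divergence(a1, m) + kl_divergence(a2, m)) / 2.0
    return min(math.sqrt(max(d, 0.0)), 1.0)


def jsd_pairwise_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise Jensen–Shannon distances between two (n, 5) arrays.

    Vectorized helper for the calibration simulations; rows must already
    be probability vectors.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log2(np.where(p > 0, p / m, 1.0)), 0.0)
        t2 = np.where(q > 0, q * np.log2(np.where(q > 0, q / m, 1.0)), 0.0)
    d = (t1.sum(axis=1) + t2.sum(axis=1)) / 2.0
    return np.sqrt(np.clip(d, 0.0, 1.0))


def average_profiles(profiles: Iterable[MCProfile]) -> MCProfile:
    """Unweighted elementwise mean of one or more profiles.

    Consensus building averages the relative abundance of each class
    across samples without coverage weighting; the returned ``n_reads``
    is the summed support of the inputs.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("cannot average an empty list of profiles")
    mean = np.mean([p.as_array() for p in profiles], axis=0)
    return MCProfile(tuple(mean), n_reads=sum(p.n_reads for p in profiles))
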
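"""Epilocus discovery: CpG indexing, 4-CpG windows, coverage/overlap filters.

Coordinates are 0-based half-open throughout.  An epilocus is delimited by
the first and fourth of four consecutive CpG sites, so its interval is
``[first_C, fourth_C + 1)``.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .profiles import N_CPG

_CG = re.compile("CG")


@dataclass(frozen=True, order=True)
class Epilocus:
    """A genomic window delimited by four consecutive CpG sites.

    ``cpg_positions`` are the 0-based forward-strand positions of the C of
    each CpG; both strands of a CpG unit collapse to this coordinate.
    """

    chrom: str
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        if len(pos) != N_CPG:
            raise ValueError(f"an epilocus holds exactly {N_CPG} CpGs, got {len(pos)}")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("CpG positions must be strictly increasing")
        object.__setattr__(self, "cpg_positions", pos)

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        return self.cpg_positions[-1] + 1

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"epl_{self.chrom}_{self.start}"

    def overlaps(self, other: "Epilocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def index_cpg_sites(sequence: str, chrom: str | None = None) -> np.ndarray:
    """Locate CpG dinucleotides on the forward strand of a sequence.

    Case-insensitive; ambiguity codes never match, so Ns break CpGs.
    Returns the sorted array of C positions.  Overlap is impossible for
    the CG motif, so a simple scan is exact.
    """
    seq = sequence.upper()
    return np.array([m.start() for m in _CG.finditer(seq)], dtype=np.int64)


def build_candidate_epiloci(
    cpg_index: Sequence[int] | np.ndarray,
    chrom: str,
    max_length: int = 100,
) -> list[Epilocus]:
    """Every window of 4 consecutive CpGs whose span fits ``max_length``.

    Windows advance one CpG at a time; a window's span is measured from
    the first C to one past the fourth C.  ``max_length`` defaults to
    100 bp (typical upper bound for short-read spanning coverage) and
    must lie in [10, 10000].
    """
    if not 10 <= max_length <= 10000:
        raise ValueError(f"max_length {max_length} outside sane range 10-10000")
    pos = np.asarray(cpg_index, dtype=np.int64)
    out = []
    for i in range(len(pos) - N_CPG + 1):
        window = pos[i : i + N_CPG]
        if window[-1] + 1 - window[0] <= max_length:
            out.append(Epilocus(chrom, tuple(int(p) for p in window)))
    return out


def select_nonoverlapping(candidates: Iterable[Epilocus]) -> list[Epilocus]:
    """Greedy leftmost-first maximal set of mutually non-overlapping epiloci.

    Candidates are processed per chromosome in (start, end) order; each
    window is kept iff it does not overlap the previously kept one.
    Deterministic and maximal: no rejected window could be added back.
    """
    kept: list[Epilocus] = []
    last_end: dict[str, int] = {}
    for epi in sorted(candidates, key=lambda e: (e.chrom, e.start, e.end)):
        if epi.start >= last_end.get(epi.chrom, -1):
            kept.append(epi)
            last_end[epi.chrom] = epi.end
    return kept


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Type-1 (nearest-rank) quantile: smallest value with CDF >= q."""
    if not values:
        raise ValueError("quantile of empty sequence")
    s = sorted(values)
    k = max(1, math.ceil(q * len(s)))
    return s[k - 1]


def filter_by_coverage(
    epiloci: Sequence[Epilocus],
    coverages: Sequence[int],
    min_cov: int = 50,
    upper_quantile: float | None = 0.99,
) -> list[Epilocus]:
    """Keep epiloci with coverage in ``[min_cov, Q(upper_quantile)]``.

    The upper cap is the nearest-rank quantile of the coverages of the
    candidate set itself (computed per sample), compared inclusively: an
    epilocus is dropped only when its coverage strictly exceeds the cap.
    Pass ``upper_quantile=None`` to disable the cap.
    """
    if len(epiloci) != len(coverages):
        raise ValueError("epiloci and coverages must align")
    if not epiloci:
        return []
    cap = (
        nearest_rank_quantile(list(coverages), upper_quantile)
        if upper_quantile is not None
        else math.inf
    )
    return [
        e for e, c in zip(epiloci, coverages) if c >= min_cov and c <= cap
    ]


def write_bed(epiloci: Iterable[Epilocus], path, coverages=None) -> None:
    """Write epiloci as 6-column BED (score = coverage when known)."""
    epiloci = list(epiloci)
    scores = list(coverages) if coverages is not None else [0] * len(epiloci)
    with open(path, "w") as fh:
        for epi, score in zip(epiloci, scores):
            fh.write(
                f"{epi.chrom}\t{epi.start}\t{epi.end}\t{epi.name}\t{score}\t+\n"
            )
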
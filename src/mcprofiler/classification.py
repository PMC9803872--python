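"""Assignment of MC profiles to archetypal methylation patterns (MPs).

Five prototype profiles describe the shapes expected at a given
methylation amount: D1 and D2 are the specular unmethylated/methylated
extremes, D3 is bimodal (fully-unmethylated plus fully-methylated
molecules), D4 is bell-shaped (binomial around half-methylation), D5 is
uniform.  A profile is assigned to the prototype at minimum Jensen–Shannon
distance; the distance to the winner (WCD) and to the runner-up (ECD)
diagnose how confident the assignment is.

The module also implements the neighborhood-concordance test: epiloci are
grouped into fixed genomic bins, bins are flagged concordant when all
member epiloci share one MP label, and a scramble bootstrap quantifies
whether the observed number of concordant bins exceeds chance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .discovery import Epilocus
from .profiles import MCProfile, jsd

MP_LABELS = ("D1", "D2", "D3", "D4", "D5")


def default_prototypes() -> dict[str, MCProfile]:
    """The five archetypal MC profiles.

    D1 unmethylated-dominant, D2 methylated-dominant, D3 bimodal,
    D4 bell-shaped (binomial n=4, p=1/2), D5 uniform.  Override by
    passing any mapping of label -> MCProfile to the classifier.
    """
    return {
        "D1": MCProfile((1.0, 0.0, 0.0, 0.0, 0.0)),
        "D2": MCProfile((0.0, 0.0, 0.0, 0.0, 1.0)),
        "D3": MCProfile((0.5, 0.0, 0.0, 0.0, 0.5)),
        "D4": MCProfile((1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16)),
        "D5": MCProfile((0.2, 0.2, 0.2, 0.2, 0.2)),
    }


@dataclass(frozen=True)
class MPAssignment:
    """Nearest-prototype label with classification diagnostics.

    ``wcd`` (within-class distance) is the JSD to the winning prototype;
    ``ecd`` (external-class distance) the JSD to the second-nearest.
    """

    label: str
    wcd: float
    ecd: float

    @property
    def ecd_wcd_ratio(self) -> float:
        """Classification confidence; +inf when the profile sits on a prototype."""
        return ecd_wcd_ratio(self)


def classify_profile(
    p: MCProfile, prototypes: Mapping[str, MCProfile] | None = None
) -> MPAssignment:
    """Assign a profile to the prototype with minimum JSD.

    Ties are broken by label order (D1 < D2 < ... ).
    """
    if prototypes is None:
        prototypes = default_prototypes()
    labels = list(prototypes)
    dists = [jsd(p, prototypes[lab]) for lab in labels]
    order = sorted(range(len(labels)), key=lambda i: (dists[i], labels[i]))
    best, second = order[0], order[1]
    return MPAssignment(labels[best], wcd=dists[best], ecd=dists[second])


def ecd_wcd_ratio(a: MPAssignment) -> float:
    if a.wcd == 0:
        return math.inf
    return a.ecd / a.wcd


def confident_fraction(
    assignments: Iterable[MPAssignment], ratio: float = 1.5
) -> float:
    """Fraction of assignments whose ECD/WCD ratio exceeds ``ratio``."""
    flags = [ecd_wcd_ratio(a) > ratio for a in assignments]
    if not flags:
        raise ValueError("no assignments")
    return sum(flags) / len(flags)


@dataclass(frozen=True)
class BinConcordance:
    """One genomic bin and the MP labels of the epiloci inside it."""

    chrom: str
    start: int
    end: int
    labels: tuple[str, ...]

    @property
    def n_epiloci(self) -> int:
        return len(self.labels)

    @property
    def concordant(self) -> bool:
        return len(set(self.labels)) == 1


def bin_epiloci(
    labeled: Mapping[Epilocus, str],
    bin_size: int = 1000,
    min_epiloci: int = 3,
) -> list[BinConcordance]:
    """Group labeled epiloci into fixed genomic bins and flag concordance.

    Bins are the windows [i*bin_size, (i+1)*bin_size); each epilocus goes
    to the single bin containing its midpoint.  Bins with fewer than
    ``min_epiloci`` members are dropped.
    """
    grouped: dict[tuple[str, int], list[str]] = defaultdict(list)
    for epi, label in labeled.items():
        mid = (epi.start + epi.end) // 2
        grouped[(epi.chrom, mid // bin_size)].append(label)
    bins = [
        BinConcordance(chrom, i * bin_size, (i + 1) * bin_size, tuple(labels))
        for (chrom, i), labels in sorted(grouped.items())
        if len(labels) >= min_epiloci
    ]
    return bins


@dataclass(frozen=True)
class BootstrapResult:
    observed_concordant: int
    null_counts: np.ndarray
    p_value: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))


def concordance_bootstrap(
    bins: Sequence[BinConcordance],
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapResult:
    """Scramble bootstrap for the number of concordant bins.

    Each replicate pools every member label, permutes the pool (sampling
    without replacement) and refills the bins at their observed sizes,
    then counts concordant bins.  The p-value uses the add-one estimator
    (1 + #{null >= observed}) / (n_reps + 1), which can never be zero.
    """
    if not bins:
        raise ValueError("no bins to bootstrap")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pooled = np.array([lab for b in bins for lab in b.labels])
    sizes = [b.n_epiloci for b in bins]
    edges = np.cumsum(sizes)[:-1]
    observed = sum(b.concordant for b in bins)
    null = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        perm = rng.permutation(pooled)
        null[r] = sum(
            len(set(chunk)) == 1 for chunk in np.split(perm, edges)
        )
    p = (1 + int(np.sum(null >= observed))) / (n_reps + 1)
    return BootstrapResult(observed, null, p)
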
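"""Cross-sample stability, per-condition consensus and differential analysis.

An epilocus is *stable* across the samples of a condition when every
pairwise Jensen–Shannon distance between its per-sample profiles is at or
below the cutoff (default 0.26, the calibrated same-source 95th
percentile); otherwise it is *variant*.  Stable epiloci get a consensus
profile by unweighted averaging.  Two conditions are then compared per
epilocus by the JSD between consensus profiles together with the signed
difference in average methylation (condition B minus condition A); a
profile is *changed* when the JSD strictly exceeds the cutoff.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .classification import MP_LABELS
from .discovery import Epilocus
from .profiles import MCProfile, average_methylation, average_profiles, jsd

DEFAULT_JSD_CUTOFF = 0.26


@dataclass(frozen=True)
class StabilityCall:
    max_jsd: float
    stable: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Differential verdict for one epilocus across two conditions."""

    jsd: float
    delta_meth: float  # condition B - condition A
    changed: bool


class VariantEpilocusError(ValueError):
    """Raised when a consensus is requested for a variant epilocus."""


def stability_call(
    profiles: Sequence[MCProfile], jsd_cutoff: float = DEFAULT_JSD_CUTOFF
) -> StabilityCall:
    """Stable iff all pairwise JSDs are <= cutoff (boundary inclusive)."""
    if len(profiles) < 2:
        raise ValueError("stability requires profiles from >= 2 samples")
    max_jsd = max(jsd(a, b) for a, b in combinations(profiles, 2))
    return StabilityCall(max_jsd=max_jsd, stable=max_jsd <= jsd_cutoff)


def consensus_for_condition(
    profiles: Sequence[MCProfile], jsd_cutoff: float = DEFAULT_JSD_CUTOFF
) -> MCProfile:
    """Consensus profile of a stable epilocus: unweighted sample average.

    Refuses variant epiloci (max pairwise JSD above the cutoff) so that a
    consensus never papers over genuine between-sample differences.
    """
    call = stability_call(profiles, jsd_cutoff)
    if not call.stable:
        raise VariantEpilocusError(
            f"max pairwise JSD {call.max_jsd:.3f} exceeds cutoff {jsd_cutoff}"
        )
    return average_profiles(profiles)


def compare_conditions(
    consensus_a: MCProfile,
    consensus_b: MCProfile,
    jsd_cutoff: float = DEFAULT_JSD_CUTOFF,
) -> ComparisonResult:
    d = jsd(consensus_a, consensus_b)
    delta = average_methylation(consensus_b) - average_methylation(consensus_a)
    return ComparisonResult(jsd=d, delta_meth=delta, changed=d > jsd_cutoff)


def compare_profile_maps(
    cond_a: Mapping[Epilocus, MCProfile],
    cond_b: Mapping[Epilocus, MCProfile],
    jsd_cutoff: float = DEFAULT_JSD_CUTOFF,
) -> tuple[dict[Epilocus, ComparisonResult], int]:
    """Compare two conditions epilocus-by-epilocus.

    Epiloci present on only one side are skipped; the second return value
    tallies them so drops are never silent.
    """
    shared = set(cond_a) & set(cond_b)
    skipped = len(set(cond_a) ^ set(cond_b))
    results = {
        epi: compare_conditions(cond_a[epi], cond_b[epi], jsd_cutoff)
        for epi in sorted(shared)
    }
    return results, skipped


def delta_meth_envelope(
    results: Iterable[ComparisonResult], q: float = 0.95
) -> float:
    """The q-quantile of |delta_meth| over the analyzed epiloci.

    Data-derived envelope of "ordinary" methylation change; profiles can
    sit outside the JSD cutoff while staying inside this envelope (changed
    shape at equal mean) and vice versa.
    """
    deltas = [abs(r.delta_meth) for r in results]
    if not deltas:
        raise ValueError("no comparison results")
    return float(np.quantile(deltas, q))


def transition_table(
    labels_a: Mapping[Epilocus, str],
    labels_b: Mapping[Epilocus, str],
    changed: Mapping[Epilocus, bool],
) -> pd.DataFrame:
    """5x5 tally of MP transitions (rows: condition A, cols: condition B).

    Restricted to epiloci flagged as changed and classified in both
    conditions.
    """
    table = pd.DataFrame(
        0, index=list(MP_LABELS), columns=list(MP_LABELS), dtype=int
    )
    for epi, is_changed in changed.items():
        if is_changed and epi in labels_a and epi in labels_b:
            table.loc[labels_a[epi], labels_b[epi]] += 1
    table.index.name = "from"
    table.columns.name = "to"
    return table
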
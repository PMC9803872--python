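"""Synthetic-data generators with a verbatim truth ledger.

Every generator is a pure function of its specification and seed, and
records exactly what it drew, so downstream expectations (extraction
tallies, profiles, classifications, stability calls, consensus profiles,
differential results, transition tables) can be recomputed from the
ledger and asserted.

The statistical model is the one the analysis assumes: reads at an
epilocus are independent draws from a truth MC profile; class counts are
multinomial and, within a class, the arrangement of methylated positions
is uniform over the C(4,k) possibilities (MC profiling is position-blind,
so any arrangement law with the right class marginals is observationally
equivalent downstream; uniform is the least-informative choice).
Replicate samples share one truth by default — pure sampling noise — with
an optional Dirichlet jitter to create deliberately variant epiloci.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .discovery import Epilocus
from .profiles import (
    MCProfile,
    N_CLASSES,
    N_CPG,
    PATTERNS_BY_CLASS,
    profile_from_counts,
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_epiallele_counts(
    truth: MCProfile, coverage: int, seed: int | np.random.Generator = 0
) -> Counter[str]:
    """Multinomial class counts, arrangements uniform within each class."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = _rng(seed)
    class_counts = rng.multinomial(coverage, truth.as_array())
    counts: Counter[str] = Counter()
    for k, n_k in enumerate(class_counts):
        if n_k == 0:
            continue
        arrangements = PATTERNS_BY_CLASS[k]
        picks = rng.integers(0, len(arrangements), size=n_k)
        for i in picks:
            counts[arrangements[i]] += 1
    return counts


def simulate_allelic_locus(
    truth_a: MCProfile,
    truth_b: MCProfile,
    mix: float = 0.5,
    coverage: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[Counter[str], Counter[str], Counter[str]]:
    """Joint epiallele counts for a locus with two allelic truth profiles.

    ``mix`` is the fraction of molecules from allele B (strictly between
    0 and 1); the per-allele read split is binomial.  Returns the joint
    table plus the per-allele tables, standing in for allele-sorted BAMs.
    """
    if not 0 < mix < 1:
        raise ValueError("mix must be strictly between 0 and 1")
    rng = _rng(seed)
    n_b = int(rng.binomial(coverage, mix))
    n_b = min(max(n_b, 1), coverage - 1)  # keep both alleles observed
    counts_a = simulate_epiallele_counts(truth_a, coverage - n_b, rng)
    counts_b = simulate_epiallele_counts(truth_b, n_b, rng)
    return counts_a + counts_b, counts_a, counts_b


@dataclass
class TruthLedger:
    """Everything the generators drew, keyed by epilocus.

    ``truth_profiles`` holds the generating MC profile per epilocus (and
    per condition when a condition pair was simulated);
    ``sample_counts`` the realized per-sample epiallele tables, recorded
    verbatim; ``allelic`` optional per-allele tables and mixing fraction;
    ``transitions`` the intended condition-A→condition-B truth pairs.
    """

    truth_profiles: dict[Epilocus, MCProfile] = field(default_factory=dict)
    sample_counts: dict[str, dict[Epilocus, Counter]] = field(default_factory=dict)
    truth_profiles_b: dict[Epilocus, MCProfile] = field(default_factory=dict)
    sample_counts_b: dict[str, dict[Epilocus, Counter]] = field(default_factory=dict)
    allelic: dict[Epilocus, dict] = field(default_factory=dict)

    def expected_counts(self, sample: str, epi: Epilocus) -> Counter:
        return self.sample_counts[sample][epi]

    def to_json(self, path) -> None:
        def enc_counts(tables):
            return {
                sample: {
                    f"{e.chrom}:{','.join(map(str, e.cpg_positions))}": dict(c)
                    for e, c in per.items()
                }
                for sample, per in tables.items()
            }

        doc = {
            "truth_profiles": {
                f"{e.chrom}:{','.join(map(str, e.cpg_positions))}": list(p.abundances)
                for e, p in self.truth_profiles.items()
            },
            "truth_profiles_b": {
                f"{e.chrom}:{','.join(map(str, e.cpg_positions))}": list(p.abundances)
                for e, p in self.truth_profiles_b.items()
            },
            "sample_counts": enc_counts(self.sample_counts),
            "sample_counts_b": enc_counts(self.sample_counts_b),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def simulate_sample_set(
    truths: Mapping[Epilocus, MCProfile],
    n_samples: int = 3,
    coverage: int | Sequence[int] = 50,
    seed: int = 0,
    jitter_concentration: float | None = None,
) -> TruthLedger:
    """Replicate epiallele tables drawn independently per sample.

    ``coverage`` is a fixed value or one value per epilocus (minimum 1).
    With ``jitter_concentration`` set, each sample's generating profile is
    a Dirichlet perturbation of the truth (concentration × truth + 0.05,
    higher = tighter), letting tests create variant epiloci on purpose;
    the default is pure sampling noise from a shared truth.
    """
    root = np.random.SeedSequence(seed)
    ledger = TruthLedger(truth_profiles=dict(truths))
    epiloci = sorted(truths)
    if isinstance(coverage, int):
        coverages = {e: coverage for e in epiloci}
    else:
        coverages = dict(zip(epiloci, coverage))
    for s, child in enumerate(root.spawn(n_samples)):
        rng = np.random.default_rng(child)
        name = f"sample_{s + 1}"
        tables: dict[Epilocus, Counter] = {}
        for epi in epiloci:
            truth = truths[epi]
            if jitter_concentration is not None:
                alpha = jitter_concentration * truth.as_array() + 0.05
                truth = MCProfile(tuple(rng.dirichlet(alpha)))
            tables[epi] = simulate_epiallele_counts(truth, coverages[epi], rng)
        ledger.sample_counts[name] = tables
    return ledger


def simulate_condition_pair(
    ledger: TruthLedger,
    transition: Mapping[Epilocus, MCProfile],
    n_samples: int = 3,
    coverage: int | Sequence[int] = 50,
    seed: int = 1,
) -> TruthLedger:
    """Add condition-B tables drawn from per-epilocus target truths.

    ``transition`` maps each epilocus to its condition-B truth profile
    (identity entries model unchanged epiloci).  The ledger records both
    truths so the intended transition tally is recomputable.
    """
    missing = set(transition) - set(ledger.truth_profiles)
    if missing:
        raise ValueError(f"transition spec covers unknown epiloci: {sorted(missing)[:3]}")
    ledger_b = simulate_sample_set(transition, n_samples, coverage, seed)
    ledger.truth_profiles_b = dict(transition)
    ledger.sample_counts_b = ledger_b.sample_counts
    return ledger


# --- synthetic reference + aligned reads ---------------------------------


def make_reference(
    epiloci: Sequence[Epilocus], pad: int = 30, seed: int = 0
) -> dict[str, str]:
    """Per-chromosome sequences whose only CpGs are the requested ones.

    The background alternates over A/T (never creating a CG), and "CG" is
    planted at each epilocus CpG position, so CpG indexing recovers
    exactly the planted sites.
    """
    rng = _rng(seed)
    lengths: dict[str, int] = {}
    for epi in epiloci:
        lengths[epi.chrom] = max(lengths.get(epi.chrom, 0), epi.end + pad)
    out = {}
    for chrom, length in lengths.items():
        seq = rng.choice(list("AT"), size=length)
        for epi in epiloci:
            if epi.chrom != chrom:
                continue
            for pos in epi.cpg_positions:
                seq[pos] = "C"
                seq[pos + 1] = "G"
        out[chrom] = "".join(seq)
    return out


def write_fasta(reference: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_synthetic_bam(
    tables: Mapping[Epilocus, Mapping[str, int]],
    reference: Mapping[str, str],
    bam_path: str,
    pad: int = 5,
    truncated_per_epilocus: int = 0,
) -> None:
    """Write one aligned record per counted molecule, sorted and indexed.

    Each read spans its epilocus with ``pad`` extra bases on both sides;
    the base sequence applies bisulfite conversion to the reference
    (unmethylated CpG C→T) and the XM-style call string marks every CpG
    with Z/z.  ``truncated_per_epilocus`` additionally emits reads
    stopping short of the fourth CpG, which downstream extraction must
    reject under the full-span rule.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": len(reference[chrom])}
            for chrom in sorted(reference)
        ],
    }
    chrom_ids = {chrom: i for i, chrom in enumerate(sorted(reference))}
    records = []
    for epi in sorted(tables):
        ref = reference[epi.chrom]
        start = max(0, epi.start - pad)
        end = min(len(ref), epi.end + pad)
        serial = 0
        for pattern in sorted(tables[epi]):
            for _ in range(tables[epi][pattern]):
                records.append(
                    _make_record(epi, pattern, ref, start, end, chrom_ids, serial)
                )
                serial += 1
        for _ in range(truncated_per_epilocus):
            # covers only the first three CpGs
            t_end = epi.cpg_positions[2] + 2
            records.append(
                _make_record(epi, "000", ref, start, t_end, chrom_ids, serial)
            )
            serial += 1
    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.index(bam_path)


def _make_record(epi, pattern, ref, start, end, chrom_ids, serial):
    import pysam

    length = end - start
    seq = list(ref[start:end].upper())
    xm = ["."] * length
    for i, pos in enumerate(epi.cpg_positions):
        if pos >= end - 1:
            break
        off = pos - start
        if i < len(pattern) and pattern[i] == "1":
            xm[off] = "Z"
        else:
            xm[off] = "z"
            seq[off] = "T"  # bisulfite conversion of unmethylated C
    rec = pysam.AlignedSegment()
    rec.query_name = f"{epi.name}_{serial}"
    rec.query_sequence = "".join(seq)
    rec.flag = 0
    rec.reference_id = chrom_ids[epi.chrom]
    rec.reference_start = start
    rec.mapping_quality = 42
    rec.cigarstring = f"{length}M"
    rec.query_qualities = pysam.qualitystring_to_array("I" * length)
    rec.set_tag("XM", "".join(xm))
    rec.set_tag("XG", "CT")
    rec.set_tag("XR", "CT")
    return rec
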
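"""Threshold calibration by subsampling simulations.

Two simulations justify the pipeline's fixed thresholds:

* the *coverage-error curve* repeatedly subsamples a high-coverage
  reference down to each coverage on a grid and measures the JSD between
  the subsampled and the reference MC profile — the curve shows where
  added coverage stops buying accuracy (the visible drop lies between 25
  and 50 reads, motivating the 50-read minimum);
* the *same-source null* draws pairs of independent coverage-sized
  samples from one source and measures the JSD within each pair — its
  95th percentile is the recommended cutoff for calling two profiles
  different (≈0.26 at 50 reads), i.e. a 5% false-positive rate when the
  underlying profiles are identical.

Subsampling from a concrete read pool is without replacement
(hypergeometric); purely synthetic sources given as profiles are sampled
multinomially.  Both converge as the reference grows.  Because MC
profiling only needs class abundances, class-level draws are exact for
every profile-level statistic.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .profiles import (
    MCProfile,
    N_CLASSES,
    _PATTERN_CLASS,
    jsd_pairwise_rows,
    profile_from_counts,
)

DEFAULT_COVERAGE_GRID = tuple(range(20, 201, 10))


def _class_counts(counts: Mapping[str, int]) -> np.ndarray:
    out = np.zeros(N_CLASSES, dtype=np.int64)
    for pattern, n in counts.items():
        out[_PATTERN_CLASS[pattern]] += n
    return out


def subsample_reads(
    counts: Mapping[str, int], n: int, seed: int | np.random.Generator = 0
) -> Counter[str]:
    """Draw ``n`` reads without replacement from an epiallele pool.

    Exactly hypergeometric over the 16 patterns, so expected class
    proportions equal the source's.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patterns = sorted(p for p, c in counts.items() if c > 0)
    pool = np.array([counts[p] for p in patterns], dtype=np.int64)
    total = int(pool.sum())
    if n > total:
        raise ValueError(f"cannot sample {n} reads from a pool of {total}")
    draw = rng.multivariate_hypergeometric(pool, n)
    return Counter({p: int(c) for p, c in zip(patterns, draw) if c > 0})


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-coverage JSD percentiles of estimate-vs-reference distance."""

    coverages: tuple[int, ...]
    jsd_p50: tuple[float, ...]
    jsd_p95: tuple[float, ...]
    n_reps: int


def coverage_error_curve(
    reference: Mapping[str, int],
    coverages: Sequence[int] = DEFAULT_COVERAGE_GRID,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CalibrationCurve:
    """Accuracy-vs-coverage curve against a high-coverage reference.

    For each coverage, ``n_reps`` subsamples are drawn without replacement
    from the reference pool; each subsample's MC profile is compared with
    the reference profile by JSD and the 50th/95th percentiles are kept.
    The reference should dwarf the largest coverage (tens of thousands of
    reads) so subsampling noise, not pool depletion, dominates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coverages = tuple(int(c) for c in coverages)
    if any(b <= a for a, b in zip(coverages, coverages[1:])):
        raise ValueError("coverage grid must be strictly increasing")
    pool = _class_counts(reference)
    total = int(pool.sum())
    if max(coverages) > total:
        raise ValueError("coverage exceeds the reference read pool")
    ref_profile = np.tile(pool / total, (n_reps, 1))
    p50, p95 = [], []
    for cov in coverages:
        draws = rng.multivariate_hypergeometric(pool, cov, size=n_reps)
        dists = jsd_pairwise_rows(draws / cov, ref_profile)
        p50.append(float(np.quantile(dists, 0.50)))
        p95.append(float(np.quantile(dists, 0.95)))
    return CalibrationCurve(coverages, tuple(p50), tuple(p95), n_reps)


@dataclass(frozen=True)
class SameSourceNull:
    """JSD null distribution between same-source coverage-sized samples."""

    coverage: int
    n_pairs: int
    sample: np.ndarray
    p95: float


def same_source_null(
    source: MCProfile | Mapping[str, int],
    coverage: int = 50,
    n_pairs: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SameSourceNull:
    """Null JSD between pairs of independent samples from one source.

    With an :class:`MCProfile` source, class counts of each sample are
    multinomial; with an epiallele count table, each sample is an
    independent without-replacement draw from the pool.  The 95th
    percentile of the pair JSDs is the recommended cutoff for declaring
    two profiles different at this coverage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(source, MCProfile):
        p = source.as_array()
        a = rng.multinomial(coverage, p, size=n_pairs) / coverage
        b = rng.multinomial(coverage, p, size=n_pairs) / coverage
    else:
        pool = _class_counts(source)
        if coverage > pool.sum():
            raise ValueError("coverage exceeds the source read pool")
        a = rng.multivariate_hypergeometric(pool, coverage, size=n_pairs) / coverage
        b = rng.multivariate_hypergeometric(pool, coverage, size=n_pairs) / coverage
    dists = jsd_pairwise_rows(a, b)
    return SameSourceNull(
        coverage=coverage,
        n_pairs=n_pairs,
        sample=dists,
        p95=float(np.quantile(dists, 0.95)),
    )


def analytic_null_p95(coverage: int, df: int = N_CLASSES - 1) -> float:
    """Large-sample 95th percentile of the same-source JSD.

    For two multinomial estimates of the same distribution with all
    classes populated, 8·n·ln2·JSD² is asymptotically chi-square with
    k−1 degrees of freedom per estimate, i.e. the pair statistic follows
    chi2(k−1) scaled by 1/(4·n·ln2): p95 = sqrt(chi2_{k-1}(0.95)/(4·n·ln2)).
    """
    from scipy.stats import chi2

    return float(np.sqrt(chi2.ppf(0.95, df) / (4 * coverage * np.log(2))))


def default_panel() -> dict[str, MCProfile]:
    """Synthetic calibration panel: 25 sources spanning average methylation 0–1.

    Five shape families (binomial, bimodal, binomial/bimodal blend,
    peaked, uniform/bimodal blend) at five methylation levels, enriched
    for intermediate methylation where low-coverage estimation is
    hardest.  Shipped as a JSON config so an in-house amplicon panel can
    be substituted.
    """
    text = resources.files("mcprofiler.data").joinpath("calibration_panel.json").read_text()
    spec = json.loads(text)
    return {
        name: MCProfile(tuple(vec)) for name, vec in spec["sources"].items()
    }


def panel_null_percentiles(
    panel: Mapping[str, MCProfile],
    coverage: int = 50,
    n_pairs: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Per-source same-source 95th percentiles across a calibration panel.

    Each source gets its own RNG stream derived from the seed by counter,
    so results are reproducible and order-independent.
    """
    out = {}
    for i, (name, source) in enumerate(sorted(panel.items())):
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(len(panel))[i])
        out[name] = same_source_null(source, coverage, n_pairs, rng).p95
    return out
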
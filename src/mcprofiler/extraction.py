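"""Per-epilocus epiallele extraction from aligned bisulfite reads.

Reads carry a per-base methylation call string (Bismark XM convention:
'Z' = methylated CpG, 'z' = unmethylated CpG, anything else = non-CpG
context or no call).  A read contributes to an epilocus only when it has a
valid Z/z call at all four CpG positions — reads covering a partial window
are discarded, so the reported coverage equals the number of molecules
whose full epiallele is observed.

Strand handling follows the Bismark convention: reads from the original
bottom strand (XG tag "GA") report the CpG call at the G position, one
base past the forward-strand C, and are shifted back so both strands pool
onto the same CpG unit.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pysam

from .discovery import Epilocus

_CALLS = frozenset("Zz")


@dataclass
class ExtractionStats:
    """QC tallies accumulated while scanning a BAM."""

    admitted: int = 0
    non_spanning: int = 0
    filtered_flags: int = 0
    low_mapq: int = 0
    malformed: int = 0


def _cpg_calls(read: pysam.AlignedSegment, xm_tag: str) -> dict[int, str]:
    """Map forward-strand CpG C-positions to this read's Z/z calls.

    Raises ValueError on a malformed call string (length mismatch with the
    aligned sequence).
    """
    xm = read.get_tag(xm_tag)
    seq = read.query_sequence
    if seq is None or len(xm) != len(seq):
        raise ValueError(f"call string length mismatch on read {read.query_name}")
    # Bottom-strand reads call the CpG on the G; shift to the C position.
    if read.has_tag("XG"):
        offset = 1 if read.get_tag("XG") == "GA" else 0
    else:
        offset = 1 if read.is_reverse else 0
    calls: dict[int, str] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        c = xm[qpos]
        if c in _CALLS:
            calls[rpos - offset] = c
    return calls


def pattern_from_calls(
    calls: Mapping[int, str], epilocus: Epilocus
) -> str | None:
    """Epiallele pattern from a position→call map, or None if not spanning."""
    bits = []
    for pos in epilocus.cpg_positions:
        c = calls.get(pos)
        if c is None:
            return None
        bits.append("1" if c == "Z" else "0")
    return "".join(bits)


def pattern_from_read(
    read: pysam.AlignedSegment, epilocus: Epilocus, xm_tag: str = "XM"
) -> str | None:
    """Extract the 4-character epiallele of one read at one epilocus.

    Returns None unless the read has a valid CpG call at all four sites
    (the full-span rule).  Indels across a site leave it uncalled, which
    makes the read non-spanning for that site.
    """
    return pattern_from_calls(_cpg_calls(read, xm_tag), epilocus)


def epiallele_counts_for_epilocus(
    bam: pysam.AlignmentFile,
    epilocus: Epilocus,
    xm_tag: str = "XM",
    min_mapq: int = 0,
    mate_aware: bool = True,
    stats: ExtractionStats | None = None,
) -> Counter[str]:
    """Tally epiallele patterns over reads spanning one epilocus.

    Duplicate-marked, secondary, supplementary and unmapped records are
    skipped.  With ``mate_aware`` (default), the two records of a proper
    pair count as one molecule: their call maps are merged with mate 1
    winning in the overlapping segment.  The total of the returned counter
    is the coverage used by downstream coverage filters.
    """
    if stats is None:
        stats = ExtractionStats()
    fragments: dict[str, dict[int, str]] = {}
    counts: Counter[str] = Counter()
    for read in bam.fetch(epilocus.chrom, epilocus.start, epilocus.end):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
        ):
            stats.filtered_flags += 1
            continue
        if read.mapping_quality < min_mapq:
            stats.low_mapq += 1
            continue
        try:
            calls = _cpg_calls(read, xm_tag)
        except (ValueError, KeyError):
            stats.malformed += 1
            continue
        if mate_aware and read.is_paired:
            merged = fragments.setdefault(read.query_name, {})
            if read.is_read1:
                merged.update(calls)  # mate 1 wins in the overlap
            else:
                for pos, c in calls.items():
                    merged.setdefault(pos, c)
        else:
            pattern = pattern_from_calls(calls, epilocus)
            if pattern is None:
                stats.non_spanning += 1
            else:
                counts[pattern] += 1
                stats.admitted += 1
    for calls in fragments.values():
        pattern = pattern_from_calls(calls, epilocus)
        if pattern is None:
            stats.non_spanning += 1
        else:
            counts[pattern] += 1
            stats.admitted += 1
    return counts


def extract_counts(
    bam_path: str,
    epiloci: Sequence[Epilocus],
    xm_tag: str = "XM",
    min_mapq: int = 0,
    mate_aware: bool = True,
) -> tuple[dict[Epilocus, Counter[str]], ExtractionStats]:
    """Extract epiallele counts for a set of epiloci from an indexed BAM."""
    stats = ExtractionStats()
    out: dict[Epilocus, Counter[str]] = {}
    with pysam.AlignmentFile(bam_path) as bam:
        for epi in epiloci:
            counts = epiallele_counts_for_epilocus(
                bam, epi, xm_tag=xm_tag, min_mapq=min_mapq,
                mate_aware=mate_aware, stats=stats,
            )
            if counts:
                out[epi] = counts
    return out, stats


# --- epiallele TSV dialect ------------------------------------------------
# Tab-separated, '#' comment lines allowed, one header line, columns:
#   chrom  start  end  cpg_positions  pattern  count
# cpg_positions is a comma-separated list of 0-based C positions.

TSV_COLUMNS = ("chrom", "start", "end", "cpg_positions", "pattern", "count")


def read_epiallele_table(path) -> dict[Epilocus, Counter[str]]:
    """Parse an epiallele TSV into per-epilocus pattern counts.

    Duplicate (epilocus, pattern) rows are summed.  Bad patterns or
    negative counts raise ValueError with the offending line number.
    """
    from .profiles import ALL_PATTERNS

    valid = set(ALL_PATTERNS)
    out: dict[Epilocus, Counter[str]] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                if line.split("\t")[:6] != list(TSV_COLUMNS):
                    raise ValueError(
                        f"line {lineno}: expected header {TSV_COLUMNS}"
                    )
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected 6 columns")
            chrom, start, end, cpgs, pattern, count = fields[:6]
            if pattern not in valid:
                raise ValueError(f"line {lineno}: invalid pattern {pattern!r}")
            try:
                n = int(count)
                positions = tuple(int(p) for p in cpgs.split(","))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if n < 0:
                raise ValueError(f"line {lineno}: negative count {n}")
            epi = Epilocus(chrom, positions)
            if epi.start != int(start) or epi.end != int(end):
                raise ValueError(
                    f"line {lineno}: interval {start}-{end} does not match "
                    f"CpG positions {cpgs}"
                )
            out.setdefault(epi, Counter())[pattern] += n
    return out


def write_epiallele_table(
    tables: Mapping[Epilocus, Mapping[str, int]], path, header_comment: str | None = None
) -> None:
    """Write per-epilocus counts in the epiallele TSV dialect."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for epi in sorted(tables):
            cpgs = ",".join(str(p) for p in epi.cpg_positions)
            for pattern in sorted(tables[epi]):
                n = tables[epi][pattern]
                if n:
                    fh.write(
                        f"{epi.chrom}\t{epi.start}\t{epi.end}\t{cpgs}\t{pattern}\t{n}\n"
                    )
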
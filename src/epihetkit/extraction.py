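"""Epiallele extraction from bisulfite alignments (methclone-style stage).

Scans bisulfite-aligned reads carrying Bismark ``XM`` methylation-call
strings, enumerates 4-CpG loci by a sliding window over observed CpG
positions, tallies per-locus epiallele counts per sample, and (in two-sample
mode) computes the Delta entropy shift per shared locus.  Per-locus results
are serialized to a gzip-compressed TSV.

Filtering defaults follow common bisulfite practice: loci with coverage
below 60 are discarded, loci whose first-to-fourth CpG span exceeds 72 bp
are never formed, reads need mapping quality >= 20, and duplicate-flagged
reads are skipped.  All are configurable.

Coordinates are 0-based half-open in memory and 1-based inclusive in the
text table.  Strands are profiled independently and never collapsed.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pysam

from .epiallele import (
    BIT_CONVENTION,
    N_PATTERNS,
    DEFAULT_ENTROPY_SCALE,
    EpihetError,
    EpialleleProfile,
    LocusKey,
    combinatorial_entropy,
    delta_entropy,
    encode_pattern,
)

logger = logging.getLogger(__name__)


class TableFormatError(EpihetError):
    """Malformed profile table."""


@dataclass
class ExtractionConfig:
    """Parameters of the epiallele extraction stage."""

    min_coverage: int = 60
    max_span: int = 72
    min_mapping_quality: int = 20
    skip_duplicates: bool = True
    entropy_scale: float = DEFAULT_ENTROPY_SCALE
    log_base: float = 2.0

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.max_span < 3:
            raise ValueError("max_span must be >= 3")


@dataclass
class ReadMethylationCalls:
    """CpG-context methylation calls of one read, keyed by reference position."""

    read_id: str
    chrom: str
    strand: str
    calls: Dict[int, bool]  # reference position -> True if methylated


@dataclass
class ExtractionStats:
    """Counters accumulated while scanning an alignment file."""

    records_seen: int = 0
    records_used: int = 0
    skipped_unmapped: int = 0
    skipped_mapq: int = 0
    skipped_duplicate: int = 0
    skipped_no_tag: int = 0
    rejected_bad_tag: int = 0


def parse_alignment(
    record: pysam.AlignedSegment,
    config: Optional[ExtractionConfig] = None,
    stats: Optional[ExtractionStats] = None,
) -> Optional[ReadMethylationCalls]:
    """Extract CpG methylation calls from one aligned record.

    Only CpG-context calls ('Z' methylated / 'z' unmethylated in the Bismark
    XM dialect) are retained; other context characters are ignored.  Reference
    positions are computed CIGAR-aware via the alignment's aligned pairs, so
    insertions and deletions are handled correctly.  Returns ``None`` for
    records removed by the mapped/quality/duplicate filters or lacking a
    usable call string.
    """
    config = config or ExtractionConfig()
    if stats is not None:
        stats.records_seen += 1
    if record.is_unmapped:
        if stats is not None:
            stats.skipped_unmapped += 1
        return None
    if record.mapping_quality < config.min_mapping_quality:
        if stats is not None:
            stats.skipped_mapq += 1
        return None
    if config.skip_duplicates and record.is_duplicate:
        if stats is not None:
            stats.skipped_duplicate += 1
        return None
    try:
        xm = record.get_tag("XM")
    except KeyError:
        if stats is not None:
            stats.skipped_no_tag += 1
        logger.warning("read %s lacks an XM methylation-call tag; skipped", record.query_name)
        return None
    if record.query_length and len(xm) != record.query_length:
        if stats is not None:
            stats.rejected_bad_tag += 1
        raise EpihetError(
            f"read {record.query_name}: XM length {len(xm)} != query length {record.query_length}"
        )
    calls: Dict[int, bool] = {}
    for qpos, rpos in record.get_aligned_pairs(matches_only=True):
        ch = xm[qpos]
        if ch == "Z":
            calls[rpos] = True
        elif ch == "z":
            calls[rpos] = False
    if stats is not None:
        stats.records_used += 1
    strand = "-" if record.is_reverse else "+"
    return ReadMethylationCalls(record.query_name, record.reference_name, strand, calls)


def enumerate_loci(
    cpg_positions: Sequence[int],
    max_span: int,
    chrom: str = "",
    strand: str = "+",
) -> List[LocusKey]:
    """Slide a 4-CpG window (stride 1) over sorted CpG positions.

    Every window whose first-to-fourth distance is within ``max_span`` yields
    one locus; overlapping windows are all emitted.
    """
    pos = sorted(set(int(p) for p in cpg_positions))
    loci = []
    for i in range(len(pos) - 3):
        window = tuple(pos[i : i + 4])
        if window[3] - window[0] <= max_span:
            loci.append(LocusKey(chrom, window, strand))
    return loci


def profile_sample(
    reads: Iterable[ReadMethylationCalls],
    loci: Sequence[LocusKey],
    config: Optional[ExtractionConfig] = None,
) -> List[EpialleleProfile]:
    """Tally epiallele counts per locus from one sample's reads.

    A read contributes to a locus only when it carries determinate calls at
    all four CpGs (matching chrom and strand).  Overlapping paired-end mates
    are deduplicated by read id, so a fragment counts once per locus.  Loci
    with total coverage below ``min_coverage`` are discarded.
    """
    config = config or ExtractionConfig()
    by_key: Dict[tuple, List[LocusKey]] = {}
    for locus in loci:
        by_key.setdefault((locus.chrom, locus.strand), []).append(locus)

    counts: Dict[LocusKey, np.ndarray] = {l: np.zeros(N_PATTERNS, dtype=np.int64) for l in loci}
    seen: Dict[LocusKey, set] = {l: set() for l in loci}
    for read in reads:
        cand = by_key.get((read.chrom, read.strand))
        if not cand:
            continue
        for locus in cand:
            states = []
            for p in locus.positions:
                call = read.calls.get(p)
                if call is None:
                    break
                states.append(call)
            if len(states) != 4:
                continue
            if read.read_id in seen[locus]:
                continue  # second mate of an overlapping pair
            seen[locus].add(read.read_id)
            counts[locus][encode_pattern(states)] += 1

    out = []
    for locus in loci:
        c = counts[locus]
        if c.sum() >= config.min_coverage:
            out.append(EpialleleProfile(locus, c))
    return out


def extract_sample(
    alignment_path: str,
    config: Optional[ExtractionConfig] = None,
    region: Optional[str] = None,
) -> tuple[List[EpialleleProfile], ExtractionStats]:
    """Scan a SAM/BAM file end to end and return passing profiles.

    CpG positions are collected from the reads' own call strings, loci are
    enumerated per chromosome and strand, and profiles are tallied.
    """
    config = config or ExtractionConfig()
    stats = ExtractionStats()
    reads: List[ReadMethylationCalls] = []
    cpg_sites: Dict[tuple, set] = {}
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_path, mode) as af:
        it = af.fetch(region=region) if region else af
        for rec in it:
            parsed = parse_alignment(rec, config, stats)
            if parsed is None or not parsed.calls:
                continue
            reads.append(parsed)
            cpg_sites.setdefault((parsed.chrom, parsed.strand), set()).update(parsed.calls)
    loci: List[LocusKey] = []
    for (chrom, strand), sites in sorted(cpg_sites.items()):
        loci.extend(enumerate_loci(sorted(sites), config.max_span, chrom, strand))
    profiles = profile_sample(reads, loci, config)
    logger.info(
        "extracted %d loci from %s (%d/%d reads used)",
        len(profiles), alignment_path, stats.records_used, stats.records_seen,
    )
    return profiles, stats


@dataclass
class LocusComparison:
    """Two-sample per-locus record: both profiles plus the entropy shift."""

    locus: LocusKey
    profile_a: EpialleleProfile
    profile_b: EpialleleProfile
    s_a: float
    s_b: float
    ds: float


def compare_samples(
    profiles_a: Sequence[EpialleleProfile],
    profiles_b: Sequence[EpialleleProfile],
    config: Optional[ExtractionConfig] = None,
) -> List[LocusComparison]:
    """Join two samples' profiles on shared loci and compute Delta entropy.

    Only loci passing coverage in BOTH samples appear; sample A is the
    baseline for the sign of the shift.
    """
    config = config or ExtractionConfig()
    index_a = {p.locus: p for p in profiles_a}
    out = []
    for pb in profiles_b:
        pa = index_a.get(pb.locus)
        if pa is None:
            continue
        s_a = combinatorial_entropy(pa, config.entropy_scale, config.log_base)
        s_b = combinatorial_entropy(pb, config.entropy_scale, config.log_base)
        out.append(LocusComparison(pb.locus, pa, pb, s_a, s_b, s_b - s_a))
    out.sort(key=lambda r: r.locus)
    if not out:
        logger.info("no shared loci between the two samples")
    return out


# ---------------------------------------------------------------------------
# Profile-table serialization (gzip TSV)
# ---------------------------------------------------------------------------

_FIXED_COLS = ["chrom", "start", "end", "strand", "positions"]
_P_A = [f"p{i}_a" for i in range(N_PATTERNS)]
_P_B = [f"p{i}_b" for i in range(N_PATTERNS)]
_SINGLE_HEADER = _FIXED_COLS + ["total_a", "s_a"] + _P_A
_PAIRED_HEADER = _FIXED_COLS + ["total_a", "total_b", "s_a", "s_b", "ds"] + _P_A + _P_B


def _locus_fields(locus: LocusKey) -> list[str]:
    # start/end: 1-based inclusive coordinates of the first/fourth CpG
    return [
        locus.chrom,
        str(locus.positions[0] + 1),
        str(locus.positions[3] + 1),
        locus.strand,
        ",".join(map(str, locus.positions)),
    ]


def write_profile_table(records: Sequence, path: str,
                        config: Optional[ExtractionConfig] = None) -> None:
    """Write single-sample profiles or two-sample comparisons as gzip TSV.

    The single-sample schema omits the ``*_b`` and ``ds`` columns.
    Proportions are written with 6 decimals.
    """
    config = config or ExtractionConfig()
    paired = bool(records) and isinstance(records[0], LocusComparison)
    header = _PAIRED_HEADER if paired else _SINGLE_HEADER
    with gzip.open(path, "wt") as fh:
        fh.write(f"# {BIT_CONVENTION}\n")
        fh.write("\t".join(header) + "\n")
        for rec in records:
            if paired:
                pa, pb = rec.profile_a, rec.profile_b
                row = _locus_fields(rec.locus) + [
                    str(pa.total), str(pb.total),
                    f"{rec.s_a:.6f}", f"{rec.s_b:.6f}", f"{rec.ds:.6f}",
                ]
                row += [f"{x:.6f}" for x in pa.proportions()]
                row += [f"{x:.6f}" for x in pb.proportions()]
            else:
                s = combinatorial_entropy(rec, config.entropy_scale, config.log_base)
                row = _locus_fields(rec.locus) + [str(rec.total), f"{s:.6f}"]
                row += [f"{x:.6f}" for x in rec.proportions()]
            fh.write("\t".join(row) + "\n")


def _profile_from_row(locus: LocusKey, total: int, props: Sequence[float]) -> EpialleleProfile:
    counts = np.rint(np.asarray(props, dtype=float) * total).astype(np.int64)
    # rounding can be off by a read; repair on the argmax to preserve the total
    drift = total - int(counts.sum())
    if drift != 0:
        counts[int(np.argmax(counts))] += drift
    return EpialleleProfile(locus, counts)


def read_profile_table(path: str):
    """Read a profile table written by :func:`write_profile_table`.

    Returns ``(records, mode)`` where mode is ``'single'`` or ``'paired'``;
    records are :class:`EpialleleProfile` or :class:`LocusComparison`.
    """
    opener = gzip.open if path.endswith(".gz") else open
    records: list = []
    with opener(path, "rt") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header == _SINGLE_HEADER:
                    paired = False
                elif header == _PAIRED_HEADER:
                    paired = True
                else:
                    raise TableFormatError(f"line {lineno}: unrecognized header")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise TableFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            chrom, start, end, strand, pos = fields[:5]
            locus = LocusKey(chrom, tuple(int(p) for p in pos.split(",")), strand)
            if locus.positions[0] != int(start) - 1 or locus.positions[3] != int(end) - 1:
                raise TableFormatError(f"line {lineno}: start/end disagree with positions")
            if paired:
                total_a, total_b = int(fields[5]), int(fields[6])
                s_a, s_b, ds = (float(x) for x in fields[7:10])
                p_a = [float(x) for x in fields[10 : 10 + N_PATTERNS]]
                p_b = [float(x) for x in fields[10 + N_PATTERNS :]]
                records.append(
                    LocusComparison(
                        locus,
                        _profile_from_row(locus, total_a, p_a),
                        _profile_from_row(locus, total_b, p_b),
                        s_a, s_b, ds,
                    )
                )
            else:
                total = int(fields[5])
                p_a = [float(x) for x in fields[7:]]
                records.append(_profile_from_row(locus, total, p_a))
    if header is None:
        raise TableFormatError("empty table: no header line")
    return records, ("paired" if paired else "single")
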
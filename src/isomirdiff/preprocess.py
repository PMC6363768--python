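"""Read cleaning: 3' adapter trimming, collapsing, contaminant exclusion.

Small-RNA libraries are sequenced through the insert into the 3' adapter,
so the adapter's 5' end appears somewhere inside almost every read.  The
trimmer removes the leftmost qualifying adapter occurrence and everything
after it.  Surviving reads are collapsed to unique sequences with
per-sample counts, then any read occurring verbatim (or as the reverse
complement, by default) inside an rRNA/tRNA/snoRNA/lncRNA reference is
excluded.  Per-sample clean-read totals — the N1/N2 library sizes of the
downstream count test — are recomputed after contaminant removal.

Every discarded read carries a reason tag so that raw counts are exactly
conserved: raw = retained + discarded.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .seqio import normalize_sequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_BOUNDS = (18, 26)


@dataclass
class CollapsedRead:
    """A unique read sequence with per-sample counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class SampleLibrary:
    """Per-sample bookkeeping; ``total_clean_reads`` is the test's N."""

    sample_id: str
    condition: str = ""
    experiment: str = ""
    total_clean_reads: int = 0


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    require_adapter: bool = False,
) -> tuple[str | None, str]:
    """Trim the 3' adapter from one read.

    Scans every position of the read for an occurrence of an adapter
    *prefix* of length >= ``min_overlap`` whose mismatch fraction is
    <= ``max_mismatch_rate``; the leftmost qualifying position wins and the
    read is cut there.  At each position the prefix length is capped by the
    bases remaining in the read, so a partial adapter hanging off the 3'
    end still qualifies once ``min_overlap`` bases are visible.

    Returns ``(trimmed_read, "")`` on success.  When no position qualifies
    the read is returned unchanged unless ``require_adapter`` is set, in
    which case ``(None, "no_adapter")`` is returned.  An empty read is
    always rejected with reason ``"empty"``.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    if not read:
        return None, "empty"
    n = len(read)
    for pos in range(n - min_overlap + 1):
        max_len = min(len(adapter), n - pos)
        budget = max_mismatch_rate * max_len  # mismatch count is monotone in length
        mismatches = 0
        for length in range(1, max_len + 1):
            if read[pos + length - 1] != adapter[length - 1]:
                mismatches += 1
                if mismatches > budget:
                    break
            if length >= min_overlap and mismatches <= max_mismatch_rate * length:
                return read[:pos], ""
    if require_adapter:
        return None, "no_adapter"
    return read, ""


def trim_reads(
    reads: list[str],
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    require_adapter: bool = False,
) -> tuple[list[str], Counter]:
    """Trim a batch of reads; returns (trimmed reads, discard reasons).

    A fast path handles the common case of an exact adapter prefix match:
    when no mismatches are tolerated at any admissible prefix length the
    leftmost exact occurrence of the ``min_overlap``-base adapter seed is
    provably the leftmost qualifying position, so ``str.find`` suffices.
    """
    exact_only = max_mismatch_rate * len(adapter) < 1.0
    seed = adapter[:min_overlap]
    trimmed: list[str] = []
    reasons: Counter = Counter()
    for read in reads:
        if exact_only:
            if not read:
                reasons["empty"] += 1
                continue
            pos = read.find(seed)
            # A seed hit can sit closer than min_overlap to the 3' end only
            # if the full remaining suffix matches, which find() guarantees
            # for the seed portion; shorter-than-seed tails cannot qualify.
            if pos != -1:
                trimmed.append(read[:pos])
            elif require_adapter:
                reasons["no_adapter"] += 1
            else:
                trimmed.append(read)
            continue
        out, reason = trim_adapter(read, adapter, min_overlap, max_mismatch_rate, require_adapter)
        if out is None:
            reasons[reason] += 1
        else:
            trimmed.append(out)
    return trimmed, reasons


def collapse_reads(
    reads_by_sample: dict[str, list[str]],
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> tuple[list[CollapsedRead], dict[str, SampleLibrary], dict[str, Counter]]:
    """Collapse trimmed reads to unique sequences with per-sample counts.

    Reads outside ``length_bounds`` are discarded with reason ``"length"``;
    reads containing ``N`` with reason ``"ambiguous_base"``.  The result is
    independent of input read order.  A sample in which no read survives is
    an error: its downstream library size would be zero.
    """
    lo, hi = length_bounds
    per_seq: dict[str, dict[str, int]] = defaultdict(dict)
    libraries: dict[str, SampleLibrary] = {}
    discards: dict[str, Counter] = {}
    for sample_id, reads in reads_by_sample.items():
        reasons: Counter = Counter()
        counts: Counter = Counter()
        for read in reads:
            read = normalize_sequence(read)
            if not (lo <= len(read) <= hi):
                reasons["length"] += 1
            elif "N" in read:
                reasons["ambiguous_base"] += 1
            else:
                counts[read] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"sample {sample_id!r}: no reads survive length/N filters")
        for seq, c in counts.items():
            per_seq[seq][sample_id] = c
        libraries[sample_id] = SampleLibrary(sample_id, total_clean_reads=total)
        discards[sample_id] = reasons
    collapsed = [
        CollapsedRead(seq, dict(sorted(cts.items()))) for seq, cts in sorted(per_seq.items())
    ]
    return collapsed, libraries, discards


def filter_contaminants(
    collapsed: list[CollapsedRead],
    references: list[tuple[str, str, str]],
    libraries: dict[str, SampleLibrary] | None = None,
    both_strands: bool = True,
) -> tuple[list[CollapsedRead], list[dict]]:
    """Remove reads matching contaminant references exactly.

    ``references`` is a list of ``(ref_id, category, sequence)`` — category
    being e.g. ``rRNA``/``tRNA``/``snoRNA``/``lncRNA``.  A collapsed read is
    removed iff its sequence, or its reverse complement when
    ``both_strands`` is on, occurs as an exact substring of any reference
    (zero-mismatch alignment, matching the precursor-mapping stringency).
    The removal log records the first matching reference in input order.
    Library totals, when given, are recomputed in place from the retained
    set.
    """
    if not references:
        logger.warning("empty contaminant reference set: pass-through")
        refs = []
    else:
        refs = [(rid, cat, normalize_sequence(seq)) for rid, cat, seq in references]
    retained: list[CollapsedRead] = []
    removal_log: list[dict] = []
    for read in collapsed:
        probes = [read.sequence]
        if both_strands:
            probes.append(reverse_complement(read.sequence))
        hit = None
        for rid, cat, refseq in refs:
            if any(p in refseq for p in probes):
                hit = (rid, cat)
                break
        if hit is None:
            retained.append(read)
        else:
            removal_log.append(
                {
                    "sequence": read.sequence,
                    "category": hit[1],
                    "reference_id": hit[0],
                    "total_count": read.total_count,
                }
            )
    if libraries is not None:
        totals: Counter = Counter()
        for read in retained:
            for sample_id, c in read.counts.items():
                totals[sample_id] += c
        for sample_id, lib in libraries.items():
            lib.total_clean_reads = totals.get(sample_id, 0)
    return retained, removal_log
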
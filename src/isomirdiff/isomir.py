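"""Templated isomiR detection and terminal-modification profiling.

Collapsed reads are mapped to precursor hairpins allowing **zero
mismatches** on the sense strand, so every reported variant is templated
by construction: its sequence is read verbatim off the precursor.  A read
overlapping an annotated mature miRNA becomes an isomiR record whose 5'
and 3' offsets are measured relative to the canonical mature interval
(negative 5' offset = 5' extension, positive 3' offset = 3' extension).

Classes:

* ``canonical``        — offsets (0, 0); the annotated mature itself.
* ``five_prime``       — shifted 5' end only.
* ``three_prime``      — shifted 3' end only (other than +1).
* ``three_prime_plus1``— canonical 5' end, exactly one extra templated
                          base at the 3' end; tracked separately because
                          single-base 3' addition is the dominant
                          terminal-modification event in plants.
* ``both_ends``        — both ends shifted.

Canonical-equal reads are retained for reporting but excluded from isomiR
summaries (a canonical mature is not an isomiR).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .preprocess import CollapsedRead
from .seqio import MatureAnnotation, PrecursorRecord

CLASS_CANONICAL = "canonical"
CLASS_5P = "five_prime"
CLASS_3P = "three_prime"
CLASS_3P_PLUS1 = "three_prime_plus1"
CLASS_BOTH = "both_ends"

DEFAULT_MAX_OFFSET = 5
DEFAULT_MIN_OVERLAP_FRAC = 0.75


@dataclass(frozen=True)
class PrecursorHit:
    """An exact sense-strand occurrence of a read on a precursor."""

    precursor_id: str
    start: int
    end: int


@dataclass
class IsomiRRecord:
    sequence: str
    hits: list[PrecursorHit]
    overlapped_matures: list[str]
    offset5: int
    offset3: int
    iso_class: str
    counts: dict[str, int] = field(default_factory=dict)
    isomir_id: str = ""
    best_mature_id: str = ""
    # Precursor base just past the canonical 3' end, for 3'+1 addition
    # tallies (equals base3 for three_prime_plus1 records).

    @property
    def base5(self) -> str:
        return self.sequence[0]

    @property
    def base3(self) -> str:
        return self.sequence[-1]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class TerminalSummary:
    """Per-condition tally of isomiR first/last nucleotides."""

    condition: str
    n_isomirs: int
    tally5: dict[str, int]
    tally3: dict[str, int]


def map_exact(
    sequences: list[str], precursors: dict[str, PrecursorRecord]
) -> dict[str, list[PrecursorHit]]:
    """Map each sequence to every exact sense-strand occurrence on every
    precursor.  Sequences with no occurrence map to an empty list."""
    prec_items = sorted(precursors.items())
    out: dict[str, list[PrecursorHit]] = {}
    for seq in sequences:
        hits: list[PrecursorHit] = []
        for pid, prec in prec_items:
            start = prec.sequence.find(seq)
            while start != -1:
                hits.append(PrecursorHit(pid, start, start + len(seq)))
                start = prec.sequence.find(seq, start + 1)
        out[seq] = hits
    return out


def _candidate_matures(
    hit: PrecursorHit,
    matures: list[MatureAnnotation],
    max_offset: int,
    min_overlap_frac: float,
) -> list[tuple[int, int, MatureAnnotation]]:
    """Matures on this precursor compatible with the hit, as
    (offset5, offset3, mature) tuples."""
    out = []
    for mat in matures:
        o5 = hit.start - mat.start
        o3 = hit.end - mat.end
        if abs(o5) > max_offset or abs(o3) > max_offset:
            continue
        overlap = min(hit.end, mat.end) - max(hit.start, mat.start)
        if overlap < min_overlap_frac * len(mat):
            continue
        out.append((o5, o3, mat))
    return out


def classify_isomir(
    read: CollapsedRead,
    hits: list[PrecursorHit],
    matures_by_precursor: dict[str, list[MatureAnnotation]],
    max_offset: int = DEFAULT_MAX_OFFSET,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> tuple[IsomiRRecord | None, str]:
    """Classify a mapped read against the mature annotations.

    For every hit, candidate matures with sufficient overlap and end
    offsets within ``max_offset`` are collected; the record lists the
    union of all overlapped matures, while offsets and class come from
    the best (hit, mature) pair — smallest ``|offset5| + |offset3|``,
    ties broken by smaller ``|offset5|``, then precursor id, then mature
    id.  Returns ``(record, "")`` or ``(None, "no_mature_overlap")``.

    The function is a pure function of its arguments: hit order does not
    affect the result.
    """
    if not hits:
        raise ValueError("classify_isomir requires at least one hit")
    best = None  # (sort key, o5, o3, mature)
    overlapped: set[str] = set()
    for hit in sorted(hits, key=lambda h: (h.precursor_id, h.start)):
        for o5, o3, mat in _candidate_matures(
            hit, matures_by_precursor.get(hit.precursor_id, []), max_offset, min_overlap_frac
        ):
            overlapped.add(mat.mature_id)
            key = (abs(o5) + abs(o3), abs(o5), mat.precursor_id, mat.mature_id)
            if best is None or key < best[0]:
                best = (key, o5, o3, mat)
    if best is None:
        return None, "no_mature_overlap"
    _, o5, o3, mat = best
    if o5 == 0 and o3 == 0:
        iso_class = CLASS_CANONICAL
    elif o5 == 0 and o3 == 1:
        iso_class = CLASS_3P_PLUS1
    elif o5 == 0:
        iso_class = CLASS_3P
    elif o3 == 0:
        iso_class = CLASS_5P
    else:
        iso_class = CLASS_BOTH
    record = IsomiRRecord(
        sequence=read.sequence,
        hits=sorted(hits, key=lambda h: (h.precursor_id, h.start)),
        overlapped_matures=sorted(overlapped),
        offset5=o5,
        offset3=o3,
        iso_class=iso_class,
        counts=dict(read.counts),
        best_mature_id=mat.mature_id,
    )
    return record, ""


def detect_isomirs(
    collapsed: list[CollapsedRead],
    precursors: dict[str, PrecursorRecord],
    matures: list[MatureAnnotation],
    max_offset: int = DEFAULT_MAX_OFFSET,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    species_code: str = "xxx",
) -> tuple[list[IsomiRRecord], dict[str, list[str]]]:
    """Full detection pass: map, classify, assign ids.

    Returns the records (canonical-equal reads included, flagged by
    class) and a rejection log ``{reason: [sequences]}``.  Each collapsed
    read contributes its counts to exactly one record or to one rejection
    bucket.
    """
    matures_by_precursor: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for mat in matures:
        matures_by_precursor[mat.precursor_id].append(mat)
    hit_map = map_exact([r.sequence for r in collapsed], precursors)
    records: list[IsomiRRecord] = []
    rejected: dict[str, list[str]] = defaultdict(list)
    for read in collapsed:
        hits = hit_map[read.sequence]
        if not hits:
            rejected["unmapped"].append(read.sequence)
            continue
        record, reason = classify_isomir(
            read, hits, matures_by_precursor, max_offset, min_overlap_frac
        )
        if record is None:
            rejected[reason].append(read.sequence)
        else:
            records.append(record)
    records = assign_ids(records, species_code)
    return records, dict(rejected)


def assign_ids(records: list[IsomiRRecord], species_code: str) -> list[IsomiRRecord]:
    """Assign stable ids ``t-<sp>-isomiR-<n>``.

    Records must be unique by sequence.  n runs 1..K in descending total
    read count, ties broken by sequence lexicographic order — a
    deterministic convention, so reruns on identical input give identical
    ids.
    """
    seqs = [r.sequence for r in records]
    if len(set(seqs)) != len(seqs):
        raise ValueError("assign_ids: duplicate sequences among records")
    ordered = sorted(records, key=lambda r: (-r.total_count, r.sequence))
    for n, rec in enumerate(ordered, start=1):
        rec.isomir_id = f"t-{species_code}-isomiR-{n}"
    return ordered


def _conditions_with_counts(
    record: IsomiRRecord, sample_conditions: dict[str, str]
) -> set[str]:
    return {
        sample_conditions[s]
        for s, c in record.counts.items()
        if c > 0 and s in sample_conditions
    }


def summarize_termini(
    records: list[IsomiRRecord],
    sample_conditions: dict[str, str],
    conditions: list[str] | None = None,
) -> list[TerminalSummary]:
    """Tally 5'/3' terminal nucleotides of isomiRs per condition.

    An isomiR is counted in every condition where it has a nonzero read
    count in at least one sample (distinct sequences per condition);
    canonical-class records are excluded.  Both tallies therefore sum to
    the per-condition isomiR count.
    """
    if conditions is None:
        conditions = sorted(set(sample_conditions.values()))
    tallies = {c: (Counter(), Counter()) for c in conditions}
    n_iso = Counter()
    for rec in records:
        if rec.iso_class == CLASS_CANONICAL:
            continue
        for cond in _conditions_with_counts(rec, sample_conditions):
            if cond in tallies:
                tallies[cond][0][rec.base5] += 1
                tallies[cond][1][rec.base3] += 1
                n_iso[cond] += 1
    return [
        TerminalSummary(
            condition=c,
            n_isomirs=n_iso[c],
            tally5={b: tallies[c][0].get(b, 0) for b in "ACGT"},
            tally3={b: tallies[c][1].get(b, 0) for b in "ACGT"},
        )
        for c in conditions
    ]


def summarize_3p_additions(
    records: list[IsomiRRecord],
    sample_conditions: dict[str, str],
    conditions: list[str] | None = None,
) -> list[dict]:
    """Per-condition count of 3'+1 isomiRs and tally of the added base.

    The added base is the record's 3' terminal nucleotide, which for a
    3'+1 isomiR equals the precursor base just past the canonical mature
    end.  Bases with zero occurrences are omitted from the tally.
    """
    if conditions is None:
        conditions = sorted(set(sample_conditions.values()))
    out = []
    for cond in conditions:
        tally: Counter = Counter()
        for rec in records:
            if rec.iso_class != CLASS_3P_PLUS1:
                continue
            if cond in _conditions_with_counts(rec, sample_conditions):
                tally[rec.base3] += 1
        out.append(
            {
                "condition": cond,
                "n_3p_plus1": sum(tally.values()),
                "tally3": {b: tally[b] for b in "ACGT" if tally[b] > 0},
            }
        )
    return out


def format_tally(tally: dict[str, int], omit_zero: bool = False) -> str:
    """Render a base tally as the conventional ``A:n;C:n;G:n;T:n`` string."""
    items = [(b, n) for b, n in sorted(tally.items()) if n > 0 or not omit_zero]
    return ";".join(f"{b}:{n}" for b, n in items)


def records_to_table(records: list[IsomiRRecord], samples: list[str]):
    """Flatten isomiR records into a report table (one row per record)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {
            "isomir_id": rec.isomir_id,
            "sequence": rec.sequence,
            "length": len(rec.sequence),
            "class": rec.iso_class,
            "offset5": rec.offset5,
            "offset3": rec.offset3,
            "base5": rec.base5,
            "base3": rec.base3,
            "hits": ";".join(f"{h.precursor_id}:{h.start}-{h.end}" for h in rec.hits),
            "overlapped_matures": ";".join(rec.overlapped_matures),
        }
        for s in samples:
            row[f"count_{s}"] = rec.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
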
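"""Sequence and table I/O for the isomiR pipeline.

Reference sequences (precursor hairpins, mature miRNAs, contaminant small
RNAs, mimic transcripts) arrive as FASTA; reads as FASTA or FASTQ.  All
sequences are uppercased and RNA ``U`` is normalized to ``T`` at parse time
so that every downstream comparison happens in a single DNA alphabet.
Coordinates are 0-based half-open everywhere internally; rendered reports
may convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters allowed in reference sequences after U->T normalization.
REFERENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A record in a sequence file violates its format."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA hairpin sequence from a reference set.

    ``species_code`` is the miRBase-style 3-letter organism prefix
    (e.g. ``ath`` for *Arabidopsis thaliana*).
    """

    precursor_id: str
    sequence: str
    species_code: str = "xxx"
    source: str = "other"  # miRBase | PMRD | other

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"precursor {self.precursor_id}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ParseError(
                f"precursor {self.precursor_id}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """A canonical mature miRNA located on its precursor.

    The interval is 0-based half-open on the precursor, so
    ``precursor.sequence[start:end] == sequence`` always holds.
    """

    mature_id: str
    precursor_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"mature {self.mature_id}: bad interval [{self.start}, {self.end})")
        if not (15 <= len(self.sequence) <= 30):
            raise ValueError(
                f"mature {self.mature_id}: length {len(self.sequence)} outside [15, 30]"
            )
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"mature {self.mature_id}: interval/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


def parse_sequences(path: str | Path, format: str = "fasta"):
    """Parse a FASTA/FASTQ file into a list of tuples.

    Returns ``(id, sequence)`` pairs for FASTA and ``(id, sequence,
    quality_string)`` triples for FASTQ, in file order, with sequences
    uppercased and U normalized to T.  An empty file yields an empty list.

    Raises
    ------
    ParseError
        If a record is malformed; the message names the record index.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    out = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            seq = normalize_sequence(str(rec.seq))
            if format == "fastq":
                quals = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(q + 33) for q in quals)
                out.append((rec.id, seq, qual))
            else:
                out.append((rec.id, seq))
    except ValueError as exc:
        raise ParseError(f"malformed {format} record at index {len(out)}: {exc}") from exc
    return out


def write_sequences(records: Iterable[tuple], path: str | Path, format: str = "fasta") -> None:
    """Write ``(id, seq)`` or ``(id, seq, qual)`` tuples as FASTA/FASTQ."""
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec[0]}\n{rec[1]}\n")
            elif format == "fastq":
                fh.write(f"@{rec[0]}\n{rec[1]}\n+\n{rec[2]}\n")
            else:
                raise ValueError(f"unsupported format: {format!r}")


def load_precursors(path: str | Path, species_code: str = "xxx", source: str = "other"):
    """Load a precursor FASTA into a dict keyed by precursor id."""
    precursors: dict[str, PrecursorRecord] = {}
    for pid, seq in parse_sequences(path, "fasta"):
        if pid in precursors:
            raise ParseError(f"duplicate precursor id {pid!r}")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ParseError(f"precursor {pid}: characters {sorted(bad)} not allowed in references")
        precursors[pid] = PrecursorRecord(pid, seq, species_code=species_code, source=source)
    return precursors


def locate_mature(precursor: PrecursorRecord, mature_sequence: str, mature_id: str = "") -> list[MatureAnnotation]:
    """Locate every exact occurrence of a mature sequence on a precursor.

    Occurrences may overlap; annotations are returned in ascending start
    order.  Zero occurrences yield an empty list and a logged warning:
    reference databases occasionally pair a mature with a hairpin it does
    not actually derive from, and such pairs simply contribute nothing.
    """
    mature_sequence = normalize_sequence(mature_sequence)
    hits = []
    start = precursor.sequence.find(mature_sequence)
    while start != -1:
        hits.append(
            MatureAnnotation(
                mature_id=mature_id or f"{precursor.precursor_id}:mature",
                precursor_id=precursor.precursor_id,
                start=start,
                end=start + len(mature_sequence),
                sequence=mature_sequence,
            )
        )
        start = precursor.sequence.find(mature_sequence, start + 1)
    if not hits:
        logger.warning(
            "mature %s not found on precursor %s", mature_id or mature_sequence, precursor.precursor_id
        )
    return hits


def load_matures(
    path: str | Path,
    precursors: dict[str, PrecursorRecord],
    format: str = "auto",
) -> list[MatureAnnotation]:
    """Load mature miRNA annotations.

    Three sources are supported:

    * FASTA of mature sequences — coordinates are recovered by exact
      substring search against every precursor (the miRBase distribution
      ships sequences, not hairpin coordinates);
    * 4+-column TSV with header ``mature_id  precursor_id  start  end``
      (0-based half-open);
    * GFF3 with ``ID`` = mature_id and ``Parent`` = precursor_id.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".fa", ".fasta", ".fna"):
            format = "fasta"
        elif suffix in (".gff", ".gff3"):
            format = "gff3"
        else:
            format = "tsv"
    annots: list[MatureAnnotation] = []
    if format == "fasta":
        for mid, seq in parse_sequences(path, "fasta"):
            for prec in precursors.values():
                annots.extend(locate_mature(prec, seq, mature_id=mid))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"mature_id", "precursor_id", "start", "end"}
        if not required.issubset(df.columns):
            raise ParseError(f"mature TSV must have columns {sorted(required)}")
        for row in df.itertuples(index=False):
            prec = precursors.get(row.precursor_id)
            if prec is None:
                logger.warning("mature %s: unknown precursor %s", row.mature_id, row.precursor_id)
                continue
            start, end = int(row.start), int(row.end)
            annots.append(
                MatureAnnotation(row.mature_id, row.precursor_id, start, end, prec.sequence[start:end])
            )
    elif format == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ParseError(f"GFF3 line with {len(fields)} fields: {line!r}")
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                mid = attrs.get("ID")
                pid = attrs.get("Parent", fields[0])
                prec = precursors.get(pid)
                if prec is None:
                    logger.warning("mature %s: unknown precursor %s", mid, pid)
                    continue
                start = int(fields[3]) - 1  # GFF3 is 1-based inclusive
                end = int(fields[4])
                annots.append(MatureAnnotation(mid, pid, start, end, prec.sequence[start:end]))
    else:
        raise ValueError(f"unsupported mature annotation format: {format!r}")
    # Deterministic order: by precursor then position then id.
    annots.sort(key=lambda a: (a.precursor_id, a.start, a.end, a.mature_id))
    return annots


def write_table(records: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write tabular data as a TAB-delimited UTF-8 file with a header row.

    Every row must carry exactly the header's columns; a row with a missing
    column is a contract violation, not silently NA-filled.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            cols = list(records[0].keys())
            for i, row in enumerate(records):
                if list(row.keys()) != cols:
                    raise ValueError(f"row {i} columns {list(row.keys())} != header {cols}")
            df = pd.DataFrame(records, columns=cols)
        else:
            df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TAB-delimited table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
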
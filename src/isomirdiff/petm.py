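"""Plant endogenous target mimics (PeTMs): window extraction + alignment.

A PeTM is a transcript carrying a miRNA-complementary mimic site that
sequesters the miRNA.  To inspect how a canonical miRNA or an isomiR
engages the mimic, the site is padded by 50 nt on each side (clipped at
the transcript ends) and the miRNA's reverse complement is locally
aligned against that window, so perfect miRNA:target complementarity
renders as an identity alignment.

Scoring is a simple convention: match +1, mismatch -1, G:U wobble +0.5,
gap -2 (linear).  The wobble pairs in reverse-complement string space are
(A, G) and (C, T): an aligned query character A stands for miRNA base U
facing target G, and query C for miRNA base G facing target U.  Midline
glyphs: '|' Watson-Crick match, ':' wobble, ' ' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import reverse_complement

MATCH = 1.0
MISMATCH = -1.0
WOBBLE = 0.5
GAP = -2.0
DEFAULT_PAD = 50

#: (query-strand char, window char) pairs that form a G:U wobble once the
#: query is read back on the miRNA strand.
WOBBLE_PAIRS = frozenset({("A", "G"), ("C", "T")})


@dataclass(frozen=True)
class PeTMRecord:
    petm_id: str
    transcript_sequence: str
    site_start: int
    site_end: int
    mimicked_mirna: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.site_start < self.site_end <= len(self.transcript_sequence)):
            raise ValueError(
                f"PeTM {self.petm_id}: site [{self.site_start}, {self.site_end}) outside "
                f"transcript of length {len(self.transcript_sequence)}"
            )


@dataclass
class PeTMAlignment:
    query_id: str
    petm_id: str
    window_start: int  # on the transcript
    window_end: int
    score: float
    aligned_query: str
    midline: str
    aligned_window: str
    target_start: int  # aligned region, transcript coordinates
    target_end: int
    n_gaps: int

    def render(self) -> str:
        head = (
            f"{self.query_id} vs {self.petm_id} "
            f"window [{self.window_start}, {self.window_end}) score {self.score:g}"
        )
        return "\n".join(
            [
                head,
                f"query (rc) {self.aligned_query}",
                f"           {self.midline}",
                f"target     {self.aligned_window}  [{self.target_start}, {self.target_end})",
            ]
        )


def extract_window(record: PeTMRecord, pad: int = DEFAULT_PAD) -> tuple[str, int, int]:
    """Mimic site padded by ``pad`` nt each side, clipped to the transcript.

    Returns ``(subsequence, start, end)`` with transcript coordinates.
    """
    start = max(0, record.site_start - pad)
    end = min(len(record.transcript_sequence), record.site_end + pad)
    return record.transcript_sequence[start:end], start, end


def _pair_score(q: str, w: str) -> float:
    if q == w:
        return MATCH
    if (q, w) in WOBBLE_PAIRS:
        return WOBBLE
    return MISMATCH


def _midline_char(q: str, w: str) -> str:
    if q == w:
        return "|"
    if (q, w) in WOBBLE_PAIRS:
        return ":"
    return " "


def align_to_window(
    query: str,
    window: str,
    query_id: str = "",
    petm_id: str = "",
    window_start: int = 0,
) -> PeTMAlignment:
    """Best local (Smith–Waterman) alignment of the reverse-complemented
    query against the window.

    Ties between equally scoring alignments are resolved deterministically:
    smaller aligned window start first, then fewer gaps, then the smaller
    window end.  The traceback itself prefers diagonal over query-gap over
    window-gap moves.
    """
    if not (15 <= len(query) <= 30):
        raise ValueError(f"query length {len(query)} outside [15, 30]")
    if len(window) < 10:
        raise ValueError(f"window shorter than 10 nt ({len(window)})")
    q = reverse_complement(query)
    n, m = len(q), len(window)
    # H[i][j]: best local score ending at q[:i], window[:j].
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        qi = q[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            row[j] = max(
                0.0,
                prev[j - 1] + _pair_score(qi, window[j - 1]),
                prev[j] + GAP,
                row[j - 1] + GAP,
            )
    best = max(max(row) for row in H)
    candidates = []
    for i in range(n + 1):
        for j in range(m + 1):
            if H[i][j] == best and best > 0:
                candidates.append(_traceback(H, q, window, i, j))
    if not candidates:  # best == 0: no positive-scoring pair at all
        return PeTMAlignment(
            query_id, petm_id, window_start, window_start + m, 0.0, "", "", "",
            window_start, window_start, 0,
        )
    # (window alignment start, gaps, window alignment end) tie-break.
    candidates.sort(key=lambda c: (c[3], c[5], c[4]))
    aq, mid, aw, jstart, jend, gaps = candidates[0]
    return PeTMAlignment(
        query_id=query_id,
        petm_id=petm_id,
        window_start=window_start,
        window_end=window_start + m,
        score=best,
        aligned_query=aq,
        midline=mid,
        aligned_window=aw,
        target_start=window_start + jstart,
        target_end=window_start + jend,
        n_gaps=gaps,
    )


def _traceback(H, q, window, i, j):
    """Greedy traceback from (i, j); diagonal > query-gap > window-gap."""
    aq, mid, aw = [], [], []
    jend = j
    gaps = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        score = H[i][j]
        diag = H[i - 1][j - 1] + _pair_score(q[i - 1], window[j - 1])
        if score == diag:
            aq.append(q[i - 1])
            mid.append(_midline_char(q[i - 1], window[j - 1]))
            aw.append(window[j - 1])
            i, j = i - 1, j - 1
        elif score == H[i - 1][j] + GAP:
            aq.append(q[i - 1])
            mid.append(" ")
            aw.append("-")
            i -= 1
            gaps += 1
        else:
            aq.append("-")
            mid.append(" ")
            aw.append(window[j - 1])
            j -= 1
            gaps += 1
    return "".join(reversed(aq)), "".join(reversed(mid)), "".join(reversed(aw)), j, jend, gaps


def align_records(
    queries: list[tuple[str, str]],
    petms: list[PeTMRecord],
    mirna_of_query: dict[str, set[str]] | None = None,
    pad: int = DEFAULT_PAD,
) -> list[PeTMAlignment]:
    """Align ``(query_id, sequence)`` pairs to PeTM windows.

    When ``mirna_of_query`` is given (query id -> set of canonical mature
    ids, e.g. an isomiR's overlapped matures), each query is aligned only
    to PeTMs whose ``mimicked_mirna`` is in its set; otherwise every query
    meets every PeTM.
    """
    out = []
    for petm in petms:
        window, start, _ = extract_window(petm, pad)
        for qid, seq in queries:
            if mirna_of_query is not None:
                allowed = mirna_of_query.get(qid, set())
                if petm.mimicked_mirna not in allowed:
                    continue
            out.append(align_to_window(seq, window, qid, petm.petm_id, start))
    return out


def load_petms(transcript_fasta, site_tsv) -> list[PeTMRecord]:
    """Load PeTM records from a transcript FASTA plus a site TSV with
    columns petm_id, transcript_id, start, end, mimicked_mirna."""
    import pandas as pd

    from .seqio import parse_sequences

    transcripts = dict(parse_sequences(transcript_fasta, "fasta"))
    sites = pd.read_csv(site_tsv, sep="\t")
    required = {"petm_id", "transcript_id", "start", "end", "mimicked_mirna"}
    if not required.issubset(sites.columns):
        raise ValueError(f"PeTM site TSV must have columns {sorted(required)}")
    records = []
    for row in sites.itertuples(index=False):
        seq = transcripts.get(row.transcript_id)
        if seq is None:
            raise ValueError(f"PeTM {row.petm_id}: unknown transcript {row.transcript_id}")
        records.append(
            PeTMRecord(row.petm_id, seq, int(row.start), int(row.end), row.mimicked_mirna)
        )
    return records
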
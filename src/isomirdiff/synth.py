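"""Synthetic small-RNA datasets with known isomiR truth.

The generator emits exactly what the pipeline consumes — precursor FASTA,
mature coordinate TSV, per-sample FASTQ, contaminant FASTA, a design
table — plus a ``truth.tsv`` recording every planted variant: sequence,
precursor, end offsets, class, per-sample expected counts and planted
fold changes.

Model
-----
Precursors are uniform-random DNA with one designated mature interval.
Each mature spawns a variant catalog: the canonical sequence, a 3'+1
single-base extension, and a configurable number of end-shifted isomiRs
whose offsets are drawn from the configured distributions — sequences are
read off the precursor, so every variant is templated by construction.
Catalog weights are lognormal, rescaled so that the 3'+1 class receives a
fixed fraction of the miRNA read mass.  Planted differential variants
have their weight multiplied by the fold change in stress conditions
(half up, half down by default, keeping library composition balanced).

Per-sample counts follow a gamma-multinomial scheme: each variant draws a
gamma-distributed abundance around its expected value (shape 1/dispersion,
so the marginal is negative-binomial-like with the configured dispersion)
and the fixed miRNA read budget is split multinomially.  This keeps every
FASTQ at exactly ``library_size`` records while still exercising the
model-based test's dispersion estimation.  Raw reads are the variant
sequence followed by the 3' adapter, truncated to the read length;
contaminant reads are random windows of the contaminant references.  No
sequencing-error model is applied by default (the pipeline maps with zero
mismatches, so errored reads can only be dropped); an optional uniform
substitution rate exists to test that drop behaviour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import isomir as _iso
from .seqio import write_sequences, write_table

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_DEFAULT_OFFSET_PROBS = {
    -3: 0.04, -2: 0.08, -1: 0.16, 0: 0.40, 1: 0.16, 2: 0.10, 3: 0.06,
}


@dataclass
class SimConfig:
    seed: int = 1
    n_precursors: int = 50
    precursor_length: int = 120
    mature_length: int = 21
    isomirs_per_mature: int = 6
    n_conditions: int = 2
    replicates_per_condition: int = 2
    library_size: int = 100_000
    offset5_probs: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_OFFSET_PROBS))
    offset3_probs: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_OFFSET_PROBS))
    fraction_3p_plus1: float = 0.2
    canonical_weight: float = 3.0  # mean abundance multiplier of the canonical
    n_de: int = 20
    de_fold_change: float = 4.0
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    contaminant_fraction: float = 0.05
    n_contaminants: int = 12
    contaminant_length: int = 200
    dispersion: float = 0.1
    error_rate: float = 0.0
    length_bounds: tuple[int, int] = (18, 26)
    max_offset: int = 5
    min_overlap_frac: float = 0.75
    species_code: str = "syn"
    experiment: str = "exp1"

    def condition_names(self) -> list[str]:
        return ["control"] + [f"stress{i}" for i in range(1, self.n_conditions)]

    def validate(self) -> None:
        margin = self.max_offset + 1
        if self.mature_length + 2 * margin > self.precursor_length:
            raise ValueError("mature_length + offset margins exceed precursor_length")
        for name, probs in (("offset5_probs", self.offset5_probs), ("offset3_probs", self.offset3_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(abs(o) > self.max_offset for o in probs):
                raise ValueError(f"{name} contains offsets beyond max_offset")
        if not 0.0 <= self.fraction_3p_plus1 < 1.0:
            raise ValueError("fraction_3p_plus1 must be in [0, 1)")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.de_fold_change <= 0:
            raise ValueError("fold changes must be > 0")
        lo, hi = self.length_bounds
        if not (self.read_length >= hi):
            raise ValueError("read_length must cover the longest insert")
        if self.n_conditions < 2:
            raise ValueError("need a control and at least one stress condition")


@dataclass
class Variant:
    """One planted catalog entry (canonical mature or isomiR)."""

    variant_id: str
    sequence: str
    precursor_id: str
    mature_id: str
    offset5: int
    offset3: int
    iso_class: str
    weight: float = 1.0
    fold_changes: dict[str, float] = field(default_factory=dict)  # condition -> fc


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _classify_offsets(o5: int, o3: int) -> str:
    if o5 == 0 and o3 == 0:
        return _iso.CLASS_CANONICAL
    if o5 == 0 and o3 == 1:
        return _iso.CLASS_3P_PLUS1
    if o5 == 0:
        return _iso.CLASS_3P
    if o3 == 0:
        return _iso.CLASS_5P
    return _iso.CLASS_BOTH


def _offset_valid(o5: int, o3: int, cfg: SimConfig) -> bool:
    lo, hi = cfg.length_bounds
    length = cfg.mature_length - o5 + o3
    if not (lo <= length <= hi):
        return False
    overlap = cfg.mature_length - max(0, o5) + min(0, o3)
    return overlap >= cfg.min_overlap_frac * cfg.mature_length


def _occurrences(seq: str, precursor_seqs: list[str]) -> int:
    total = 0
    for p in precursor_seqs:
        start = p.find(seq)
        while start != -1:
            total += 1
            start = p.find(seq, start + 1)
    return total


def build_catalog(cfg: SimConfig, rng: np.random.Generator):
    """Generate precursors, matures and the planted variant catalog."""
    margin = cfg.max_offset + 1
    precursors: list[tuple[str, str]] = []
    matures: list[dict] = []
    variants: list[Variant] = []
    seen: set[str] = set()
    for i in range(cfg.n_precursors):
        pid = f"{cfg.species_code}-MIR{i + 1:03d}"
        mid = f"{cfg.species_code}-miR{i + 1:03d}"
        seq = _random_dna(rng, cfg.precursor_length)
        ms = int(rng.integers(margin, cfg.precursor_length - margin - cfg.mature_length + 1))
        me = ms + cfg.mature_length
        precursors.append((pid, seq))
        matures.append({"mature_id": mid, "precursor_id": pid, "start": ms, "end": me})
        offsets = [(0, 0), (0, 1)]
        o5_vals = np.array(sorted(cfg.offset5_probs))
        o5_p = np.array([cfg.offset5_probs[o] for o in o5_vals], dtype=float)
        o3_vals = np.array(sorted(cfg.offset3_probs))
        o3_p = np.array([cfg.offset3_probs[o] for o in o3_vals], dtype=float)
        attempts = 0
        while len(offsets) < cfg.isomirs_per_mature + 2 and attempts < 200:
            attempts += 1
            o5 = int(rng.choice(o5_vals, p=o5_p / o5_p.sum()))
            o3 = int(rng.choice(o3_vals, p=o3_p / o3_p.sum()))
            if (o5, o3) in offsets or not _offset_valid(o5, o3, cfg):
                continue
            offsets.append((o5, o3))
        for j, (o5, o3) in enumerate(offsets):
            vseq = seq[ms + o5 : me + o3]
            if vseq in seen:
                continue
            seen.add(vseq)
            variants.append(
                Variant(
                    variant_id=f"v{len(variants) + 1:05d}",
                    sequence=vseq,
                    precursor_id=pid,
                    mature_id=mid,
                    offset5=o5,
                    offset3=o3,
                    iso_class=_classify_offsets(o5, o3),
                )
            )
    # Keep only variants occurring exactly once across all precursors, so
    # every plant is unambiguous and its class/offsets are identifiable,
    # and whose sequence survives adapter trimming intact (an internal
    # near-match to the adapter would truncate every read of the variant).
    from .preprocess import trim_adapter

    precursor_seqs = [s for _, s in precursors]
    kept = []
    for v in variants:
        if _occurrences(v.sequence, precursor_seqs) != 1:
            continue
        raw = (v.sequence + cfg.adapter)[: cfg.read_length]
        if trim_adapter(raw, cfg.adapter)[0] != v.sequence:
            continue
        kept.append(v)
    return precursors, matures, kept


def _assign_weights(cfg: SimConfig, rng: np.random.Generator, variants: list[Variant]) -> None:
    for v in variants:
        v.weight = float(rng.lognormal(mean=0.0, sigma=1.0))
        if v.iso_class == _iso.CLASS_CANONICAL:
            v.weight *= cfg.canonical_weight
    w_plus1 = sum(v.weight for v in variants if v.iso_class == _iso.CLASS_3P_PLUS1)
    w_rest = sum(v.weight for v in variants if v.iso_class != _iso.CLASS_3P_PLUS1)
    if w_plus1 > 0 and cfg.fraction_3p_plus1 > 0:
        scale_plus1 = cfg.fraction_3p_plus1 / w_plus1
        scale_rest = (1.0 - cfg.fraction_3p_plus1) / w_rest
        for v in variants:
            v.weight *= scale_plus1 if v.iso_class == _iso.CLASS_3P_PLUS1 else scale_rest


def _plant_de(cfg: SimConfig, rng: np.random.Generator, variants: list[Variant]) -> None:
    """Give ``n_de`` isomiR variants a fold change in every stress
    condition: half up, half down, keeping library totals balanced."""
    stresses = cfg.condition_names()[1:]
    candidates = [i for i, v in enumerate(variants) if v.iso_class != _iso.CLASS_CANONICAL]
    n_de = min(cfg.n_de, len(candidates))
    chosen = rng.choice(np.array(candidates), size=n_de, replace=False)
    for rank, idx in enumerate(sorted(int(i) for i in chosen)):
        fc = cfg.de_fold_change if rank % 2 == 0 else 1.0 / cfg.de_fold_change
        for cond in stresses:
            variants[idx].fold_changes[cond] = fc


def _sample_counts(
    cfg: SimConfig, rng: np.random.Generator, mu: np.ndarray, n_reads: int
) -> np.ndarray:
    """Gamma-multinomial draw: NB-like marginals, exact total."""
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        g = rng.gamma(shape, mu * cfg.dispersion)
    else:
        g = mu.astype(float)
    g = np.maximum(g, 0.0)
    if g.sum() <= 0:
        g = np.ones_like(g)
    return rng.multinomial(n_reads, g / g.sum())


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate a full dataset bundle under ``outdir``.

    Writes ``precursors.fasta``, ``matures.tsv``, ``contaminants.fasta``,
    ``design.tsv``, ``truth.tsv`` and one ``<sample>.fastq`` per sample;
    byte-identical across reruns with the same config.  Returns a dict
    with the paths plus the in-memory truth table.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    precursors, matures, variants = build_catalog(cfg, rng)
    _assign_weights(cfg, rng, variants)
    _plant_de(cfg, rng, variants)
    contaminants = [
        (f"{cat}|{cfg.species_code}-cont{i + 1:03d}", _random_dna(rng, cfg.contaminant_length))
        for i, cat in enumerate(
            ["rRNA", "tRNA", "snoRNA", "lncRNA"][i % 4] for i in range(cfg.n_contaminants)
        )
    ]
    conditions = cfg.condition_names()
    samples = [
        (f"{cond}_rep{r + 1}", cond)
        for cond in conditions
        for r in range(cfg.replicates_per_condition)
    ]
    n_contam = int(round(cfg.contaminant_fraction * cfg.library_size))
    n_mirna = cfg.library_size - n_contam
    weights = np.array([v.weight for v in variants])
    expected: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    fastq_paths: dict[str, Path] = {}
    for sample_id, cond in samples:
        fc = np.array([v.fold_changes.get(cond, 1.0) for v in variants])
        w = weights * fc
        mu = n_mirna * w / w.sum()
        expected[sample_id] = mu
        counts = _sample_counts(cfg, rng, mu, n_mirna)
        observed[sample_id] = counts
        reads: list[str] = []
        for v, c in zip(variants, counts):
            reads.extend([v.sequence] * int(c))
        for _ in range(n_contam):
            ref = contaminants[int(rng.integers(0, len(contaminants)))][1]
            length = int(rng.integers(cfg.length_bounds[0], cfg.length_bounds[1] + 1))
            start = int(rng.integers(0, len(ref) - length + 1))
            reads.append(ref[start : start + length])
        order = rng.permutation(len(reads))
        records = []
        for n, i in enumerate(order):
            raw = (reads[i] + cfg.adapter)[: cfg.read_length]
            raw = _mutate(rng, raw, cfg.error_rate)
            records.append((f"{sample_id}.{n + 1}", raw, "I" * len(raw)))
        path = outdir / f"{sample_id}.fastq"
        write_sequences(records, path, "fastq")
        fastq_paths[sample_id] = path
    # reference files
    write_sequences(precursors, outdir / "precursors.fasta", "fasta")
    write_table(pd.DataFrame(matures), outdir / "matures.tsv")
    write_sequences(contaminants, outdir / "contaminants.fasta", "fasta")
    design = pd.DataFrame(
        {
            "sample": [s for s, _ in samples],
            "condition": [c for _, c in samples],
            "experiment": cfg.experiment,
            "is_control": [int(c == "control") for _, c in samples],
            "fastq": [fastq_paths[s].name for s, _ in samples],  # relative to design.tsv
        }
    )
    write_table(design, outdir / "design.tsv")
    truth_rows = []
    for j, v in enumerate(variants):
        row = {
            "variant_id": v.variant_id,
            "sequence": v.sequence,
            "precursor_id": v.precursor_id,
            "mature_id": v.mature_id,
            "offset5": v.offset5,
            "offset3": v.offset3,
            "class": v.iso_class,
            "weight": v.weight,
        }
        for cond in conditions:
            row[f"fold_change_{cond}"] = v.fold_changes.get(cond, 1.0)
        for sample_id, _ in samples:
            row[f"expected_{sample_id}"] = expected[sample_id][j]
            row[f"count_{sample_id}"] = int(observed[sample_id][j])
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    write_table(truth, outdir / "truth.tsv")
    return {
        "precursors": outdir / "precursors.fasta",
        "matures": outdir / "matures.tsv",
        "contaminants": outdir / "contaminants.fasta",
        "design": outdir / "design.tsv",
        "truth_path": outdir / "truth.tsv",
        "fastq": fastq_paths,
        "truth": truth,
        "config": dataclasses.asdict(cfg),
    }


def simulate_count_matrix(
    n_null: int = 2000,
    n_de: int = 0,
    fold_change: float = 4.0,
    mean: float = 100.0,
    dispersion: float = 0.1,
    reps: tuple[int, int] = (3, 3),
    seed: int = 0,
    balanced: bool = True,
):
    """Replicated two-condition NB count matrices with planted truth.

    Used for calibration and power studies of the differential tests at
    the count level, without simulating reads.  Rows are isomiRs (nulls
    first, then planted); columns replicates.  With ``balanced`` the
    planted fold changes alternate up/down so library totals stay
    comparable.  Returns ``(counts_a, counts_b, is_de, fc)``.
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_de
    fc = np.ones(n)
    mu_a = np.full(n, float(mean))
    if n_de:
        for i in range(n_de):
            j = n_null + i
            if i % 2 == 0 or not balanced:
                fc[j] = fold_change  # up in condition b
            else:
                # down in b, implemented as elevated in a so that the two
                # directions add identical read mass and totals stay equal
                fc[j] = 1.0 / fold_change
                mu_a[j] = mean * fold_change
    mu_b = np.where(fc >= 1.0, mu_a * fc, np.full(n, float(mean)))

    def _nb(mu: np.ndarray, nrep: int) -> np.ndarray:
        mu2 = np.repeat(mu[:, None], nrep, axis=1)
        if dispersion <= 0:
            return rng.poisson(mu2)
        shape = 1.0 / dispersion
        p = shape / (shape + mu2)
        return rng.negative_binomial(shape, p)

    counts_a = _nb(mu_a, reps[0])
    counts_b = _nb(mu_b, reps[1])
    is_de = np.zeros(n, dtype=bool)
    is_de[n_null:] = True
    return counts_a, counts_b, is_de, fc
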
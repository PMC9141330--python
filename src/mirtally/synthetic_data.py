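"""Synthetic small-RNA study generator with full ground truth.

Emits a mature-miR reference FASTA (with optional sequence-identical
locus pairs to exercise reference collapsing), per-group compositions,
negative-binomial true counts, and adapter-ligated FASTQ libraries with
a 3'-decaying quality model and controlled contaminant classes, so every
pipeline stage can be validated against known truth with no external
data.

Determinism: every output is a pure function of (spec, seed).  Each
library draws from its own RNG stream derived by hashing
(seed, sample_id), so adding a library never perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    MatureMiR,
    SampleManifest,
    SmallRNARead,
    write_fastq,
    write_manifest,
    write_mature_fasta,
)
from .mir_quantification import CollapsedReference, CountMatrix, collapse_reference
from .read_processing import TrimParams, find_adapter

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class QualityModel:
    plateau: int = 38  # high-quality plateau Phred
    decay: float = 0.15  # per-cycle decay toward the 3' end
    noise_sd: float = 2.0
    floor: int = 2
    ceiling: int = 40


@dataclass(frozen=True)
class SpikeIn:
    feature_index: int  # index into the collapsed feature list
    group: str
    multiplier: float


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic multi-group small-RNA study.

    Defaults mirror the profiled four-population design: groups Mk, MkMP,
    PLP with 3 replicates each and PLT with 2, 51-cycle reads, and a
    heavy-tailed (log-normal) composition so a handful of features
    dominates each library.
    """

    n_mirs: int = 100
    mature_length_range: tuple[int, int] = (18, 25)
    groups: tuple[str, ...] = ("Mk", "MkMP", "PLP", "PLT")
    replicates: tuple[int, ...] = (3, 3, 3, 2)
    composition_sigma: float = 2.0
    spikes: tuple[SpikeIn, ...] = ()
    dispersion: float = 0.1
    depth: int = 100_000
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 51
    qual_model: QualityModel = QualityModel()
    contaminant_rates: dict = field(
        default_factory=lambda: {"no_adapter": 0.0, "long_insert": 0.0, "low_quality": 0.0}
    )
    n_duplicate_matures: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirs < 1:
            raise ValueError("n_mirs must be >= 1")
        lo, hi = self.mature_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid mature_length_range")
        if len(self.groups) != len(self.replicates):
            raise ValueError("groups and replicates must align")
        if any(r < 1 for r in self.replicates):
            raise ValueError("each group needs >= 1 replicate")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        rates = self.contaminant_rates
        if any(not (0 <= v < 1) for v in rates.values()) or sum(rates.values()) >= 1:
            raise ValueError("contaminant rates must be in [0,1) and sum < 1")
        if self.n_duplicate_matures * 2 > self.n_mirs:
            raise ValueError("too many duplicate pairs for n_mirs")
        if hi + 8 > self.read_length:
            raise ValueError(
                "mature + minimum adapter overlap exceeds read length; "
                "adapter would be undetectable by construction"
            )

    @property
    def n_features(self) -> int:
        """Collapsed feature count (duplicate pairs merge into one feature)."""
        return self.n_mirs - self.n_duplicate_matures

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{group}_{i + 1}"
            for group, reps in zip(self.groups, self.replicates)
            for i in range(reps)
        ]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {
            f"{group}_{i + 1}": group
            for group, reps in zip(self.groups, self.replicates)
            for i in range(reps)
        }


@dataclass
class LibraryLedger:
    """Realized per-library read accounting (sums to the library's total)."""

    assigned: int
    no_adapter: int
    long_insert: int
    low_quality: int

    @property
    def total(self) -> int:
        return self.assigned + self.no_adapter + self.long_insert + self.low_quality

    def as_dict(self) -> dict:
        return {
            "assigned": self.assigned,
            "no_adapter": self.no_adapter,
            "long_insert": self.long_insert,
            "low_quality": self.low_quality,
            "total": self.total,
        }


@dataclass
class GroundTruth:
    counts: CountMatrix  # true counts over collapsed features
    compositions: dict[str, np.ndarray]  # group -> proportions over features
    ledgers: dict[str, LibraryLedger]
    spikes: tuple[SpikeIn, ...]


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------


def _stable_int(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "little")


def _rng(spec: SimulationSpec, *key) -> np.random.Generator:
    parts = [spec.seed] + [_stable_int(k) if isinstance(k, str) else int(k) for k in key]
    return np.random.default_rng(parts)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def generate_reference(spec: SimulationSpec) -> list[MatureMiR]:
    """Random mature entries, unique except the requested duplicate pairs.

    Candidate sequences whose 3' end resembles the adapter prefix are
    rejected so the adapter boundary of every simulated read is
    unambiguous (leftmost detection lands exactly at the insert length).
    Deterministic under the spec seed.
    """
    lo, hi = spec.mature_length_range
    n_unique = spec.n_mirs - spec.n_duplicate_matures
    capacity = sum(4 ** L for L in range(lo, hi + 1))
    if capacity < n_unique * 4:  # margin for adapter-collision rejection
        raise ValueError("mature_length_range too narrow for n_mirs unique sequences")
    rng = _rng(spec, "reference")
    guard = TrimParams(adapter=spec.adapter)
    sequences: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(sequences) < n_unique:
        attempts += 1
        if attempts > 1000 * n_unique:
            raise ValueError("could not generate enough unique mature sequences")
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        if seq in seen:
            continue
        # unambiguous adapter boundary by construction
        if find_adapter(seq + spec.adapter, guard) != len(seq):
            continue
        seen.add(seq)
        sequences.append(seq)
    entries: list[MatureMiR] = []
    for i, seq in enumerate(sequences):
        entries.append(MatureMiR(name=f"syn-mir-{i + 1:04d}-3p", sequence=seq))
    # duplicate pairs: same sequence, distinct locus names (collapse fodder)
    for d in range(spec.n_duplicate_matures):
        entries.append(
            MatureMiR(name=f"syn-mir-{d + 1:04d}-b-3p", sequence=sequences[d])
        )
    return entries


# ---------------------------------------------------------------------------
# composition and counts
# ---------------------------------------------------------------------------


def generate_compositions(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Log-normal per-group proportions with spikes applied then renormalized."""
    rng = _rng(spec, "composition")
    base = np.exp(spec.composition_sigma * rng.standard_normal(spec.n_features))
    compositions: dict[str, np.ndarray] = {}
    for group in spec.groups:
        jitter = np.exp(0.05 * rng.standard_normal(spec.n_features))
        weights = base * jitter
        for spike in spec.spikes:
            if spike.group == group:
                weights[spike.feature_index] *= spike.multiplier
        compositions[group] = weights / weights.sum()
    return compositions


def generate_counts(
    spec: SimulationSpec, compositions: Optional[dict[str, np.ndarray]] = None
) -> CountMatrix:
    """True counts: counts[f, s] ~ NB(mean = depth * p_group(f), phi)."""
    compositions = compositions if compositions is not None else generate_compositions(spec)
    feature_names = [f"feature_{i}" for i in range(spec.n_features)]
    columns = []
    for sample_id in spec.sample_ids:
        group = spec.sample_groups[sample_id]
        mu = spec.depth * compositions[group]
        rng = _rng(spec, "counts", sample_id)
        if spec.dispersion == 0:
            columns.append(rng.poisson(mu))
        else:
            size = 1.0 / spec.dispersion
            p = size / (size + mu)
            columns.append(rng.negative_binomial(size, p))
    counts = np.column_stack(columns).astype(np.int64)
    return CountMatrix(
        feature_names=feature_names,
        sample_ids=spec.sample_ids,
        counts=counts,
        groups=spec.sample_groups,
    )


# ---------------------------------------------------------------------------
# FASTQ libraries
# ---------------------------------------------------------------------------


def _quality_vector(
    rng: np.random.Generator, length: int, model: QualityModel
) -> np.ndarray:
    return _quality_block(rng, 1, length, model)[0]


def _quality_block(
    rng: np.random.Generator, n: int, length: int, model: QualityModel
) -> np.ndarray:
    q = (
        model.plateau
        - model.decay * np.arange(length)
        + model.noise_sd * rng.standard_normal((n, length))
    )
    return np.clip(np.rint(q), model.floor, model.ceiling).astype(np.int64)


_LOW_QUALITY_MODEL = QualityModel(plateau=12, decay=0.05, noise_sd=3.0, floor=2, ceiling=20)


def _assemble_read(
    rng: np.random.Generator, insert: str, spec: SimulationSpec, model: QualityModel
) -> tuple[str, np.ndarray]:
    seq = insert + spec.adapter
    if len(seq) < spec.read_length:
        seq += _random_seq(rng, spec.read_length - len(seq))
    seq = seq[: spec.read_length]
    return seq, _quality_vector(rng, spec.read_length, model)


def _contaminant_no_adapter(rng, spec: SimulationSpec, guard: TrimParams) -> str:
    while True:
        seq = _random_seq(rng, spec.read_length)
        if find_adapter(seq, guard) is None:
            return seq


def _contaminant_insert(rng, spec: SimulationSpec, guard: TrimParams, lo: int, hi: int) -> str:
    while True:
        length = int(rng.integers(lo, hi + 1))
        insert = _random_seq(rng, length)
        read = (insert + spec.adapter)[: spec.read_length]
        if find_adapter(read, guard) == length:
            return insert


def generate_library(
    spec: SimulationSpec,
    sample_id: str,
    true_counts: np.ndarray,
    feature_sequences: Sequence[str],
) -> tuple[list[SmallRNARead], LibraryLedger]:
    """One library's reads (deterministically shuffled) plus its ledger.

    Assigned reads are mature + adapter truncated to the read length with
    plateau-then-decay qualities.  Contaminant classes: adapter-free
    random reads; 41+ nt inserts (kept but outside the miR fraction);
    low-quality reads that empty under quality trimming.  Contaminant
    counts are binomial draws at the configured rates on the nominal
    depth; ledger categories sum to the realized library total.
    """
    rng = _rng(spec, "library", sample_id)
    guard = TrimParams(adapter=spec.adapter)
    rates = {
        "no_adapter": spec.contaminant_rates.get("no_adapter", 0.0),
        "long_insert": spec.contaminant_rates.get("long_insert", 0.0),
        "low_quality": spec.contaminant_rates.get("low_quality", 0.0),
    }
    n_contam = {
        k: int(rng.binomial(spec.depth, r)) if r > 0 else 0 for k, r in rates.items()
    }
    long_hi = min(spec.read_length - guard.min_overlap, guard.long_max)

    reads: list[SmallRNARead] = []
    serial = 0

    def emit_fast(seq: str, quals: list[int]) -> None:
        nonlocal serial
        serial += 1
        reads.append(
            SmallRNARead(
                read_id=f"{sample_id}:{serial:07d}", sequence=seq, qualities=quals
            )
        )

    def emit(seq: str, quals: np.ndarray) -> None:
        emit_fast(seq, [int(q) for q in quals])

    for f, n in enumerate(true_counts):
        n = int(n)
        if n == 0:
            continue
        base = (feature_sequences[f] + spec.adapter)[: spec.read_length]
        pad_len = spec.read_length - len(base)
        if pad_len > 0:
            pads = _BASES[rng.integers(0, 4, size=(n, pad_len))]
            seqs = [base + bytes(row).decode("ascii") for row in pads]
        else:
            seqs = [base] * n
        quals = _quality_block(rng, n, spec.read_length, spec.qual_model).tolist()
        for seq, q in zip(seqs, quals):
            emit_fast(seq, q)
    for _ in range(n_contam["no_adapter"]):
        seq = _contaminant_no_adapter(rng, spec, guard)
        emit(seq, _quality_vector(rng, spec.read_length, spec.qual_model))
    for _ in range(n_contam["long_insert"]):
        insert = _contaminant_insert(rng, spec, guard, guard.insert_max + 1, long_hi)
        emit(*_assemble_read(rng, insert, spec, spec.qual_model))
    for _ in range(n_contam["low_quality"]):
        insert = _contaminant_insert(rng, spec, guard, guard.insert_min, guard.insert_max)
        emit(*_assemble_read(rng, insert, spec, _LOW_QUALITY_MODEL))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    ledger = LibraryLedger(
        assigned=int(np.sum(true_counts)),
        no_adapter=n_contam["no_adapter"],
        long_insert=n_contam["long_insert"],
        low_quality=n_contam["low_quality"],
    )
    return reads, ledger


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    spec: SimulationSpec
    matures: list[MatureMiR]
    reference: CollapsedReference
    truth: GroundTruth
    manifest: SampleManifest


def simulate_study(
    spec: SimulationSpec, out_dir: Optional[str | Path] = None
) -> SimulatedStudy:
    """Generate the full study; optionally write FASTQ/FASTA/TSV artifacts.

    The truth count matrix is indexed by the collapsed feature names so it
    compares directly against the pipeline's output matrix.
    """
    matures = generate_reference(spec)
    reference = collapse_reference(matures)
    assert len(reference.entries) == spec.n_features
    feature_sequences = [e.sequence for e in reference.entries]
    compositions = generate_compositions(spec)
    counts = generate_counts(spec, compositions)
    counts = CountMatrix(
        feature_names=reference.feature_names,
        sample_ids=counts.sample_ids,
        counts=counts.counts,
        groups=counts.groups,
    )

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_mature_fasta(matures, out / "reference.fasta")

    ledgers: dict[str, LibraryLedger] = {}
    entries = []
    for j, sample_id in enumerate(spec.sample_ids):
        reads, ledger = generate_library(
            spec, sample_id, counts.counts[:, j], feature_sequences
        )
        ledgers[sample_id] = ledger
        fastq_path = ""
        if out is not None:
            fastq_path = str(out / f"{sample_id}.fastq")
            write_fastq(reads, fastq_path)
        entries.append((sample_id, fastq_path, spec.sample_groups[sample_id]))
    manifest = SampleManifest(entries=entries)
    if out is not None:
        write_manifest(manifest, out / "manifest.tsv")
        from .io_formats import write_counts, write_json

        write_counts(counts, out / "truth_counts.tsv")
        write_json(
            {s: l.as_dict() for s, l in ledgers.items()}, out / "truth_ledger.json"
        )

    truth = GroundTruth(
        counts=counts, compositions=compositions, ledgers=ledgers, spikes=spec.spikes
    )
    return SimulatedStudy(
        spec=spec, matures=matures, reference=reference, truth=truth, manifest=manifest
    )
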
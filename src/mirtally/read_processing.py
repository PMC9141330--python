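"""Read cleanup: 3' adapter detection, quality end-trimming, size partition.

Only reads whose 3' flanking adapter is detected are retained (they
represent full-length sequencing of the insert).  The retained insert is
then end-trimmed so its mean Phred quality is strictly above a threshold,
and finally partitioned into the miR/piRNA (18-40 nt) and long (41-150 nt)
size fractions.  The default stage order is adapter-first: the adapter
defines the biological insert boundary, and trimming quality first could
destroy the adapter and discard otherwise valid reads; ``order`` exposes
the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SmallRNARead

# Illumina TruSeq small-RNA 3' adapter; a configurable default, not asserted
# to match any particular library prep.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_N = ord("N")


class TrimStatus(str, Enum):
    KEPT = "KEPT"
    NO_ADAPTER = "NO_ADAPTER"
    EMPTY_AFTER_QTRIM = "EMPTY_AFTER_QTRIM"
    OUT_OF_SIZE = "OUT_OF_SIZE"


class SizeFraction(str, Enum):
    MIR_PIRNA_18_40 = "MIR_PIRNA_18_40"
    LONG_40_150 = "LONG_40_150"
    NONE = "NONE"


@dataclass(frozen=True)
class TrimParams:
    """Parameters for the adapter / quality / size cleanup stages."""

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 8
    max_mismatch_rate: float = 0.1
    qual_threshold: float = 30.0
    insert_min: int = 18
    insert_max: int = 40
    long_max: int = 150

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not (0.0 <= self.max_mismatch_rate < 1.0):
            raise ValueError("max_mismatch_rate must be in [0, 1)")
        if len(self.adapter) < self.min_overlap:
            raise ValueError("adapter shorter than min_overlap")
        if not (0 <= self.insert_min <= self.insert_max <= self.long_max):
            raise ValueError("require 0 <= insert_min <= insert_max <= long_max")
        bad = set(self.adapter) - set("ACGTN")
        if bad:
            raise ValueError(f"adapter has non-DNA characters {sorted(bad)}")


@dataclass
class TrimOutcome:
    """Per-read cleanup outcome (KEPT iff non-empty insert in a size fraction)."""

    status: TrimStatus
    insert: str = ""
    insert_qualities: tuple[int, ...] = ()
    fraction: SizeFraction = SizeFraction.NONE


@dataclass
class AttritionStats:
    """Per-status and per-fraction read accounting; statuses sum to the input."""

    by_status: dict[str, int] = field(
        default_factory=lambda: {s.value: 0 for s in TrimStatus}
    )
    by_fraction: dict[str, int] = field(
        default_factory=lambda: {f.value: 0 for f in SizeFraction}
    )
    total: int = 0

    def add(self, outcome: TrimOutcome) -> None:
        self.by_status[outcome.status.value] += 1
        self.by_fraction[outcome.fraction.value] += 1
        self.total += 1

    def merge(self, other: "AttritionStats") -> None:
        for k, v in other.by_status.items():
            self.by_status[k] += v
        for k, v in other.by_fraction.items():
            self.by_fraction[k] += v
        self.total += other.total

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_status": dict(self.by_status),
            "by_fraction": dict(self.by_fraction),
        }


# ---------------------------------------------------------------------------
# per-read primitives
# ---------------------------------------------------------------------------


def find_adapter(sequence: str, params: TrimParams) -> Optional[int]:
    """Leftmost position where the 3' adapter is detected, or None.

    The adapter is detected at position i when the overlap between the
    adapter prefix and the read suffix starting at i has length
    >= min_overlap (it may run off the read end) with at most
    floor(max_mismatch_rate * overlap) mismatches.  'N' always counts as
    a mismatch.
    """
    adapter = params.adapter
    alen = len(adapter)
    length = len(sequence)
    for i in range(0, length - params.min_overlap + 1):
        overlap = min(alen, length - i)
        allowed = int(params.max_mismatch_rate * overlap)
        mismatches = 0
        ok = True
        for j in range(overlap):
            c = sequence[i + j]
            if c == "N" or c != adapter[j]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return i
    return None


def quality_end_trim(
    sequence: str, qualities: Sequence[int], threshold: float
) -> tuple[str, list[int]]:
    """Longest prefix whose mean Phred score is strictly above ``threshold``.

    May return an empty prefix; the caller decides what that means.
    """
    if len(sequence) != len(qualities):
        raise ValueError("sequence/quality length mismatch")
    total = sum(qualities)
    for k in range(len(qualities), 0, -1):
        if total > threshold * k:
            return sequence[:k], list(qualities[:k])
        total -= qualities[k - 1]
    return "", []


def partition_by_size(insert_length: int, params: TrimParams) -> SizeFraction:
    """Map an insert length to its library size fraction."""
    if params.insert_min <= insert_length <= params.insert_max:
        return SizeFraction.MIR_PIRNA_18_40
    if params.insert_max < insert_length <= params.long_max:
        return SizeFraction.LONG_40_150
    return SizeFraction.NONE


def detect_and_trim_adapter(read: SmallRNARead, params: TrimParams) -> TrimOutcome:
    """Adapter stage only: locate the 3' adapter and cut the insert.

    A read with no detectable adapter is NO_ADAPTER (discarded).  A read
    that is pure adapter (detection at position 0) had its adapter detected,
    so it falls to the size rule: the empty insert is OUT_OF_SIZE.
    """
    pos = find_adapter(read.sequence, params)
    if pos is None:
        return TrimOutcome(TrimStatus.NO_ADAPTER)
    return _classify(read.sequence[:pos], read.qualities[:pos], params)


def _classify(insert: str, qualities: Sequence[int], params: TrimParams) -> TrimOutcome:
    fraction = partition_by_size(len(insert), params)
    if fraction is SizeFraction.NONE:
        return TrimOutcome(TrimStatus.OUT_OF_SIZE)
    return TrimOutcome(
        TrimStatus.KEPT,
        insert=insert,
        insert_qualities=tuple(qualities),
        fraction=fraction,
    )


def process_read(
    read: SmallRNARead, params: TrimParams, order: str = "adapter-first"
) -> TrimOutcome:
    """Apply the full cleanup to one read in the configured stage order."""
    if order == "adapter-first":
        pos = find_adapter(read.sequence, params)
        if pos is None:
            return TrimOutcome(TrimStatus.NO_ADAPTER)
        if pos == 0:
            return TrimOutcome(TrimStatus.OUT_OF_SIZE)
        insert, quals = quality_end_trim(
            read.sequence[:pos], read.qualities[:pos], params.qual_threshold
        )
        if not insert:
            return TrimOutcome(TrimStatus.EMPTY_AFTER_QTRIM)
        return _classify(insert, quals, params)
    if order == "qtrim-first":
        seq, quals = quality_end_trim(
            read.sequence, read.qualities, params.qual_threshold
        )
        if not seq:
            return TrimOutcome(TrimStatus.EMPTY_AFTER_QTRIM)
        pos = find_adapter(seq, params)
        if pos is None:
            return TrimOutcome(TrimStatus.NO_ADAPTER)
        if pos == 0:
            return TrimOutcome(TrimStatus.OUT_OF_SIZE)
        return _classify(seq[:pos], quals[:pos], params)
    raise ValueError(f"unknown order {order!r}")


# ---------------------------------------------------------------------------
# vectorized library processing
# ---------------------------------------------------------------------------


def _encode_chunk(
    sequences: list[str], qualities: list[Sequence[int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(sequences)
    lengths = np.fromiter((len(s) for s in sequences), dtype=np.int64, count=n)
    width = int(lengths.max()) if n else 0
    seq_mat = np.zeros((n, width), dtype=np.uint8)
    qual_mat = np.zeros((n, width), dtype=np.int64)
    for i, (s, q) in enumerate(zip(sequences, qualities)):
        seq_mat[i, : len(s)] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        qual_mat[i, : len(q)] = q
    return seq_mat, qual_mat, lengths


def _scan_adapter_batch(
    seq_mat: np.ndarray, lengths: np.ndarray, params: TrimParams
) -> np.ndarray:
    """Leftmost adapter position per row, -1 when not detected."""
    n, width = seq_mat.shape
    adapter = np.frombuffer(params.adapter.encode("ascii"), dtype=np.uint8)
    alen = adapter.size
    found = np.full(n, -1, dtype=np.int64)
    for i in range(0, width - params.min_overlap + 1):
        if (found >= 0).all():
            break
        w = min(alen, width - i)
        block = seq_mat[:, i : i + w]
        mism = (block != adapter[:w]) | (block == _N)
        mm_cum = np.cumsum(mism, axis=1)
        overlap = np.minimum(alen, lengths - i)
        candidate = (found < 0) & (overlap >= params.min_overlap)
        if not candidate.any():
            continue
        idx = np.clip(overlap, 1, w) - 1
        mm = mm_cum[np.arange(n), idx]
        allowed = np.floor(params.max_mismatch_rate * overlap).astype(np.int64)
        hit = candidate & (mm <= allowed)
        found[hit] = i
    return found


def _qtrim_batch(
    qual_mat: np.ndarray, limits: np.ndarray, threshold: float
) -> np.ndarray:
    """Per-row longest prefix length (capped at ``limits``) with mean > threshold."""
    n, width = qual_mat.shape
    if width == 0:
        return np.zeros(n, dtype=np.int64)
    csum = np.cumsum(qual_mat, axis=1)
    positions = np.arange(1, width + 1)
    valid = csum > threshold * positions
    valid &= np.arange(width) < limits[:, None]
    any_valid = valid.any(axis=1)
    last_true = width - np.argmax(valid[:, ::-1], axis=1)
    return np.where(any_valid, last_true, 0).astype(np.int64)


def _process_chunk(
    sequences: list[str],
    qualities: list[Sequence[int]],
    params: TrimParams,
    order: str,
) -> tuple[list[str], AttritionStats]:
    seq_mat, qual_mat, lengths = _encode_chunk(sequences, qualities)
    n = len(sequences)

    if order == "adapter-first":
        pos = _scan_adapter_batch(seq_mat, lengths, params)
        insert_len = np.where(pos > 0, pos, 0)
        trimmed = _qtrim_batch(qual_mat, insert_len, params.qual_threshold)
        no_adapter = pos < 0
        adapter_at_zero = pos == 0
        empty_after = (pos > 0) & (trimmed == 0)
        final_len = trimmed
    elif order == "qtrim-first":
        trimmed_full = _qtrim_batch(qual_mat, lengths, params.qual_threshold)
        empty_after = trimmed_full == 0
        pos = _scan_adapter_batch(seq_mat, trimmed_full, params)
        no_adapter = (~empty_after) & (pos < 0)
        adapter_at_zero = (~empty_after) & (pos == 0)
        final_len = np.where(pos > 0, pos, 0)
    else:
        raise ValueError(f"unknown order {order!r}")

    mir = (
        (final_len >= params.insert_min)
        & (final_len <= params.insert_max)
        & ~(no_adapter | adapter_at_zero | empty_after)
    )
    long_frac = (
        (final_len > params.insert_max)
        & (final_len <= params.long_max)
        & ~(no_adapter | adapter_at_zero | empty_after)
    )
    kept = mir | long_frac
    out_of_size = ~(no_adapter | empty_after | kept)

    stats = AttritionStats()
    stats.total = n
    stats.by_status[TrimStatus.NO_ADAPTER.value] = int(no_adapter.sum())
    stats.by_status[TrimStatus.EMPTY_AFTER_QTRIM.value] = int(empty_after.sum())
    stats.by_status[TrimStatus.OUT_OF_SIZE.value] = int(out_of_size.sum())
    stats.by_status[TrimStatus.KEPT.value] = int(kept.sum())
    stats.by_fraction[SizeFraction.MIR_PIRNA_18_40.value] = int(mir.sum())
    stats.by_fraction[SizeFraction.LONG_40_150.value] = int(long_frac.sum())
    stats.by_fraction[SizeFraction.NONE.value] = n - int(kept.sum())

    inserts = [sequences[i][: final_len[i]] for i in np.flatnonzero(mir)]
    return inserts, stats


def process_library(
    reads: Iterable[SmallRNARead],
    params: TrimParams,
    *,
    order: str = "adapter-first",
    chunk_size: int = 65536,
) -> tuple[list[str], AttritionStats]:
    """Clean a whole library; returns miR-fraction inserts plus attrition.

    Every input read is counted exactly once in the attrition statuses.
    Long-fraction (41-150 nt) reads are counted (KEPT / LONG_40_150) but
    not returned for quantification.
    """
    inserts: list[str] = []
    stats = AttritionStats()
    seq_buf: list[str] = []
    qual_buf: list[Sequence[int]] = []
    for read in reads:
        seq_buf.append(read.sequence)
        qual_buf.append(read.qualities)
        if len(seq_buf) >= chunk_size:
            chunk_inserts, chunk_stats = _process_chunk(seq_buf, qual_buf, params, order)
            inserts.extend(chunk_inserts)
            stats.merge(chunk_stats)
            seq_buf, qual_buf = [], []
    if seq_buf:
        chunk_inserts, chunk_stats = _process_chunk(seq_buf, qual_buf, params, order)
        inserts.extend(chunk_inserts)
        stats.merge(chunk_stats)
    return inserts, stats
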
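"""Readers and writers for the formats the pipeline touches.

FASTQ (Phred+33, optionally gzipped), mature-miR FASTA (miRBase mature
dialect, RNA or DNA alphabet), sample manifests and count matrices as
TSV, and JSON run summaries.  All readers validate strictly and fail
with an error naming the offending record.
"""

from __future__ import annotations

import gzip
import json
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 60
READ_ALPHABET = frozenset("ACGTN")
FASTA_ALPHABET = frozenset("ACGTUN")

_ARM_RE = re.compile(r"^(?P<base>.*?)[-_](?P<arm>[35]p)$")


class FastqFormatError(ValueError):
    """Malformed FASTQ record."""


class FastaFormatError(ValueError):
    """Malformed mature-miR FASTA entry."""


class ManifestError(ValueError):
    """Invalid sample manifest."""


class CountsFormatError(ValueError):
    """Invalid counts TSV."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SmallRNARead:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if not READ_ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - READ_ALPHABET)
            raise ValueError(f"read {self.read_id!r}: non-{{A,C,G,T,N}} characters {bad}")
        if self.qualities and not (
            0 <= min(self.qualities) and max(self.qualities) <= MAX_PHRED
        ):
            raise ValueError(
                f"read {self.read_id!r}: Phred score outside [0, {MAX_PHRED}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MatureMiR:
    """A mature microRNA reference entry (sequence stored as DNA)."""

    name: str
    sequence: str
    gene_ids: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - (READ_ALPHABET)
        if bad:
            raise FastaFormatError(
                f"{self.name}: non-DNA characters {sorted(bad)} after U->T conversion"
            )
        if not (15 <= len(self.sequence) <= 30):
            raise FastaFormatError(
                f"{self.name}: mature length {len(self.sequence)} outside [15, 30]"
            )

    @property
    def arm(self) -> Optional[str]:
        """'3p'/'5p' suffix of the name, if present."""
        m = _ARM_RE.match(self.name)
        return m.group("arm") if m else None


@dataclass
class SampleManifest:
    """Ordered sample_id -> (fastq_path, group_label) mapping."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sample_id, _path, group in self.entries:
            if sample_id in seen:
                raise ManifestError(f"duplicate sample_id {sample_id!r}")
            if not group:
                raise ManifestError(f"sample {sample_id!r}: empty group label")
            seen.add(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return {s: g for s, _, g in self.entries}

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for _, _, g in self.entries:
            if g not in seen:
                seen.append(g)
        return seen

    def fastq_path(self, sample_id: str) -> str:
        for s, p, _ in self.entries:
            if s == sample_id:
                return p
        raise KeyError(sample_id)

    def group_members(self, group: str) -> list[str]:
        members = [s for s, _, g in self.entries if g == group]
        if not members:
            raise ManifestError(f"unknown group {group!r}")
        return members


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    # gzip handled transparently by extension sniffing
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(
    path: str | os.PathLike, *, phred_offset: int = PHRED_OFFSET
) -> Iterator[SmallRNARead]:
    """Stream reads from a 4-line FASTQ file (Phred+33 unless overridden).

    Raises :class:`FastqFormatError` naming the (0-based) record index on
    any malformed record.
    """
    with _open_text(path) as fh:
        iterator = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"record {index}: {exc}") from exc
            qualities = [ord(c) - phred_offset for c in qual]
            try:
                yield SmallRNARead(title.split()[0] if title else "", seq.upper(), qualities)
            except ValueError as exc:
                raise FastqFormatError(f"record {index}: {exc}") from exc
            index += 1


def write_fastq(
    reads: Iterable[SmallRNARead],
    path: str | os.PathLike,
    *,
    phred_offset: int = PHRED_OFFSET,
) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# mature-miR FASTA
# ---------------------------------------------------------------------------


def read_mature_fasta(path: str | os.PathLike) -> list[MatureMiR]:
    """Parse a mature-miR FASTA file.

    The miR name is the first whitespace-delimited header token; remaining
    tokens are stored as the description.  Sequences are uppercased with
    U->T conversion.  Duplicate names are rejected; duplicate sequences are
    allowed (collapsed downstream).
    """
    entries: list[MatureMiR] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            name = record.id
            raw = str(record.seq).upper()
            if not raw:
                raise FastaFormatError(f"{name}: entry has no sequence")
            bad = set(raw) - FASTA_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"{name}: non-{{A,C,G,U,T,N}} characters {sorted(bad)}"
                )
            if name in seen:
                raise FastaFormatError(f"duplicate entry name {name!r}")
            seen.add(name)
            description = record.description[len(record.id):].strip()
            entries.append(
                MatureMiR(name=name, sequence=raw.replace("U", "T"), description=description)
            )
    return entries


def write_mature_fasta(entries: Iterable[MatureMiR], path: str | os.PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for e in entries:
            header = f">{e.name}" + (f" {e.description}" if e.description else "")
            fh.write(f"{header}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# manifest TSV
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("sample_id", "fastq", "group")


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a TSV manifest with columns sample_id, fastq, group."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ManifestError(f"{path}: empty manifest")
    header = tuple(lines[0].split("\t"))
    if header != _MANIFEST_COLUMNS:
        raise ManifestError(
            f"{path}: expected header {list(_MANIFEST_COLUMNS)}, got {list(header)}"
        )
    entries = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ManifestError(f"{path}:{i}: expected 3 tab-separated fields")
        entries.append((fields[0], fields[1], fields[2]))
    return SampleManifest(entries=entries)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for sample_id, fastq, group in manifest.entries:
            fh.write(f"{sample_id}\t{fastq}\t{group}\n")


# ---------------------------------------------------------------------------
# counts TSV round-trip
# ---------------------------------------------------------------------------


def write_counts(matrix, path: str | os.PathLike) -> None:
    """Write a CountMatrix (or CPMMatrix) as a TSV with feature IDs first."""
    import numpy as np

    values = matrix.values_array()
    integral = np.issubdtype(values.dtype, np.integer)
    fmt = (lambda v: str(int(v))) if integral else (lambda v: repr(float(v)))
    with _open_text(path, "wt") as fh:
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        for name, row in zip(matrix.feature_names, values):
            fh.write(name + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def read_counts(path: str | os.PathLike, groups: Optional[dict[str, str]] = None):
    """Read a counts TSV back into a CountMatrix.

    Counts must be non-negative integers; anything else is a hard error.
    ``write_counts`` then ``read_counts`` is an identity on integer
    matrices (column order preserved).
    """
    # deferred import: mir_quantification owns the matrix types and imports
    # this module at top level
    from .mir_quantification import CountMatrix
    import numpy as np

    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CountsFormatError(f"{path}: empty counts file")
    header = lines[0].split("\t")
    if header[0] != "feature":
        raise CountsFormatError(f"{path}: first header column must be 'feature'")
    sample_ids = header[1:]
    feature_names: list[str] = []
    rows: list[list[int]] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise CountsFormatError(f"{path}:{i}: ragged row")
        feature_names.append(fields[0])
        row = []
        for cell in fields[1:]:
            try:
                value = int(cell)
            except ValueError as exc:
                raise CountsFormatError(
                    f"{path}:{i}: non-integer count {cell!r}"
                ) from exc
            if value < 0:
                raise CountsFormatError(f"{path}:{i}: negative count {value}")
            row.append(value)
        rows.append(row)
    counts = np.asarray(rows, dtype=np.int64).reshape(len(feature_names), len(sample_ids))
    return CountMatrix(
        feature_names=feature_names,
        sample_ids=sample_ids,
        counts=counts,
        groups=dict(groups) if groups else {s: s for s in sample_ids},
    )


# ---------------------------------------------------------------------------
# JSON summaries / atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write-then-rename so a partial failure leaves no truncated output."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_json(obj, path: str | os.PathLike) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)
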
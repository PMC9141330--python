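"""Exact-sequence clustering, mature-miR assignment, count and CPM matrices.

Identical inserts are clustered; mature reference entries with
byte-identical sequences are merged into one feature (named e.g.
``mir-19b-1//mir-19b-2_3p``); clusters are assigned to features either by
exact sequence equality (default) or with a bounded 3' length tolerance
for isomiRs.  CPM uses the miR-assigned read total of each sample as the
denominator, so CPM / 10^4 is the percent of total miR content.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import MatureMiR, SampleManifest

_ARM_RE = re.compile(r"^(?P<base>.*?)[-_](?P<arm>[35]p)$")

UNASSIGNED = None  # sentinel: assignment result for clusters matching no feature


# ---------------------------------------------------------------------------
# reference collapsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollapsedFeature:
    merged_name: str
    sequence: str
    member_names: tuple[str, ...]
    gene_ids: tuple[str, ...] = ()


@dataclass
class CollapsedReference:
    """Mature sequences with identical-sequence loci merged into one feature."""

    entries: list[CollapsedFeature]

    def __post_init__(self) -> None:
        sequences = [e.sequence for e in self.entries]
        if len(set(sequences)) != len(sequences):
            raise ValueError("collapsed reference has duplicate sequences")
        self.by_sequence: dict[str, CollapsedFeature] = {
            e.sequence: e for e in self.entries
        }

    @property
    def feature_names(self) -> list[str]:
        return [e.merged_name for e in self.entries]


def merged_feature_name(member_names: Sequence[str]) -> str:
    """Deterministic feature name for a set of sequence-identical loci.

    Members are ordered lexicographically; when all share one arm suffix
    (``-3p``/``_3p``/``-5p``/``_5p``) it is stripped and re-appended once
    in underscore form: ``mir-19b-1-3p`` + ``mir-19b-2-3p`` ->
    ``mir-19b-1//mir-19b-2_3p``.
    """
    names = sorted(member_names)
    if len(names) == 1:
        return names[0]
    matches = [_ARM_RE.match(n) for n in names]
    if all(matches) and len({m.group("arm") for m in matches}) == 1:
        return "//".join(m.group("base") for m in matches) + "_" + matches[0].group("arm")
    return "//".join(names)


def collapse_reference(entries: Sequence[MatureMiR]) -> CollapsedReference:
    """Merge reference entries with byte-identical mature sequences."""
    groups: dict[str, list[MatureMiR]] = {}
    for entry in entries:
        groups.setdefault(entry.sequence, []).append(entry)
    features = []
    for sequence, members in groups.items():
        members = sorted(members, key=lambda m: m.name)
        gene_ids: list[str] = []
        for m in members:
            for g in m.gene_ids:
                if g not in gene_ids:
                    gene_ids.append(g)
        features.append(
            CollapsedFeature(
                merged_name=merged_feature_name([m.name for m in members]),
                sequence=sequence,
                member_names=tuple(m.name for m in members),
                gene_ids=tuple(gene_ids),
            )
        )
    features.sort(key=lambda f: f.merged_name)
    return CollapsedReference(entries=features)


# ---------------------------------------------------------------------------
# clustering and assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceCluster:
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")


def cluster_reads(inserts: Iterable[str]) -> list[SequenceCluster]:
    """Exact multiset tally of identical insert sequences (sorted by sequence)."""
    tally = Counter(inserts)
    return [SequenceCluster(seq, n) for seq, n in sorted(tally.items())]


@dataclass(frozen=True)
class MatchPolicy:
    """Cluster-to-reference matching policy.

    ``exact``: byte equality only.  ``tol3p``: additionally match reads
    missing up to ``tol`` 3' bases of a mature, or carrying up to ``tol``
    extra 3' bases beyond a mature; zero internal mismatches.  Ambiguity
    is broken deterministically: exact-length match, then longest matched
    mature, then lexicographically smallest feature name.
    """

    kind: str = "exact"
    tol: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "tol3p"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


class _Matcher:
    """Reference indexes for fast repeated cluster assignment."""

    def __init__(self, ref: CollapsedReference, policy: MatchPolicy):
        self.ref = ref
        self.policy = policy
        if policy.kind == "tol3p" and policy.tol > 0:
            # read-shorter case: mature truncated by 1..tol 3' bases -> feature
            self.trunc_index: dict[str, list[CollapsedFeature]] = {}
            for entry in ref.entries:
                for d in range(1, policy.tol + 1):
                    if len(entry.sequence) - d >= 1:
                        self.trunc_index.setdefault(entry.sequence[:-d], []).append(entry)
        else:
            self.trunc_index = {}

    def assign(self, sequence: str) -> Optional[str]:
        exact = self.ref.by_sequence.get(sequence)
        if exact is not None:
            return exact.merged_name
        if self.policy.kind == "exact":
            return UNASSIGNED
        candidates: list[CollapsedFeature] = []
        candidates.extend(self.trunc_index.get(sequence, ()))
        for d in range(1, self.policy.tol + 1):
            if len(sequence) - d < 1:
                break
            entry = self.ref.by_sequence.get(sequence[:-d])
            if entry is not None:
                candidates.append(entry)
        if not candidates:
            return UNASSIGNED
        best = min(candidates, key=lambda e: (-len(e.sequence), e.merged_name))
        return best.merged_name


def assign_cluster(
    cluster: SequenceCluster, ref: CollapsedReference, policy: MatchPolicy
) -> Optional[str]:
    """Assign one cluster to a feature name, or UNASSIGNED (None)."""
    return _Matcher(ref, policy).assign(cluster.sequence)


def assign_clusters(
    clusters: Sequence[SequenceCluster],
    ref: CollapsedReference,
    policy: MatchPolicy,
) -> tuple[Counter, int]:
    """Assign many clusters; returns (feature -> read count, unassigned reads)."""
    matcher = _Matcher(ref, policy)
    counts: Counter = Counter()
    unassigned = 0
    for cluster in clusters:
        feature = matcher.assign(cluster.sequence)
        if feature is UNASSIGNED:
            unassigned += cluster.count
        else:
            counts[feature] += cluster.count
    return counts, unassigned


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample group labels."""

    feature_names: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_names), len(self.sample_ids)):
            raise ValueError("count matrix shape inconsistent with labels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing group labels: {missing}")

    def values_array(self) -> np.ndarray:
        return self.counts

    def group_columns(self, group: str) -> list[int]:
        cols = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not cols:
            raise KeyError(f"unknown group {group!r}")
        return cols

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class CPMMatrix:
    """Counts-per-million; each sample column with assigned reads sums to 1e6."""

    feature_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_names), len(self.sample_ids)):
            raise ValueError("CPM matrix shape inconsistent with labels")
        if (self.values < 0).any():
            raise ValueError("CPM values must be non-negative")

    def values_array(self) -> np.ndarray:
        return self.values

    def group_columns(self, group: str) -> list[int]:
        cols = [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]
        if not cols:
            raise KeyError(f"unknown group {group!r}")
        return cols

    def group_mean(self, group: str) -> np.ndarray:
        return self.values[:, self.group_columns(group)].mean(axis=1)


def build_count_matrix(
    per_sample_counts: dict[str, Counter],
    manifest: SampleManifest,
    ref: CollapsedReference,
) -> CountMatrix:
    """Assemble assigned counts into a feature x sample matrix.

    Features with zero reads everywhere are retained as all-zero rows;
    unassigned reads are never a matrix row (they are tallied in the run
    summary).  A sample present in the assignments but absent from the
    manifest is a hard error.
    """
    unknown = set(per_sample_counts) - set(manifest.sample_ids)
    if unknown:
        raise ValueError(f"samples not in manifest: {sorted(unknown)}")
    feature_names = ref.feature_names
    sample_ids = list(manifest.sample_ids)
    counts = np.zeros((len(feature_names), len(sample_ids)), dtype=np.int64)
    index = {name: i for i, name in enumerate(feature_names)}
    for j, sample in enumerate(sample_ids):
        for feature, n in per_sample_counts.get(sample, {}).items():
            counts[index[feature], j] = n
    return CountMatrix(
        feature_names=feature_names,
        sample_ids=sample_ids,
        counts=counts,
        groups=dict(manifest.groups),
    )


def cpm(matrix: CountMatrix) -> CPMMatrix:
    """Normalize each sample to counts per million assigned reads.

    Samples with zero assigned reads are left as all-zero columns with a
    warning rather than dividing by zero.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero) if z]
        warnings.warn(f"samples with zero assigned reads left as zeros: {bad}")
    safe = np.where(zero, 1.0, totals)
    values = matrix.counts / safe * 1e6
    values[:, zero] = 0.0
    return CPMMatrix(
        feature_names=list(matrix.feature_names),
        sample_ids=list(matrix.sample_ids),
        values=values,
        groups=dict(matrix.groups),
    )
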
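"""Profile summaries, Venn overlaps, and the end-to-end pipeline driver.

Detection uses group-mean CPM >= 1; high abundance uses group-mean
CPM >= 1000; ranked composition tables report each feature's percent of
total miR content (CPM / 10^4) with cumulative shares.  Percents are
rounded half-up to one decimal for display only; all set operations and
cumulative sums use unrounded values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

import yaml

from . import io_formats
from .differential_enrichment import TestConfig, results_table, run_enrichment
from .io_formats import atomic_write_text, read_manifest, read_mature_fasta
from .mir_quantification import (
    CPMMatrix,
    MatchPolicy,
    assign_clusters,
    build_count_matrix,
    cluster_reads,
    collapse_reference,
    cpm,
)
from .read_processing import TrimParams, process_library

logger = logging.getLogger(__name__)

DETECT_CPM = 1.0
ABUNDANT_CPM = 1000.0
MAX_VENN_SETS = 4
OTHER_LABEL = "Other miRNAs"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for display columns."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# composition / detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionRow:
    rank: int
    feature: str
    mean_cpm: float
    percent: float  # unrounded, = mean_cpm / 1e4
    cumulative_percent: float  # unrounded


@dataclass
class ProfileSummary:
    """Detected/abundant sets and ranked composition for one group."""

    group: str
    detected: set[str]
    abundant: set[str]
    composition: list[CompositionRow]
    top_n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.abundant <= self.detected:
            raise ValueError("abundant set must be a subset of detected set")

    def top_rows(self) -> list[CompositionRow]:
        if self.top_n is None:
            return self.composition
        return self.composition[: self.top_n]

    def other_percent(self) -> Optional[float]:
        """Unrounded remainder share beyond ``top_n`` rows."""
        rows = self.top_rows()
        if self.top_n is None or not rows:
            return None
        return 100.0 - rows[-1].cumulative_percent

    def to_dict(self) -> dict:
        rows = [
            {
                "rank": r.rank,
                "feature": r.feature,
                "mean_cpm": r.mean_cpm,
                "percent": round_half_up(r.percent, 1),
                "cumulative_percent": round_half_up(r.cumulative_percent, 1),
            }
            for r in self.top_rows()
        ]
        other = self.other_percent()
        if other is not None:
            rows.append({"feature": OTHER_LABEL, "percent": round_half_up(other, 1)})
        return {
            "group": self.group,
            "n_detected": len(self.detected),
            "n_abundant": len(self.abundant),
            "detected": sorted(self.detected),
            "abundant": sorted(self.abundant),
            "composition": rows,
        }


def detect(cpm_matrix: CPMMatrix, group: str, threshold: float = DETECT_CPM) -> set[str]:
    """Features whose mean CPM across the group's samples is >= threshold."""
    means = cpm_matrix.group_mean(group)  # raises KeyError on unknown group
    return {
        name for name, value in zip(cpm_matrix.feature_names, means) if value >= threshold
    }


def rank_abundance(rows: Iterable[tuple[str, float]]) -> list[CompositionRow]:
    """Rank (feature, mean CPM) pairs by descending CPM, ties lexicographic.

    percent = CPM / 10^4 (the share of total miR content when columns are
    CPM-normalized); cumulative sums use unrounded percents.
    """
    ordered = sorted(rows, key=lambda kv: (-kv[1], kv[0]))
    out: list[CompositionRow] = []
    cumulative = 0.0
    for rank, (name, value) in enumerate(ordered, start=1):
        percent = value / 1e4
        cumulative += percent
        out.append(CompositionRow(rank, name, value, percent, cumulative))
    return out


def composition(
    cpm_matrix: CPMMatrix, group: str, top_n: Optional[int] = None
) -> ProfileSummary:
    """Ranked composition plus detected / abundant sets for one group."""
    means = cpm_matrix.group_mean(group)
    rows = rank_abundance(zip(cpm_matrix.feature_names, means))
    return ProfileSummary(
        group=group,
        detected=detect(cpm_matrix, group, DETECT_CPM),
        abundant=detect(cpm_matrix, group, ABUNDANT_CPM),
        composition=rows,
        top_n=top_n,
    )


# ---------------------------------------------------------------------------
# Venn overlap
# ---------------------------------------------------------------------------


@dataclass
class VennCounts:
    """Exact region counts over the membership-pattern partition of <= 4 sets."""

    set_names: list[str]
    region_counts: dict[frozenset, int]
    pairwise_shared: dict[tuple[str, str], int]

    def region(self, *names: str) -> int:
        return self.region_counts.get(frozenset(names), 0)

    def to_dict(self) -> dict:
        return {
            "sets": list(self.set_names),
            "regions": {
                "&".join(sorted(k)): v for k, v in sorted(
                    self.region_counts.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "pairwise_shared": {
                f"{a}&{b}": v for (a, b), v in sorted(self.pairwise_shared.items())
            },
        }


def venn(sets: dict[str, set]) -> VennCounts:
    """Partition the union of 2-4 named sets into exclusive membership regions."""
    if not (2 <= len(sets) <= MAX_VENN_SETS):
        raise ValueError(f"venn supports 2..{MAX_VENN_SETS} sets, got {len(sets)}")
    names = list(sets)
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for element in union:
        pattern = frozenset(n for n in names if element in sets[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(sorted(names), 2)
    }
    return VennCounts(set_names=names, region_counts=regions, pairwise_shared=pairwise)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


DEFAULT_CONFIG: dict = {
    "manifest": None,
    "reference": None,
    "trim": {},  # TrimParams fields
    "order": "adapter-first",
    "match_policy": {"kind": "exact", "tol": 2},
    "de": {"pairs": [], "config": {}},  # pairs: [[group_a, group_b], ...]
    "report": {"top_n": 10},
}


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | os.PathLike) -> dict[str, str]:
    """Run trim -> quantify -> normalize -> DE -> report, atomically.

    Deterministic given the config and inputs; every output carries the
    config hash.  Returns a mapping of output names to paths.
    """
    for key in ("manifest", "reference"):
        if not config.get(key):
            raise ValueError(f"config missing required key {key!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config_hash(config)

    manifest = read_manifest(config["manifest"])
    matures = read_mature_fasta(config["reference"])
    reference = collapse_reference(matures)
    params = TrimParams(**config.get("trim", {}))
    order = config.get("order", "adapter-first")
    policy = MatchPolicy(**config.get("match_policy", {}))

    per_sample_counts = {}
    attrition = {}
    unassigned = {}
    for sample_id, fastq, _group in manifest.entries:
        reads = io_formats.read_fastq(fastq)
        inserts, stats = process_library(reads, params, order=order)
        clusters = cluster_reads(inserts)
        counts, n_unassigned = assign_clusters(clusters, reference, policy)
        per_sample_counts[sample_id] = counts
        attrition[sample_id] = stats.as_dict()
        unassigned[sample_id] = n_unassigned
        logger.info(
            "sample %s: %d reads, %d miR-assigned, %d unassigned",
            sample_id, stats.total, sum(counts.values()), n_unassigned,
        )

    matrix = build_count_matrix(per_sample_counts, manifest, reference)
    cpm_matrix = cpm(matrix)

    paths: dict[str, str] = {}

    counts_path = out / "counts.tsv"
    io_formats.write_counts(matrix, counts_path)
    paths["counts"] = str(counts_path)
    cpm_path = out / "cpm.tsv"
    io_formats.write_counts(cpm_matrix, cpm_path)
    paths["cpm"] = str(cpm_path)

    top_n = config.get("report", {}).get("top_n", 10)
    profiles = {
        group: composition(cpm_matrix, group, top_n=top_n)
        for group in manifest.group_labels
    }
    groups_for_venn = manifest.group_labels[:MAX_VENN_SETS]
    venn_counts = (
        venn({g: profiles[g].detected for g in groups_for_venn})
        if len(groups_for_venn) >= 2
        else None
    )

    de_outputs = {}
    de_cfg = TestConfig(**config.get("de", {}).get("config", {}))
    for pair in config.get("de", {}).get("pairs", []):
        group_a, group_b = pair
        results, est = run_enrichment(matrix, group_a, group_b, de_cfg)
        frame = results_table(results)
        de_path = out / f"de_{group_a}_vs_{group_b}.tsv"
        atomic_write_text(de_path, frame.to_csv(sep="\t", index=False))
        paths[f"de_{group_a}_vs_{group_b}"] = str(de_path)
        de_outputs[f"{group_a}_vs_{group_b}"] = {
            "dispersion": est.phi,
            "n_enriched": sum(r.classification == "ENRICHED" for r in results),
            "n_depleted": sum(r.classification == "DEPLETED" for r in results),
        }

    summary = {
        "config_hash": stamp,
        "match_policy": {"kind": policy.kind, "tol": policy.tol},
        "order": order,
        "attrition": attrition,
        "unassigned_reads": unassigned,
        "profiles": {g: p.to_dict() for g, p in profiles.items()},
        "venn": venn_counts.to_dict() if venn_counts else None,
        "differential": de_outputs,
    }
    summary_path = out / "summary.json"
    io_formats.write_json(summary, summary_path)
    paths["summary"] = str(summary_path)
    attrition_path = out / "attrition.json"
    io_formats.write_json({"config_hash": stamp, "attrition": attrition}, attrition_path)
    paths["attrition"] = str(attrition_path)
    return paths
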
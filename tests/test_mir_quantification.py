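from collections import Counter

import numpy as np
import pytest

from mirtally.io_formats import MatureMiR
from mirtally.mir_quantification import (
    CountMatrix,
    MatchPolicy,
    SequenceCluster,
    assign_cluster,
    assign_clusters,
    build_count_matrix,
    cluster_reads,
    collapse_reference,
    cpm,
    merged_feature_name,
)
from conftest import random_seq


# ---------------------------------------------------------------------------
# reference collapsing
# ---------------------------------------------------------------------------


class TestCollapseReference:
    def test_identical_loci_merge_with_shared_arm(self):
        seq = "TGTGCAAATCCATGCAAAACTGA"
        ref = collapse_reference(
            [
                MatureMiR(name="mir-19b-1-3p", sequence=seq),
                MatureMiR(name="mir-19b-2-3p", sequence=seq),
            ]
        )
        assert len(ref.entries) == 1
        assert ref.entries[0].merged_name == "mir-19b-1//mir-19b-2_3p"
        assert ref.entries[0].member_names == ("mir-19b-1-3p", "mir-19b-2-3p")

    def test_distinct_sequences_identity_mapping(self, small_reference):
        distinct = small_reference[:2]
        ref = collapse_reference(distinct)
        assert sorted(ref.feature_names) == sorted(e.name for e in distinct)

    def test_mixed_arms_join_full_names(self):
        seq = "TGTGCAAATCCATGCAAAACTGA"
        ref = collapse_reference(
            [
                MatureMiR(name="mir-x-3p", sequence=seq),
                MatureMiR(name="mir-y-5p", sequence=seq),
            ]
        )
        assert ref.entries[0].merged_name == "mir-x-3p//mir-y-5p"

    def test_underscore_arm_spelling_accepted(self):
        assert merged_feature_name(["mir-a_3p", "mir-b-3p"]) == "mir-a//mir-b_3p"

    def test_three_loci_one_sequence_and_brute_force_grouping(self, rng):
        # random reference with engineered collisions
        pool = [random_seq(rng, 22) for _ in range(20)]
        entries = []
        for i in range(60):
            seq = pool[int(rng.integers(0, len(pool)))]
            entries.append(MatureMiR(name=f"mir-{i:03d}-3p", sequence=seq))
        ref = collapse_reference(entries)
        # O(n^2) hash-free grouping oracle
        groups = []
        for entry in entries:
            for group in groups:
                if group[0].sequence == entry.sequence:
                    group.append(entry)
                    break
            else:
                groups.append([entry])
        assert len(ref.entries) == len(groups)
        by_seq = {g[0].sequence: sorted(m.name for m in g) for g in groups}
        for feature in ref.entries:
            assert list(feature.member_names) == by_seq[feature.sequence]

    def test_gene_ids_union_in_member_order(self):
        seq = "TGTGCAAATCCATGCAAAACTGA"
        ref = collapse_reference(
            [
                MatureMiR(name="mir-a-3p", sequence=seq, gene_ids=("1", "2")),
                MatureMiR(name="mir-b-3p", sequence=seq, gene_ids=("2", "3")),
            ]
        )
        assert ref.entries[0].gene_ids == ("1", "2", "3")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class TestClusterReads:
    def test_multiset_tally(self):
        clusters = cluster_reads(["ACGT", "ACGT", "TTTT"])
        assert {(c.sequence, c.count) for c in clusters} == {("ACGT", 2), ("TTTT", 1)}

    def test_empty_stream(self):
        assert cluster_reads([]) == []

    def test_count_conservation_vs_sort_and_scan_oracle(self, rng):
        inserts = [random_seq(rng, int(rng.integers(18, 26))) for _ in range(10_000)]
        clusters = cluster_reads(inserts)
        assert sum(c.count for c in clusters) == len(inserts)
        # sort-and-scan oracle
        expected = []
        for seq in sorted(inserts):
            if expected and expected[-1][0] == seq:
                expected[-1][1] += 1
            else:
                expected.append([seq, 1])
        assert [(c.sequence, c.count) for c in clusters] == [tuple(e) for e in expected]


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def oracle_assign(sequence, ref, tol):
    """Brute-force scan of all (feature, 3' trim) combinations with tie-break."""
    candidates = []
    for entry in ref.entries:
        mature = entry.sequence
        if sequence == mature:
            candidates.append((entry, 0))
            continue
        if tol == 0:
            continue
        # read missing <= tol 3' bases of the mature
        if 0 < len(mature) - len(sequence) <= tol and mature.startswith(sequence):
            candidates.append((entry, len(mature) - len(sequence)))
        # read carrying <= tol extra 3' bases beyond the mature
        if 0 < len(sequence) - len(mature) <= tol and sequence.startswith(mature):
            candidates.append((entry, len(sequence) - len(mature)))
    if not candidates:
        return None
    exact = [e for e, d in candidates if d == 0]
    if exact:
        return exact[0].merged_name
    best = min(candidates, key=lambda ed: (-len(ed[0].sequence), ed[0].merged_name))
    return best[0].merged_name


class TestAssignCluster:
    def test_exact_match(self, small_reference):
        ref = collapse_reference(small_reference)
        cluster = SequenceCluster("AAGCTGCCAGTTGAAGAACTGT", 3)
        assert assign_cluster(cluster, ref, MatchPolicy("exact")) == "hsa-miR-22-3p"

    def test_three_prime_tolerance(self, small_reference):
        ref = collapse_reference(small_reference)
        cluster = SequenceCluster("AAGCTGCCAGTTGAAGAACT", 1)  # mature minus 2 nt
        assert assign_cluster(cluster, ref, MatchPolicy("tol3p", tol=2)) == "hsa-miR-22-3p"
        assert assign_cluster(cluster, ref, MatchPolicy("tol3p", tol=0)) is None
        assert assign_cluster(cluster, ref, MatchPolicy("exact")) is None

    def test_extra_three_prime_bases(self, small_reference):
        ref = collapse_reference(small_reference)
        cluster = SequenceCluster("AAGCTGCCAGTTGAAGAACTGTCA", 1)  # mature plus 2 nt
        assert assign_cluster(cluster, ref, MatchPolicy("tol3p", tol=2)) == "hsa-miR-22-3p"

    def test_matches_exhaustive_oracle(self, rng):
        entries = [
            MatureMiR(name=f"mir-{i:03d}-3p", sequence=random_seq(rng, int(rng.integers(18, 26))))
            for i in range(40)
        ]
        ref = collapse_reference(entries)
        policy = MatchPolicy("tol3p", tol=2)
        probes = []
        for entry in ref.entries:  # probe near every mature and at random
            probes.append(entry.sequence)
            probes.append(entry.sequence[:-1])
            probes.append(entry.sequence[:-2])
            probes.append(entry.sequence[:-3])
            probes.append(entry.sequence + "A")
            probes.append(entry.sequence + "AC")
        probes += [random_seq(rng, int(rng.integers(18, 28))) for _ in range(200)]
        for probe in probes:
            cluster = SequenceCluster(probe, 1)
            assert assign_cluster(cluster, ref, policy) == oracle_assign(probe, ref, 2)

    def test_assignment_invariant_under_reference_shuffle(self, rng):
        entries = [
            MatureMiR(name=f"mir-{i:03d}-3p", sequence=random_seq(rng, 22))
            for i in range(30)
        ]
        probes = [e.sequence for e in entries] + [
            e.sequence[:-2] for e in entries
        ] + [random_seq(rng, 22) for _ in range(50)]
        baseline = None
        for _ in range(5):
            shuffled = [entries[i] for i in rng.permutation(len(entries))]
            ref = collapse_reference(shuffled)
            result = [
                assign_cluster(SequenceCluster(p, 1), ref, MatchPolicy("tol3p", tol=2))
                for p in probes
            ]
            if baseline is None:
                baseline = result
            assert result == baseline


# ---------------------------------------------------------------------------
# count matrix / CPM
# ---------------------------------------------------------------------------


class TestCountMatrix:
    def test_single_sample_single_feature(self, small_reference, manifest_1sample):
        ref = collapse_reference(small_reference)
        matrix = build_count_matrix(
            {"s1": Counter({"hsa-miR-22-3p": 5})}, manifest_1sample, ref
        )
        row = matrix.feature_names.index("hsa-miR-22-3p")
        assert matrix.counts[row, 0] == 5

    def test_zero_count_feature_retained(self, small_reference, manifest_1sample):
        ref = collapse_reference(small_reference)
        matrix = build_count_matrix(
            {"s1": Counter({"hsa-miR-22-3p": 5})}, manifest_1sample, ref
        )
        assert matrix.counts.shape[0] == len(ref.entries)
        assert (matrix.counts.sum(axis=1) == 0).sum() == len(ref.entries) - 1

    def test_sample_missing_from_manifest_errors(self, small_reference, manifest_1sample):
        ref = collapse_reference(small_reference)
        with pytest.raises(ValueError, match="not in manifest"):
            build_count_matrix({"ghost": Counter()}, manifest_1sample, ref)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["f"], ["s"], np.array([[-1]]), {"s": "G"})


class TestCPM:
    def test_simple_proportions(self):
        matrix = CountMatrix(
            ["A", "B", "C"], ["s1"], np.array([[50], [30], [20]]), {"s1": "G"}
        )
        values = cpm(matrix).values[:, 0]
        assert values == pytest.approx([500_000, 300_000, 200_000])

    def test_percent_of_total_is_cpm_over_1e4(self):
        # a feature at CPM 164,087 is 16.4% of total miR content
        from mirtally.profiling_reports import round_half_up

        assert round_half_up(164_087 / 1e4, 1) == 16.4

    def test_column_sums_on_random_matrices(self, rng):
        counts = rng.integers(0, 1000, size=(50, 6))
        counts[0] += 1  # guarantee nonzero columns
        matrix = CountMatrix(
            [f"f{i}" for i in range(50)],
            [f"s{j}" for j in range(6)],
            counts.astype(np.int64),
            {f"s{j}": "G" for j in range(6)},
        )
        sums = cpm(matrix).values.sum(axis=0)
        assert sums == pytest.approx([1e6] * 6, rel=1e-9)

    def test_zero_sample_warns_and_zeroes(self):
        matrix = CountMatrix(
            ["A"], ["s1", "s2"], np.array([[5, 0]]), {"s1": "G", "s2": "G"}
        )
        with pytest.warns(UserWarning, match="zero assigned"):
            values = cpm(matrix).values
        assert values[0, 1] == 0.0
        assert values[0, 0] == pytest.approx(1e6)


class TestEndToEndRecovery:
    def test_contaminant_free_library_recovers_truth_exactly(self):
        from mirtally.read_processing import TrimParams, process_library
        from mirtally.synthetic_data import SimulationSpec, generate_library, simulate_study

        spec = SimulationSpec(n_mirs=40, depth=3000, seed=3, n_duplicate_matures=3)
        study = simulate_study(spec)
        sequences = [e.sequence for e in study.reference.entries]
        trim_params = TrimParams(adapter=spec.adapter)
        per_sample = {}
        for j, sample_id in enumerate(spec.sample_ids):
            reads, _ledger = generate_library(
                spec, sample_id, study.truth.counts.counts[:, j], sequences
            )
            inserts, _stats = process_library(reads, trim_params)
            counts, unassigned = assign_clusters(
                cluster_reads(inserts), study.reference, MatchPolicy("exact")
            )
            assert unassigned == 0
            per_sample[sample_id] = counts
        matrix = build_count_matrix(per_sample, study.manifest, study.reference)
        assert matrix.feature_names == study.truth.counts.feature_names
        assert np.array_equal(matrix.counts, study.truth.counts.counts)
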
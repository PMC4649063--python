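"""Pairwise identity, greedy clustering, and species-specific SSP detection."""

import numpy as np
import pytest

from secretominer import clustering
from secretominer.clustering import (
    filter_clusters,
    global_identity,
    greedy_cluster,
    species_specific_ssps,
)
from secretominer.models import ProteinRecord
from secretominer.simulate import ancestor_identity_for_pairwise, plant_ssp_family

from .conftest import random_protein
from .oracles import optimal_alignment_stats


class TestGlobalIdentity:
    def test_identical_sequences(self):
        seq = "MKVLAT" * 17  # 102 residues
        result = global_identity(seq, seq)
        assert result.identity == 1.0
        assert result.aligned_matches == len(seq)
        assert result.denominator == len(seq)

    def test_unrelated_homopolymers(self):
        assert global_identity("AAAA", "TTTT").identity == 0.0

    def test_single_gap_still_full_identity_over_shorter(self):
        result = global_identity("MKKLLAV", "MKKLAV")
        assert result.aligned_matches == 6
        assert result.denominator == 6
        assert result.identity == 1.0

    @pytest.mark.parametrize(
        "a,b",
        [("MKKLLAV", "MKKLAV"), ("ACDEF", "ACEF"), ("WWWWK", "WWWK"), ("MKVA", "MKVA")],
    )
    def test_matches_exhaustive_oracle_on_tiny_pairs(self, a, b):
        """Score-optimal alignment found by exhaustive enumeration agrees."""
        calc = clustering.IdentityCalculator()
        result = calc.identity(ProteinRecord("a", a), ProteinRecord("b", b))
        best_score, match_counts = optimal_alignment_stats(a, b)
        assert calc.score(a, b) == pytest.approx(best_score)
        assert result.aligned_matches in match_counts

    def test_x_never_matches(self):
        result = global_identity("MKXXLA", "MKXXLA")
        assert result.aligned_matches == 4
        assert result.identity == 4 / 6

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(20, 60)), "a")
            b = random_protein(rng, int(rng.integers(20, 60)), "b")
            assert global_identity(a, b).identity == pytest.approx(
                global_identity(b, a).identity
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            global_identity("", "MKVA")

    def test_alignment_length_denominator_option(self):
        scoring = clustering.ScoringConfig(denominator="alignment")
        result = global_identity("MKKLLAV", "MKKLAV", scoring)
        assert result.denominator == 7  # alignment spans the longer sequence
        assert result.identity == pytest.approx(6 / 7)


class TestGreedyCluster:
    def test_three_identical_across_species(self):
        seq = "MKVLATPQRS" * 8
        ssps = [ProteinRecord(f"p{i}", seq, f"Simulatus sp{i}") for i in range(3)]
        clusters = greedy_cluster(ssps)
        assert len(clusters) == 1
        assert clusters[0].n_species == 3
        assert clusters[0].representative == "p0"

    def test_threshold_is_inclusive_lower_bound(self):
        rng = np.random.default_rng(5)
        a = random_protein(rng, 100, "a", "s1")
        mutated = list(a.sequence)
        for i in range(0, 60, 2):  # 30 substitutions
            mutated[i] = "W" if mutated[i] != "W" else "Y"
        b = ProteinRecord("b", "".join(mutated), "s2")
        ident = global_identity(a, b).identity
        assert 0.5 < ident < 1.0
        assert len(greedy_cluster([a, b], threshold=ident)) == 1
        assert len(greedy_cluster([a, b], threshold=min(ident + 0.01, 1.0))) == 2

    def test_planted_family_plus_unrelated_randoms(self):
        family = plant_ssp_family(
            ancestor_length=150,
            n_members=6,
            species_set=[f"Simulatus sp{i}" for i in range(6)],
            target_identity=0.92,
            seed=13,
        )
        rng = np.random.default_rng(14)
        randoms = [random_protein(rng, 150, f"r{i}", "Simulatus spX") for i in range(4)]
        clusters = greedy_cluster(family.members + randoms, threshold=0.70)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 1, 1, 1, 6]

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(8)
        base = [random_protein(rng, int(rng.integers(50, 120)), f"p{i}") for i in range(12)]
        # add some near-duplicates
        extra = [
            ProteinRecord(f"d{i}", p.sequence[:-2] + "AA", p.species)
            for i, p in enumerate(base[:4])
        ]
        ssps = base + extra
        clusters = greedy_cluster(ssps, 0.70)
        members = [pid for c in clusters for pid, _ in c.members]
        assert sorted(members) == sorted(p.protein_id for p in ssps)
        shuffled = [ssps[i] for i in rng.permutation(len(ssps))]
        clusters2 = greedy_cluster(shuffled, 0.70)
        key = lambda cs: [(c.cluster_id, c.representative, sorted(c.members)) for c in cs]
        assert key(clusters) == key(clusters2)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(21)
        seqs = []
        for i in range(5):
            anc = random_protein(rng, 80, f"a{i}")
            seqs.append(anc)
            for j in range(2):
                mutated = list(anc.sequence)
                for k in rng.integers(0, 80, size=10):
                    mutated[k] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
                seqs.append(ProteinRecord(f"a{i}m{j}", "".join(mutated)))
        previous = 0
        for threshold in (0.3, 0.5, 0.7, 0.9, 1.0):
            n = len(greedy_cluster(seqs, threshold))
            assert n >= previous
            previous = n

    def test_representative_is_longest_member(self):
        rng = np.random.default_rng(30)
        ssps = [random_protein(rng, n, f"p{n}") for n in (60, 80, 100)]
        for cluster in greedy_cluster(ssps, 0.2):
            lengths = {pid: int(pid[1:]) for pid, _ in cluster.members}
            assert lengths[cluster.representative] == max(lengths.values())


class TestFilterClusters:
    def test_two_species_cluster_removed(self):
        seq = "MKVLATPQRS" * 8
        ssps = [ProteinRecord(f"p{i}", seq, f"s{i % 2}") for i in range(4)]
        clusters = greedy_cluster(ssps)
        assert filter_clusters(clusters, min_species=3) == []

    def test_species_not_member_count(self):
        seq = "MKVLATPQRS" * 8
        ssps = [ProteinRecord(f"p{i}", seq, "same species") for i in range(3)]
        clusters = greedy_cluster(ssps)
        assert len(clusters[0].members) == 3
        assert filter_clusters(clusters, min_species=3) == []

    def test_identity_on_published_fixture(self, fixture_clusters):
        assert filter_clusters(fixture_clusters, min_species=3) == fixture_clusters

    def test_ids_preserved(self):
        rng = np.random.default_rng(9)
        ssps = [random_protein(rng, 60, f"p{i}", f"s{i}") for i in range(5)]
        seq = "MKVLATPQRS" * 6
        ssps += [ProteinRecord(f"q{i}", seq, f"s{i}") for i in range(3)]
        clusters = greedy_cluster(ssps, 0.7)
        kept = filter_clusters(clusters, 3)
        original_ids = {c.cluster_id for c in clusters}
        assert kept and all(k.cluster_id in original_ids for k in kept)
        # the surviving cluster keeps its creation-order id, not a new 0-based one
        (q_cluster,) = [c for c in clusters if c.representative.startswith("q")]
        assert [k.cluster_id for k in kept] == [q_cluster.cluster_id]


class TestSpeciesSpecificSsps:
    def test_identical_cross_species_pair_not_specific(self):
        seq = "MKVLATPQRSWEDNCH" * 9  # 144 aa
        rng = np.random.default_rng(17)
        others = [random_protein(rng, 140, f"r{i}", "s3") for i in range(3)]
        ssps = [
            ProteinRecord("a", seq, "s1"),
            ProteinRecord("b", seq, "s2"),
            *others,
        ]
        specific = species_specific_ssps(ssps)
        assert "a" not in specific and "b" not in specific
        assert {o.protein_id for o in others} <= specific

    def test_intra_species_similarity_ignored(self):
        seq = "MKVLATPQRSWEDNCH" * 9
        rng = np.random.default_rng(18)
        ssps = [
            ProteinRecord("a", seq, "s1"),
            ProteinRecord("b", seq, "s1"),  # same species twin
            random_protein(rng, 140, "r0", "s2"),
        ]
        specific = species_specific_ssps(ssps)
        assert {"a", "b"} <= specific

    def test_single_species_returns_all_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(19)
        ssps = [random_protein(rng, 100, f"p{i}", "only") for i in range(3)]
        with caplog.at_level(logging.WARNING):
            specific = species_specific_ssps(ssps)
        assert specific == {p.protein_id for p in ssps}
        assert any("single species" in r.message for r in caplog.records)


class TestGreedyRuleOracle:
    def test_membership_rule_verified_by_all_pairs_identity(self):
        """Brute-force check of the greedy rule on a moderate random set."""
        rng = np.random.default_rng(55)
        calc = clustering.IdentityCalculator()
        ssps = []
        for i in range(6):
            anc = random_protein(rng, int(rng.integers(50, 110)), f"f{i}", f"s{i%3}")
            ssps.append(anc)
            rate = 1 - ancestor_identity_for_pairwise(0.85)
            for j in range(3):
                mutated = [
                    c
                    if rng.random() > rate
                    else "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
                    for c in anc.sequence
                ]
                ssps.append(ProteinRecord(f"f{i}v{j}", "".join(mutated), f"s{j%3}"))
        threshold = 0.70
        clusters = greedy_cluster(ssps, threshold)
        by_id = {p.protein_id: p for p in ssps}
        reps = {c.cluster_id: by_id[c.representative] for c in clusters}
        for cluster in clusters:
            for pid, _ in cluster.members:
                member = by_id[pid]
                if pid != cluster.representative:
                    assert (
                        calc.identity(member, reps[cluster.cluster_id]).identity
                        >= threshold
                    )
                # earlier-created clusters all existed when this member was
                # processed, so the member must have failed against their reps
                for earlier in clusters:
                    if earlier.cluster_id >= cluster.cluster_id:
                        break
                    rep = reps[earlier.cluster_id]
                    assert calc.identity(member, rep).identity < threshold
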
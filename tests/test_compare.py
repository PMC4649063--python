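"""Lifestyle partitioning, enrichment statistics, and summary comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secretominer import compare
from secretominer.compare import (
    compact_letters,
    fisher_greater,
    lifestyle_profile,
    pfam_enrichment,
    size_correlation,
    ssp_proportion_stats,
    venn_partition,
)
from secretominer.models import SSPCluster, SpeciesRecord

from .oracles import hypergeom_tail_greater


def _cluster(cluster_id, species):
    return SSPCluster(
        cluster_id=cluster_id,
        representative="",
        members=[(f"p{i}", sp) for i, sp in enumerate(species)],
    )


class TestLifestyleProfile:
    def test_fixture_ecm_only_cluster(self, registry, fixture_clusters):
        (c92,) = [c for c in fixture_clusters if c.cluster_id == 92]
        profile = lifestyle_profile(c92, registry)
        assert profile.specificity == "ECM_only"
        assert profile.region == ("ECM",)

    def test_fixture_saprotroph_only_cluster(self, registry, fixture_clusters):
        (c16,) = [c for c in fixture_clusters if c.cluster_id == 16]
        profile = lifestyle_profile(c16, registry)
        assert profile.specificity == "saprotroph_only"
        assert "ECM" not in profile.lifestyles

    def test_fixture_shared_cluster(self, registry, fixture_clusters):
        (c0,) = [c for c in fixture_clusters if c.cluster_id == 0]
        profile = lifestyle_profile(c0, registry)
        assert profile.specificity == "shared_ECM_saprotroph"

    def test_all_other_lifestyles_give_other(self, registry):
        cluster = _cluster(1, ["Ustilago maydis", "Tremella mesenterica", "Pichia stipitis"])
        profile = lifestyle_profile(cluster, registry)
        assert profile.specificity == "other"
        assert profile.region == ()

    def test_ecm_plus_pathogen_is_not_ecm_only(self, registry):
        cluster = _cluster(2, ["Laccaria bicolor", "Ustilago maydis"])
        profile = lifestyle_profile(cluster, registry)
        assert profile.specificity == "other"
        assert profile.region == ("ECM",)

    def test_unknown_species_raises(self, registry):
        with pytest.raises(KeyError, match="Madeupus"):
            lifestyle_profile(_cluster(3, ["Madeupus novus"]), registry)


class TestVennPartition:
    def test_all_ecm_only(self, registry):
        clusters = [_cluster(i, ["Laccaria bicolor", "Suillus luteus"]) for i in range(4)]
        profiles = [lifestyle_profile(c, registry) for c in clusters]
        assert venn_partition(profiles) == {("ECM",): 4}

    def test_two_group_regions(self, registry):
        groups = ("ECM", "white_rot")
        clusters = {
            "A": _cluster(0, ["Laccaria bicolor"]),
            "B": _cluster(1, ["Trametes versicolor"]),
            "AB": _cluster(2, ["Laccaria bicolor", "Trametes versicolor"]),
        }
        profiles = [lifestyle_profile(c, registry) for c in clusters.values()]
        counts = venn_partition(profiles, groups)
        assert counts == {("ECM",): 1, ("white_rot",): 1, ("ECM", "white_rot"): 1}

    def test_fixture_reproduces_published_partition(self, registry, fixture_clusters):
        profiles = [lifestyle_profile(c, registry) for c in fixture_clusters]
        counts = venn_partition(profiles)
        assert counts[("ECM",)] == 17
        assert sum(counts.values()) == len(fixture_clusters)
        ecm_only_no_pfam = [
            c
            for c, p in zip(fixture_clusters, profiles)
            if p.specificity == "ECM_only" and c.pfam_label == "None"
        ]
        assert len(ecm_only_no_pfam) == 6

    def test_conservation(self, registry, fixture_clusters):
        profiles = [lifestyle_profile(c, registry) for c in fixture_clusters]
        in_scope = [p for p in profiles if p.region]
        assert sum(venn_partition(profiles).values()) == len(in_scope)


class TestEnrichment:
    def test_fisher_matches_hypergeometric_tail(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            assert fisher_greater(a, b, c, d) == pytest.approx(
                hypergeom_tail_greater(a, b, c, d), abs=1e-12
            )

    def test_degenerate_tables_give_p_one(self):
        assert fisher_greater(0, 0, 5, 7) == 1.0
        assert fisher_greater(3, 4, 0, 0) == 1.0

    def test_ubiquitous_domain_not_enriched(self, registry):
        from secretominer.models import SecretomeAnnotation

        annotations = []
        species = ["Laccaria bicolor", "Suillus luteus", "Trametes versicolor",
                   "Serpula lacrymans"]
        for i, sp in enumerate(species * 10):
            annotations.append(
                SecretomeAnnotation(protein_id=f"p{i}", species=sp,
                                    pfam_domains=("PF99999",))
            )
        results = pfam_enrichment(annotations, registry, "Ectomycorrhizal")
        assert results[0].p_value == 1.0
        assert not results[0].enriched

    def test_planted_tenfold_domain_detected(self, small_dataset):
        """A domain planted at 10x background in one lifestyle tops the ranking."""
        from secretominer import annotation, prediction, simulate

        enrichment = {("Ectomycorrhizal", "PF00082"): 10.0}
        hits = simulate.generate_hit_tables(small_dataset, enrichment, seed=23)
        decisions = prediction.predict_secretome(
            small_dataset.proteins, small_dataset.evidence
        )
        annotations = annotation.annotate_secretome(
            small_dataset.proteins, decisions, hits
        )
        results = pfam_enrichment(
            annotations, small_dataset.species, "Ectomycorrhizal"
        )
        assert results[0].pfam == "PF00082"
        assert results[0].enriched

    def test_contingency_counts_sum_to_total(self, registry):
        from secretominer.models import SecretomeAnnotation

        rng = np.random.default_rng(2)
        species = ["Laccaria bicolor", "Trametes versicolor", "Serpula lacrymans"]
        annotations = [
            SecretomeAnnotation(
                protein_id=f"p{i}",
                species=species[i % 3],
                pfam_domains=("PF1",) if rng.random() < 0.4 else (),
            )
            for i in range(60)
        ]
        results = pfam_enrichment(annotations, registry, "Ectomycorrhizal")
        for res in results:
            assert res.a + res.b + res.c + res.d == len(annotations)
            assert res.adjusted_p >= res.p_value


class TestHolmProperties:
    def test_monotone_and_above_raw(self):
        from statsmodels.stats.multitest import multipletests

        raw = [0.001, 0.02, 0.04, 0.3, 0.9]
        adjusted = multipletests(raw, method="holm")[1]
        assert all(a >= r for a, r in zip(adjusted, raw))
        order = np.argsort(raw)
        assert all(np.diff(adjusted[order]) >= -1e-15)

    def test_reordering_does_not_change_values(self):
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.04, 0.001, 0.9, 0.02, 0.3])
        adj = multipletests(raw, method="holm")[1]
        perm = np.array([2, 0, 4, 1, 3])
        adj_perm = multipletests(raw[perm], method="holm")[1]
        assert np.allclose(adj[perm], adj_perm)


def _summary_frame(groups: dict[str, list[float]], registry_names) -> pd.DataFrame:
    """Build a per-species summary with SSP percentages given per lifestyle."""
    rows = []
    for lifestyle, values in groups.items():
        names = [s.name for s in registry_names if s.lifestyle == lifestyle]
        for name, pct in zip(names, values):
            rows.append((name, 10000, 400, pct * 400 / 100, 0))
    return pd.DataFrame(
        rows,
        columns=["species", "proteome_size", "secretome_size", "ssp_count",
                 "species_specific_ssp_count"],
    )


class TestProportionStats:
    def test_identical_groups_share_a_letter(self, registry):
        values = [30.0] * 12
        frame = _summary_frame(
            {"Ectomycorrhizal": values[:11], "White rot": values[:12],
             "Brown rot": values[:8], "Litter decayers": values[:7]},
            registry,
        )
        result = ssp_proportion_stats(frame, registry)
        pairs = result.pairwise[result.pairwise["metric"] == "ssp_pct"]
        assert (pairs["t_p_adj"] == 1.0).all()
        letters = set(result.letters["ssp_pct"].values())
        assert len(letters) == 1

    def test_separated_groups_significant_and_match_closed_form(self, registry):
        rng = np.random.default_rng(4)
        high = list(np.clip(rng.normal(30, 3, 8), 0, 100))
        low = list(np.clip(rng.normal(15, 3, 8), 0, 100))
        frame = _summary_frame({"Ectomycorrhizal": high, "White rot": low}, registry)
        result = ssp_proportion_stats(frame, registry)
        row = result.pairwise.iloc[0]
        # closed-form pooled two-sample t statistic
        x, y = np.array(high), np.array(low)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        p = 2 * stats.t.sf(abs(t), len(x) + len(y) - 2)
        assert row["t_p"] == pytest.approx(p, rel=1e-12)
        assert row["t_p_adj"] < 0.01
        assert result.letters["ssp_pct"]["Ectomycorrhizal"] != result.letters[
            "ssp_pct"
        ]["White rot"]

    def test_min_group_size_excludes_small_lifestyles(self, registry):
        frame = _summary_frame(
            {"Ectomycorrhizal": [30] * 6, "White rot": [20] * 6,
             "Orchid symbiont": [25] * 2},
            registry,
        )
        result = ssp_proportion_stats(frame, registry, min_group_size=5)
        groups = set(result.pairwise["group1"]) | set(result.pairwise["group2"])
        assert "Orchid symbiont" not in groups

    def test_fewer_than_two_groups_is_error(self, registry):
        frame = _summary_frame({"Ectomycorrhizal": [30] * 6}, registry)
        with pytest.raises(ValueError, match="at least two"):
            ssp_proportion_stats(frame, registry)

    def test_compact_letters_basic(self):
        letters = compact_letters(["a", "b", "c"], {("a", "b")})
        assert set(letters["a"]) != set(letters["b"])
        assert set(letters["c"]) & (set(letters["a"]) | set(letters["b"]))


class TestSizeCorrelation:
    def _frame(self, points, lifestyle_names):
        return pd.DataFrame(
            [(name, x, y) for name, (x, y) in zip(lifestyle_names, points)],
            columns=["species", "proteome_size", "secretome_size"],
        )

    def test_perfectly_linear(self, registry):
        ecm = [s.name for s in registry if s.lifestyle == "Ectomycorrhizal"]
        points = [(1000 * (i + 1), 50 * (i + 1) + 7) for i in range(6)]
        result = size_correlation(self._frame(points, ecm), registry)
        row = result[result["lifestyle"] == "Ectomycorrhizal"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)

    def test_orthogonal_points_r_zero(self, registry):
        ecm = [s.name for s in registry if s.lifestyle == "Ectomycorrhizal"]
        points = [(0, 0), (0, 2), (2, 1), (-2, 1)]  # cov(x, y) = 0 by symmetry
        result = size_correlation(self._frame(points, ecm), registry)
        row = result[result["lifestyle"] == "Ectomycorrhizal"].iloc[0]
        assert row["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_on_noisy_data(self, registry):
        rng = np.random.default_rng(6)
        ecm = [s.name for s in registry if s.lifestyle == "Ectomycorrhizal"]
        x = rng.uniform(4000, 25000, 10)
        y = 0.05 * x + rng.normal(0, 40, 10)
        result = size_correlation(self._frame(list(zip(x, y)), ecm), registry)
        row = result[result["lifestyle"] == "Ectomycorrhizal"].iloc[0]
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["r2"] == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_reported_missing(self, registry):
        ecm = [s.name for s in registry if s.lifestyle == "Ectomycorrhizal"]
        points = [(1000, 50), (1000, 60), (1000, 70)]
        result = size_correlation(self._frame(points, ecm), registry)
        row = result[result["lifestyle"] == "Ectomycorrhizal"].iloc[0]
        assert np.isnan(row["r"])
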
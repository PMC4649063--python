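"""Lifestyle partitioning of SSP clusters and the pipeline's summary statistics.

Covers: Venn partitioning of clusters over lifestyle groups, shared- versus
lifestyle-specific cluster calls, PFAM domain enrichment per lifestyle
(one-sided Fisher exact test with Holm adjustment), pairwise comparisons of
SSP proportions across lifestyles, and per-lifestyle correlation of secretome
size with proteome size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    EnrichmentResult,
    LifestyleProfile,
    SSPCluster,
    SecretomeAnnotation,
    SpeciesRecord,
)
from .registry_io import load_lifestyle_groups

logger = logging.getLogger(__name__)

#: Lifestyle groups regarded as saprotrophic for cluster specificity calls.
SAPROTROPH_GROUPS = frozenset({"white_rot", "brown_rot", "litter_decayer"})
#: The four groups of the cluster-sharing Venn analysis.
DEFAULT_GROUPS = ("ECM", "white_rot", "brown_rot", "litter_decayer")


# ---------------------------------------------------------------------------
# Lifestyle profiles and Venn partition
# ---------------------------------------------------------------------------

def lifestyle_profile(
    cluster: SSPCluster,
    registry: list[SpeciesRecord],
    grouping: dict[str, str] | None = None,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
) -> LifestyleProfile:
    """Lifestyle composition and specificity call for one cluster.

    ``lifestyles`` is the image of the member species' registry lifestyles
    under the grouping map (lifestyles outside the declared groups map to
    "other"); ``region`` restricts that set to the declared Venn groups.
    Specificity: ECM_only iff the composition is exactly {ECM};
    saprotroph_only iff it is a non-empty subset of the saprotroph groups;
    shared_ECM_saprotroph iff ECM plus at least one saprotroph group and
    nothing else; anything else is "other".
    """
    if grouping is None:
        grouping = load_lifestyle_groups()
    lifestyle_of = {s.name: s.lifestyle for s in registry}
    lifestyles = set()
    for _, species in cluster.members:
        if species not in lifestyle_of:
            raise KeyError(
                f"cluster {cluster.cluster_id}: species {species!r} not in registry"
            )
        lifestyles.add(grouping.get(lifestyle_of[species], "other"))
    region = tuple(sorted(lifestyles & set(groups)))
    if lifestyles == {"ECM"}:
        specificity = "ECM_only"
    elif lifestyles and lifestyles <= SAPROTROPH_GROUPS:
        specificity = "saprotroph_only"
    elif (
        "ECM" in lifestyles
        and (lifestyles - {"ECM"})
        and (lifestyles - {"ECM"}) <= SAPROTROPH_GROUPS
    ):
        specificity = "shared_ECM_saprotroph"
    else:
        specificity = "other"
    return LifestyleProfile(
        cluster_id=cluster.cluster_id,
        lifestyles=frozenset(lifestyles),
        region=region,
        specificity=specificity,
    )


def venn_partition(
    profiles: list[LifestyleProfile], groups: tuple[str, ...] = DEFAULT_GROUPS
) -> dict[tuple[str, ...], int]:
    """Count clusters per exact Venn region over the declared groups.

    Each profile falls in exactly one region (the sorted tuple of groups its
    members cover); profiles covering none of the declared groups are left
    out, so region counts sum to the number of in-scope profiles.
    """
    counts: dict[tuple[str, ...], int] = {}
    for profile in profiles:
        region = tuple(sorted(set(profile.region) & set(groups)))
        if not region:
            continue
        counts[region] = counts.get(region, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# PFAM enrichment
# ---------------------------------------------------------------------------

def pfam_enrichment(
    annotations: list[SecretomeAnnotation],
    registry: list[SpeciesRecord],
    lifestyle: str,
    min_count: int = 1,
    alpha: float = 0.01,
    method: str = "holm",
) -> list[EnrichmentResult]:
    """One-sided over-representation tests of PFAM domains in one lifestyle.

    For each domain, a 2x2 table of secreted proteins (in lifestyle vs
    elsewhere) x (has domain vs lacks domain) is tested with a one-sided
    Fisher exact test; p-values are adjusted across domains (Holm by
    default). Degenerate tables (zero margin) give p = 1. Domains occurring
    fewer than ``min_count`` times overall are not tested.
    """
    lifestyle_of = {s.name: s.lifestyle for s in registry}
    in_group = []
    domains_of: dict[str, tuple[str, ...]] = {}
    for ann in annotations:
        ls = lifestyle_of.get(ann.species)
        if ls is None:
            raise KeyError(f"species {ann.species!r} not in registry")
        in_group.append(ls == lifestyle)
        domains_of[ann.protein_id] = ann.pfam_domains
    in_group_arr = np.array(in_group)
    n_in = int(in_group_arr.sum())
    n_out = len(annotations) - n_in
    if n_in == 0:
        raise ValueError(f"no secreted proteins belong to lifestyle {lifestyle!r}")

    domain_counts: dict[str, int] = {}
    for ann in annotations:
        for dom in set(ann.pfam_domains):
            domain_counts[dom] = domain_counts.get(dom, 0) + 1
    tested = sorted(d for d, n in domain_counts.items() if n >= min_count)

    raw_p = []
    tables = []
    for domain in tested:
        a = sum(
            1
            for ann, flag in zip(annotations, in_group)
            if flag and domain in ann.pfam_domains
        )
        c = domain_counts[domain] - a
        b = n_in - a
        d = n_out - c
        tables.append((a, b, c, d))
        raw_p.append(fisher_greater(a, b, c, d))
    if tested:
        adjusted = multipletests(raw_p, method=method)[1]
    else:
        adjusted = []
    results = [
        EnrichmentResult(
            lifestyle=lifestyle,
            pfam=domain,
            a=a,
            b=b,
            c=c,
            d=d,
            p_value=p,
            adjusted_p=float(ap),
            enriched=bool(ap < alpha),
        )
        for domain, (a, b, c, d), p, ap in zip(tested, tables, raw_p, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.pfam))
    return results


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact p for a 2x2 table.

    Degenerate tables with a zero row or column margin return 1.0.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


# ---------------------------------------------------------------------------
# SSP proportion statistics
# ---------------------------------------------------------------------------

@dataclass
class ProportionStats:
    """Pairwise group comparisons of per-species SSP proportions."""

    per_species: pd.DataFrame  # species, lifestyle, metric columns (percent)
    pairwise: pd.DataFrame  # group pair x metric with raw and adjusted p
    letters: dict[str, dict[str, str]]  # metric -> group -> significance letters


def ssp_proportion_stats(
    summary: pd.DataFrame,
    registry: list[SpeciesRecord],
    min_group_size: int = 5,
    alpha: float = 0.01,
) -> ProportionStats:
    """Compare SSP%% of secretome (and species-specific SSP%%) across lifestyles.

    ``summary`` must carry per-species columns ``species``, ``secretome_size``,
    ``ssp_count`` and optionally ``species_specific_ssp_count``. Only
    lifestyles with at least ``min_group_size`` species are compared, with
    pairwise two-sample t-tests (pooled variance) and rank-sum tests, each
    Holm-adjusted across pairs, plus compact significance letters at alpha.
    """
    lifestyle_of = {s.name: s.lifestyle for s in registry}
    frame = summary.copy()
    frame["lifestyle"] = frame["species"].map(lifestyle_of)
    if frame["lifestyle"].isna().any():
        missing = frame.loc[frame["lifestyle"].isna(), "species"].tolist()
        raise KeyError(f"species not in registry: {missing}")
    frame["ssp_pct"] = 100.0 * frame["ssp_count"] / frame["secretome_size"]
    metrics = ["ssp_pct"]
    if "species_specific_ssp_count" in frame.columns:
        frame["specific_ssp_pct"] = (
            100.0 * frame["species_specific_ssp_count"] / frame["secretome_size"]
        )
        metrics.append("specific_ssp_pct")

    sizes = frame.groupby("lifestyle")["species"].count()
    qualifying = sorted(sizes[sizes >= min_group_size].index)
    if len(qualifying) < 2:
        raise ValueError(
            f"need at least two lifestyles with >= {min_group_size} species; "
            f"got {qualifying}"
        )

    rows = []
    letters: dict[str, dict[str, str]] = {}
    for metric in metrics:
        values = {g: frame.loc[frame["lifestyle"] == g, metric].to_numpy() for g in qualifying}
        pairs = list(itertools.combinations(qualifying, 2))
        t_p, w_p = [], []
        for g1, g2 in pairs:
            x, y = values[g1], values[g2]
            if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
                t_p.append(1.0)
                w_p.append(1.0)
                continue
            t_p.append(float(stats.ttest_ind(x, y, equal_var=True).pvalue))
            w_p.append(float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue))
        t_adj = multipletests(t_p, method="holm")[1] if pairs else []
        w_adj = multipletests(w_p, method="holm")[1] if pairs else []
        for (g1, g2), tp, ta, wp, wa in zip(pairs, t_p, t_adj, w_p, w_adj):
            rows.append((metric, g1, g2, tp, float(ta), wp, float(wa)))
        significant = {
            (g1, g2) for (g1, g2), ta in zip(pairs, t_adj) if ta < alpha
        }
        letters[metric] = compact_letters(qualifying, significant)

    pairwise = pd.DataFrame(
        rows,
        columns=["metric", "group1", "group2", "t_p", "t_p_adj", "wilcoxon_p", "wilcoxon_p_adj"],
    )
    per_species = frame[["species", "lifestyle"] + metrics]
    return ProportionStats(per_species=per_species, pairwise=pairwise, letters=letters)


def compact_letters(
    groups: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly different.

    Insert-and-absorb algorithm: start from one letter covering all groups;
    every significant pair splits the letters containing both members;
    letters that become subsets of others are absorbed.
    """
    sets: list[set[str]] = [set(groups)]
    for g1, g2 in sorted(significant_pairs):
        new_sets: list[set[str]] = []
        for current in sets:
            if g1 in current and g2 in current:
                new_sets.extend([current - {g1}, current - {g2}])
            else:
                new_sets.append(current)
        # absorb subsets
        new_sets = [s for s in new_sets if s]
        sets = [
            s
            for i, s in enumerate(new_sets)
            if not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, members in zip(alphabet, sets):
        for g in members:
            out[g] += letter
    return out


# ---------------------------------------------------------------------------
# Secretome-size correlation
# ---------------------------------------------------------------------------

def size_correlation(
    summary: pd.DataFrame, registry: list[SpeciesRecord], min_species: int = 3
) -> pd.DataFrame:
    """Pearson r and r^2 of secretome size vs proteome size per lifestyle.

    Lifestyles with fewer than ``min_species`` species, or with zero variance
    on either axis, are reported with missing r.
    """
    lifestyle_of = {s.name: s.lifestyle for s in registry}
    frame = summary.copy()
    frame["lifestyle"] = frame["species"].map(lifestyle_of)
    rows = []
    for lifestyle, sub in frame.groupby("lifestyle"):
        x = sub["proteome_size"].to_numpy(dtype=float)
        y = sub["secretome_size"].to_numpy(dtype=float)
        if len(sub) < min_species or np.std(x) == 0 or np.std(y) == 0:
            rows.append((lifestyle, len(sub), np.nan, np.nan))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append((lifestyle, len(sub), r, r * r))
    return pd.DataFrame(rows, columns=["lifestyle", "n_species", "r", "r2"]).sort_values(
        "lifestyle", ignore_index=True
    )
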
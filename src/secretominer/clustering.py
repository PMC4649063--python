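"""Pairwise sequence identity and greedy incremental clustering of SSPs.

Identity is measured on an optimal global alignment (BLOSUM62, affine gaps)
as identical aligned residue pairs divided by the length of the shorter
sequence — the convention of greedy incremental clustering tools. Clustering
processes sequences longest-first; each sequence joins the earliest cluster
whose representative it matches at or above the identity threshold, otherwise
it founds a new cluster. Species-specific SSPs are those with no
cross-species alignment passing a bit-score/e-value criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .models import IdentityResult, ProteinRecord, SSPCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring and identity convention."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    denominator: str = "shorter"  # or "alignment"

    def __post_init__(self) -> None:
        if self.denominator not in ("shorter", "alignment"):
            raise ValueError(f"unknown identity denominator {self.denominator!r}")


def _make_aligner(scoring: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = "global"
    return aligner


class IdentityCalculator:
    """Caches one aligner; computes global-alignment identities."""

    def __init__(self, scoring: ScoringConfig = ScoringConfig()):
        self.scoring = scoring
        self._aligner = _make_aligner(scoring)

    def identity(self, a: ProteinRecord, b: ProteinRecord) -> IdentityResult:
        if not a.sequence or not b.sequence:
            raise ValueError("cannot align an empty sequence")
        alignment = next(iter(self._aligner.align(a.sequence, b.sequence)))
        matches = 0
        aligned_columns = 0
        target_blocks, query_blocks = alignment.aligned
        for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
            aligned_columns += te - ts
            for x, y in zip(a.sequence[ts:te], b.sequence[qs:qe]):
                if x == y and x != "X":  # X never counts as a match
                    matches += 1
        if self.scoring.denominator == "shorter":
            denominator = min(len(a.sequence), len(b.sequence))
        else:
            denominator = alignment.length
        return IdentityResult(
            query=a.protein_id,
            subject=b.protein_id,
            identity=matches / denominator,
            aligned_matches=matches,
            denominator=denominator,
        )

    def score(self, a: str, b: str) -> float:
        return self._aligner.score(a, b)


def global_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    scoring: ScoringConfig = ScoringConfig(),
) -> IdentityResult:
    """Identity between two sequences under an optimal global alignment."""
    if isinstance(a, str):
        a = ProteinRecord("query", a)
    if isinstance(b, str):
        b = ProteinRecord("subject", b)
    return IdentityCalculator(scoring).identity(a, b)


def greedy_cluster(
    ssps: list[ProteinRecord],
    threshold: float = 0.70,
    scoring: ScoringConfig = ScoringConfig(),
) -> list[SSPCluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are sorted by length descending (ties broken by protein id);
    each joins the first existing cluster whose representative it matches at
    identity >= threshold, else founds a new cluster with itself as the
    representative. Clusters are numbered in creation order, so the
    representative is always a longest member and the outcome is independent
    of input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    calc = IdentityCalculator(scoring)
    ordered = sorted(ssps, key=lambda p: (-p.length, p.protein_id))
    clusters: list[SSPCluster] = []
    representatives: list[ProteinRecord] = []
    for protein in ordered:
        placed = False
        for cluster, rep in zip(clusters, representatives):
            if calc.identity(protein, rep).identity >= threshold:
                cluster.members.append((protein.protein_id, protein.species))
                lo, hi = cluster.length_range
                cluster.length_range = (min(lo, protein.length), max(hi, protein.length))
                placed = True
                break
        if not placed:
            clusters.append(
                SSPCluster(
                    cluster_id=len(clusters),
                    representative=protein.protein_id,
                    members=[(protein.protein_id, protein.species)],
                    length_range=(protein.length, protein.length),
                )
            )
            representatives.append(protein)
    return clusters


def filter_clusters(clusters: list[SSPCluster], min_species: int = 3) -> list[SSPCluster]:
    """Keep clusters spanning at least ``min_species`` distinct species; ids unchanged."""
    return [c for c in clusters if c.n_species >= min_species]


# ---------------------------------------------------------------------------
# Species-specific SSP detection
# ---------------------------------------------------------------------------

#: Karlin-Altschul parameters for gapped BLOSUM62 scoring (surrogate for the
#: named similarity-search tool).
_KA_LAMBDA = 0.267
_KA_K = 0.041


def bitscore(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2)


def species_specific_ssps(
    ssps: list[ProteinRecord],
    evalue_cutoff: float = 1e-5,
    scoring: ScoringConfig = ScoringConfig(),
) -> set[str]:
    """SSPs with no significant alignment to any SSP of a different species.

    Significance uses a Karlin-Altschul e-value surrogate: a pair is a hit
    when ``m * N * 2**-bitscore <= cutoff`` with m the query length and N the
    total residue count of SSPs from other species. Intra-species similarity
    is ignored. With a single species present every SSP is trivially
    species-specific (logged as a warning).
    """
    species_present = {p.species for p in ssps}
    if len(species_present) < 2:
        logger.warning(
            "species-specific SSP detection called with a single species; "
            "all SSPs returned"
        )
        return {p.protein_id for p in ssps}
    calc = IdentityCalculator(scoring)
    total_residues = {
        sp: sum(p.length for p in ssps if p.species != sp) for sp in species_present
    }
    specific: set[str] = set()
    ordered = sorted(ssps, key=lambda p: p.protein_id)
    has_hit: set[str] = set()
    for i, query in enumerate(ordered):
        for subject in ordered[i + 1 :]:
            if query.species == subject.species:
                continue
            if query.protein_id in has_hit and subject.protein_id in has_hit:
                continue
            raw = calc.score(query.sequence, subject.sequence)
            bits = bitscore(raw)
            evalue_q = query.length * total_residues[query.species] * 2.0 ** (-bits)
            evalue_s = subject.length * total_residues[subject.species] * 2.0 ** (-bits)
            if evalue_q <= evalue_cutoff:
                has_hit.add(query.protein_id)
            if evalue_s <= evalue_cutoff:
                has_hit.add(subject.protein_id)
    for protein in ordered:
        if protein.protein_id not in has_hit:
            specific.add(protein.protein_id)
    return specific


def clusters_frame(clusters: list[SSPCluster]):
    """Long-format membership table (cluster_id, representative, member, species)."""
    import pandas as pd

    rows = []
    for cluster in clusters:
        for protein_id, species in cluster.members:
            rows.append((cluster.cluster_id, cluster.representative, protein_id, species))
    return pd.DataFrame(
        rows, columns=["cluster_id", "representative", "member", "species"]
    )


def cluster_summary_frame(clusters: list[SSPCluster]):
    """One row per cluster mirroring the published cluster-table columns."""
    import pandas as pd

    rows = [
        (
            c.cluster_id,
            c.n_species,
            c.length_range[0],
            c.length_range[1],
            c.pfam_label,
            ";".join(sorted(c.member_species)),
        )
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_species", "length_min", "length_max", "pfam", "species"],
    )
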
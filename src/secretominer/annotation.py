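"""Functional categorization of secreted proteins from reference hit tables.

Each secreted protein is assigned to one of the categories CAZyme, Protease,
Lipase, SSP or Other from its best similarity hits against CAZy-, MEROPS- and
LED-style reference tables; PFAM hits annotate domains without driving the
category. Composition metrics (cysteine percentage, K/R-rich regions) and an
optional surrogate NLS scan complete the annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .models import ProteinRecord, ReferenceHit, SecretionDecision, SecretomeAnnotation

logger = logging.getLogger(__name__)

#: Category implied by the database of the overall best hit.
_CATEGORY_BY_DB = {"CAZy": "CAZyme", "MEROPS": "Protease", "LED": "Lipase"}
#: Database precedence used only to break exact e-value/bitscore ties.
_DB_ORDER = {"CAZy": 0, "MEROPS": 1, "LED": 2}

_LIPASE_CLASSES = ("GGGX", "GX")


@dataclass(frozen=True)
class AnnotationConfig:
    evalue_cutoff: float = 1e-5
    kr_window: int = 20
    kr_min_fraction: float = 0.4
    nls_scan: bool = False  # surrogate basic-residue scan, off by default


def best_hits(
    hits: list[ReferenceHit], evalue_cutoff: float = 1e-5
) -> dict[str, ReferenceHit]:
    """Best hit per database among hits at or below the e-value cutoff.

    Ties on e-value are broken by larger bitscore, then lexicographically
    smaller subject label.
    """
    best: dict[str, ReferenceHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        current = best.get(hit.database)
        if current is None or _hit_rank(hit) < _hit_rank(current):
            best[hit.database] = hit
    return best


def _hit_rank(hit: ReferenceHit) -> tuple:
    return (hit.evalue, -hit.bitscore, hit.subject_label)


def assign_category(per_db_best: dict[str, ReferenceHit], ssp_flag: bool) -> str:
    """Category of the overall smallest-e-value hit across CAZy/MEROPS/LED.

    Without any qualifying hit the protein is SSP when flagged, else Other.
    The SSP flag itself is stored independently of the category.
    """
    candidates = [per_db_best[db] for db in _CATEGORY_BY_DB if db in per_db_best]
    if not candidates:
        return "SSP" if ssp_flag else "Other"
    winner = min(candidates, key=lambda h: _hit_rank(h) + (_DB_ORDER[h.database],))
    return _CATEGORY_BY_DB[winner.database]


def protease_type(merops_family: str, mapping: dict[str, str]) -> str:
    """endo/exo type of a MEROPS family; families outside the mapping are unassigned."""
    return mapping.get(merops_family, "unassigned")


def lipase_classify(led_label: str) -> tuple[str | None, str | None]:
    """Parse an LED-style label like ``GGGX.carboxylesterase`` into (class, subfamily)."""
    label = str(led_label)
    cls, _, subfamily = label.partition(".")
    if cls not in _LIPASE_CLASSES:
        logger.warning("LED label %r has no recognized GX/GGGX class prefix", led_label)
        return None, None
    return cls, subfamily or None


def cys_percent(sequence: str) -> float:
    """Percentage of cysteine residues over the full sequence length."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * sequence.count("C") / len(sequence)


def kr_rich_regions(
    sequence: str, window: int = 20, min_fraction: float = 0.4
) -> list[tuple[int, int]]:
    """Maximal 1-based intervals covered by K/R-rich sliding windows.

    A window of ``window`` residues qualifies when its K+R fraction is at
    least ``min_fraction``; overlapping qualifying windows merge into one
    interval. Sequences shorter than the window yield no regions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(sequence)
    if n < window:
        return []
    is_kr = [1 if res in "KR" else 0 for res in sequence]
    count = sum(is_kr[:window])
    need = min_fraction * window
    regions: list[tuple[int, int]] = []
    current: tuple[int, int] | None = None
    for i in range(n - window + 1):
        if i > 0:
            count += is_kr[i + window - 1] - is_kr[i - 1]
        if count >= need:
            start, end = i + 1, i + window  # 1-based inclusive
            if current is not None and start <= current[1] + 1:
                current = (current[0], end)
            else:
                if current is not None:
                    regions.append(current)
                current = (start, end)
    if current is not None:
        regions.append(current)
    return regions


_NLS_RE = re.compile(r"K[KR].[KR]")


def nls_scan(sequence: str) -> bool:
    """Surrogate monopartite NLS scan (K-[KR]-x-[KR]); a crude stand-in for a
    dedicated nuclear-localization predictor, disabled by default."""
    return _NLS_RE.search(sequence) is not None


def annotate_protein(
    protein: ProteinRecord,
    decision: SecretionDecision,
    hits: list[ReferenceHit],
    protease_mapping: dict[str, str],
    config: AnnotationConfig = AnnotationConfig(),
) -> SecretomeAnnotation:
    """Full annotation of one secreted protein."""
    per_db = best_hits(hits, config.evalue_cutoff)
    category = assign_category(per_db, decision.ssp)
    merops = per_db["MEROPS"].subject_label if "MEROPS" in per_db else None
    cazy = per_db["CAZy"].subject_label if "CAZy" in per_db else None
    lip_class = lip_sub = None
    if "LED" in per_db:
        lip_class, lip_sub = lipase_classify(per_db["LED"].subject_label)
    pfams = tuple(
        sorted({h.subject_label for h in hits if h.database == "PFAM" and h.evalue <= config.evalue_cutoff})
    )
    return SecretomeAnnotation(
        protein_id=protein.protein_id,
        species=protein.species,
        category=category,
        ssp=decision.ssp,
        cazy_family=cazy,
        merops_family=merops,
        protease_type=protease_type(merops, protease_mapping) if merops else "unassigned",
        lipase_class=lip_class,
        lipase_subfamily=lip_sub,
        pfam_domains=pfams,
        cys_percent=cys_percent(protein.sequence),
        kr_rich_regions=tuple(
            kr_rich_regions(protein.sequence, config.kr_window, config.kr_min_fraction)
        ),
        nls_predicted=nls_scan(protein.sequence) if config.nls_scan else False,
    )


def annotate_secretome(
    proteins: list[ProteinRecord],
    decisions: list[SecretionDecision],
    hits: list[ReferenceHit],
    protease_mapping: dict[str, str] | None = None,
    config: AnnotationConfig = AnnotationConfig(),
) -> list[SecretomeAnnotation]:
    """Annotate every secreted protein of a proteome (non-secreted are skipped)."""
    if protease_mapping is None:
        from .registry_io import load_protease_types

        protease_mapping = load_protease_types()
    by_id = {p.protein_id: p for p in proteins}
    hits_by_id: dict[str, list[ReferenceHit]] = {}
    for hit in hits:
        hits_by_id.setdefault(hit.protein_id, []).append(hit)
    annotations = []
    for decision in decisions:
        if not decision.secreted:
            continue
        protein = by_id[decision.protein_id]
        annotations.append(
            annotate_protein(
                protein,
                decision,
                hits_by_id.get(decision.protein_id, []),
                protease_mapping,
                config,
            )
        )
    return annotations
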
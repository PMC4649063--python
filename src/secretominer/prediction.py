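"""The combined secretion decision rule and the surrogate evidence predictor.

A protein is called secreted when all five sub-criteria hold: a predicted
signal peptide, a compatible transmembrane topology (no helix, or a single
helix overlapping the signal peptide), a secretory-pathway call, a top-ranked
extracellular compartment, and no C-terminal ER-retention motif. Secreted
proteins shorter than 300 residues (full precursor) are flagged as
small-secreted proteins (SSPs).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .models import (
    ConfigError,
    EvidenceRecord,
    FormatError,
    ProteinRecord,
    RuleOutcomes,
    SecretionDecision,
)

#: Residues counted as hydrophobic when detecting signal-peptide h-regions.
HYDROPHOBIC = frozenset("AILMFVW")
#: Small residues accepted at the -3/-1 cleavage-site positions.
SMALL_RESIDUES = frozenset("AGSCT")

#: PROSITE ER_TARGET (PS00014) position sets for the C-terminal tetrapeptide.
_PS00014 = (frozenset("KRHQSA"), frozenset("DENQ"), frozenset("E"), frozenset("L"))


@dataclass(frozen=True)
class PredictConfig:
    """Tunables of the decision rule."""

    kdel_mode: str = "ps00014"  # or "strict_kdel"
    ssp_threshold: int = 300

    def __post_init__(self) -> None:
        if self.kdel_mode not in ("ps00014", "strict_kdel"):
            raise ConfigError(f"unknown kdel mode {self.kdel_mode!r}")
        if self.ssp_threshold < 1:
            raise ConfigError("ssp_threshold must be >= 1")


def scan_cterm_retention(sequence: str, mode: str = "ps00014") -> bool:
    """True iff the last four residues form an ER-retention motif.

    ``strict_kdel`` matches the literal K-D-E-L; ``ps00014`` matches the
    PROSITE ER_TARGET pattern [KRHQSA]-[DENQ]-E-L. Sequences shorter than
    four residues cannot carry the motif.
    """
    if mode not in ("ps00014", "strict_kdel"):
        raise ConfigError(f"unknown kdel mode {mode!r}")
    if len(sequence) < 4:
        return False
    tail = sequence[-4:].upper()
    if mode == "strict_kdel":
        return tail == "KDEL"
    return all(res in allowed for res, allowed in zip(tail, _PS00014))


def tm_compatible(
    tm_helices: tuple[tuple[int, int], ...] | list[tuple[int, int]],
    sp_present: bool,
    sp_cleavage_pos: int,
) -> bool:
    """Transmembrane criterion: no helix, or one helix inside the signal peptide.

    A single helix is compatible iff its start lies at or before the predicted
    cleavage position (the helix then overlaps the signal-peptide region and
    is the signal peptide itself misread as a membrane anchor).
    """
    if not sp_present and sp_cleavage_pos != 0:
        raise FormatError("sp_cleavage_pos must be 0 when sp_present is false")
    helices = list(tm_helices)
    if len(helices) == 0:
        return True
    if len(helices) == 1:
        start, _ = helices[0]
        return start <= sp_cleavage_pos
    return False


def wolfpsort_extracellular(wolfpsort_top: str) -> bool:
    """True iff "extr" is the top-ranked compartment (ties at rank 1 count).

    ``wolfpsort_top`` is the ranked "compartment score" string, e.g.
    ``"extr 20, cyto 3"``.
    """
    pairs = []
    for chunk in str(wolfpsort_top).split(","):
        bits = chunk.split()
        if len(bits) != 2:
            continue
        pairs.append((bits[0], float(bits[1])))
    if not pairs:
        return False
    top_score = max(score for _, score in pairs)
    return any(label == "extr" and score == top_score for label, score in pairs)


def decide_secreted(
    evidence: EvidenceRecord,
    protein: ProteinRecord,
    config: PredictConfig = PredictConfig(),
) -> SecretionDecision:
    """Apply the combined five-way rule to one protein.

    All five sub-criteria are evaluated and recorded even when an earlier one
    already fails; ``secreted`` is their conjunction.
    """
    if evidence.protein_id != protein.protein_id:
        raise ValueError(
            f"evidence is for {evidence.protein_id!r}, sequence for {protein.protein_id!r}"
        )
    reasons = RuleOutcomes(
        sp_present=evidence.sp_present,
        tm_ok=tm_compatible(
            evidence.tm_helices, evidence.sp_present, evidence.sp_cleavage_pos
        ),
        targetp_ok=evidence.targetp_loc == "S",
        wolfpsort_ok=wolfpsort_extracellular(evidence.wolfpsort_top),
        kdel_ok=not scan_cterm_retention(protein.sequence, config.kdel_mode),
    )
    secreted = reasons.all_pass()
    decision = SecretionDecision(
        protein_id=protein.protein_id,
        secreted=secreted,
        reasons=reasons,
        ssp=secreted and protein.length < config.ssp_threshold,
    )
    return decision


def flag_ssp(decision: SecretionDecision, length: int, threshold: int = 300) -> bool:
    """SSP rule: secreted and strictly shorter than the threshold (precursor length)."""
    if threshold < 1:
        raise ConfigError("SSP threshold must be >= 1")
    return decision.secreted and length < threshold


def predict_secretome(
    proteins: list[ProteinRecord],
    evidence: list[EvidenceRecord],
    config: PredictConfig = PredictConfig(),
) -> list[SecretionDecision]:
    """Run the decision rule over a proteome; one decision per protein.

    Proteins without evidence raise — callers are expected to have merged or
    generated complete evidence first.
    """
    by_id = {e.protein_id: e for e in evidence}
    decisions = []
    for protein in proteins:
        ev = by_id.get(protein.protein_id)
        if ev is None:
            raise FormatError(f"no evidence record for protein {protein.protein_id!r}")
        decisions.append(decide_secreted(ev, protein, config))
    return decisions


# ---------------------------------------------------------------------------
# Surrogate predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateConfig:
    """Tunables of the built-in heuristic evidence predictor."""

    n_region_window: int = 5  # K/R required within the first residues
    h_region_min: int = 8  # consecutive hydrophobic residues
    sp_search_window: int = 30  # signal peptide confined to the N-terminus
    cleavage_search_limit: int = 45
    tm_window: int = 19
    tm_hydropathy_cutoff: float = 1.6
    kdel_mode: str = "ps00014"


def _find_hydrophobic_run(sequence: str, start: int, stop: int, min_len: int) -> tuple[int, int] | None:
    """First run of >= min_len hydrophobic residues beginning in [start, stop)."""
    run_start = None
    for i in range(start, min(len(sequence), stop + min_len)):
        if sequence[i] in HYDROPHOBIC:
            if run_start is None:
                run_start = i
            if i - run_start + 1 >= min_len and run_start < stop:
                # extend to the full run
                j = i
                while j + 1 < len(sequence) and sequence[j + 1] in HYDROPHOBIC:
                    j += 1
                return run_start, j
        else:
            run_start = None
    return None


def surrogate_predict(
    protein: ProteinRecord, config: SurrogateConfig = SurrogateConfig()
) -> EvidenceRecord:
    """Deterministic heuristic stand-in for the external predictors.

    Calls a signal peptide when the N-terminus shows a positively charged
    n-region (>=1 K/R in the first five residues), a hydrophobic h-region
    (>= 8 consecutive residues from {A,I,L,M,F,V,W}) within the first 30
    residues, and a small-residue cleavage context (small residues at -3 and
    -1). Transmembrane helices come from 19-residue Kyte-Doolittle windows
    above a hydropathy cutoff, outside the predicted signal. This heuristic
    is NOT equivalent to the published tools; it exists so the pipeline can
    run self-contained on demo and synthetic data.
    """
    seq = protein.sequence
    sp_present = False
    cleavage = 0

    has_n_region = any(res in "KR" for res in seq[: config.n_region_window])
    h_run = None
    if has_n_region:
        h_run = _find_hydrophobic_run(
            seq, 1, config.sp_search_window, config.h_region_min
        )
    if h_run is not None:
        # cleavage context: small residues at -3 and -1. Alanine is both
        # hydrophobic and small, so scan from the minimal h-region length
        # rather than the end of the full hydrophobic run, which may extend
        # into the cleavage context itself.
        scan_from = h_run[0] + config.h_region_min
        for i in range(scan_from, min(len(seq) - 2, config.cleavage_search_limit)):
            if seq[i] in SMALL_RESIDUES and seq[i + 2] in SMALL_RESIDUES:
                sp_present = True
                cleavage = i + 3  # 1-based last residue of the signal peptide
                break

    helices: list[tuple[int, int]] = []
    window = config.tm_window
    if len(seq) >= window:
        scores = [KYTE_DOOLITTLE.get(res, 0.0) for res in seq]
        above: list[bool] = []
        total = sum(scores[:window])
        above.append(total / window > config.tm_hydropathy_cutoff)
        for i in range(1, len(seq) - window + 1):
            total += scores[i + window - 1] - scores[i - 1]
            above.append(total / window > config.tm_hydropathy_cutoff)
        start = None
        for i, flag in enumerate(above + [False]):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                helix = (start + 1, i - 1 + window)  # 1-based inclusive
                if helix[0] > cleavage:  # ignore windows inside the signal
                    helices.append(helix)
                start = None

    kdel = scan_cterm_retention(seq, config.kdel_mode)
    return EvidenceRecord(
        protein_id=protein.protein_id,
        sp_present=sp_present,
        sp_cleavage_pos=cleavage,
        sp_dscore=0.7 if sp_present else 0.1,
        tm_helices=tuple(helices),
        targetp_loc="S" if sp_present else "O",
        wolfpsort_top="extr 20, cyto 3" if sp_present else "cyto 20, extr 3",
        kdel_cterm=kdel,
    )
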
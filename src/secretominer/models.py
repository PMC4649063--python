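"""Core domain types shared across the pipeline.

All records are plain dataclasses; tabular I/O lives in :mod:`secretominer.registry_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Closed set of lifestyle labels accepted in a species registry.
LIFESTYLES = frozenset({
    "Ectomycorrhizal",
    "White rot",
    "Brown rot",
    "Litter decayers",
    "Pathogen",
    "Orchid symbiont",
    "Ericoid symbiont",
    "Endophyte",
    "Mycoparasitic",
    "Yeast",
})

#: Amino-acid alphabet accepted in protein sequences (20 standard residues + X).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class SecretominerError(Exception):
    """Base class for all package errors."""


class ConfigError(SecretominerError):
    """Invalid configuration value (CLI exit code 2)."""


class FormatError(SecretominerError):
    """Malformed input file (CLI exit code 3)."""


class StageError(SecretominerError):
    """A pipeline stage failed (CLI exit code 4)."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One row of the species registry: binomial name, lifestyle, phylum, family."""

    name: str
    lifestyle: str
    phylum: str
    family: str

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise FormatError(
                f"unknown lifestyle {self.lifestyle!r} for species {self.name!r}; "
                f"allowed: {', '.join(sorted(LIFESTYLES))}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and source species."""

    protein_id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"protein {self.protein_id!r} contains invalid residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EvidenceRecord:
    """Merged per-protein outputs of the four localization predictors.

    ``sp_cleavage_pos`` is the 1-based position of the last signal-peptide
    residue (0 when no signal peptide is predicted). ``tm_helices`` are
    1-based inclusive intervals. ``wolfpsort_top`` keeps the ranked
    "compartment score" string so rank-1 ties remain visible to the
    decision rule.
    """

    protein_id: str
    sp_present: bool
    sp_cleavage_pos: int
    sp_dscore: float
    tm_helices: tuple[tuple[int, int], ...]
    targetp_loc: str  # one of S, M, O
    wolfpsort_top: str  # e.g. "extr 20, cyto 3"
    kdel_cterm: bool

    def __post_init__(self) -> None:
        if self.targetp_loc not in ("S", "M", "O"):
            raise FormatError(
                f"protein {self.protein_id!r}: targetp_loc must be S, M or O, "
                f"got {self.targetp_loc!r}"
            )
        if not self.sp_present and self.sp_cleavage_pos != 0:
            raise FormatError(
                f"protein {self.protein_id!r}: sp_cleavage_pos must be 0 when "
                "sp_present is false"
            )
        for start, end in self.tm_helices:
            if not (1 <= start <= end):
                raise FormatError(
                    f"protein {self.protein_id!r}: invalid TM interval ({start}, {end})"
                )


@dataclass(frozen=True)
class ReferenceHit:
    """One similarity-search hit of a protein against a reference database."""

    protein_id: str
    database: str  # CAZy, MEROPS, LED or PFAM
    subject_label: str
    evalue: float
    bitscore: float

    DATABASES = ("CAZy", "MEROPS", "LED", "PFAM")

    def __post_init__(self) -> None:
        if self.database not in self.DATABASES:
            raise FormatError(
                f"hit for {self.protein_id!r}: unknown database {self.database!r}"
            )
        if self.evalue < 0:
            raise FormatError(f"hit for {self.protein_id!r}: negative e-value")


@dataclass(frozen=True)
class RuleOutcomes:
    """The five sub-decisions of the secretion rule, in evaluation order."""

    sp_present: bool
    tm_ok: bool
    targetp_ok: bool
    wolfpsort_ok: bool
    kdel_ok: bool

    def as_items(self) -> list[tuple[str, bool]]:
        return [
            ("sp_present", self.sp_present),
            ("tm_ok", self.tm_ok),
            ("targetp_ok", self.targetp_ok),
            ("wolfpsort_ok", self.wolfpsort_ok),
            ("kdel_ok", self.kdel_ok),
        ]

    def all_pass(self) -> bool:
        return (
            self.sp_present
            and self.tm_ok
            and self.targetp_ok
            and self.wolfpsort_ok
            and self.kdel_ok
        )


@dataclass(frozen=True)
class SecretionDecision:
    """Outcome of the combined secretion rule for one protein."""

    protein_id: str
    secreted: bool
    reasons: RuleOutcomes
    ssp: bool

    def __post_init__(self) -> None:
        if self.secreted != self.reasons.all_pass():
            raise ValueError(
                f"protein {self.protein_id!r}: secreted flag inconsistent with reasons"
            )
        if self.ssp and not self.secreted:
            raise ValueError(f"protein {self.protein_id!r}: ssp implies secreted")


@dataclass
class SecretomeAnnotation:
    """Functional annotation of one secreted protein."""

    protein_id: str
    species: str = ""
    category: str = "Other"  # CAZyme, Protease, Lipase, SSP or Other
    ssp: bool = False
    cazy_family: str | None = None
    merops_family: str | None = None
    protease_type: str = "unassigned"  # endo, exo or unassigned
    lipase_class: str | None = None  # GX or GGGX
    lipase_subfamily: str | None = None
    pfam_domains: tuple[str, ...] = ()
    cys_percent: float = 0.0
    kr_rich_regions: tuple[tuple[int, int], ...] = ()
    nls_predicted: bool = False

    def __post_init__(self) -> None:
        if self.protease_type != "unassigned" and self.merops_family is None:
            raise ValueError(
                f"protein {self.protein_id!r}: protease_type set without merops_family"
            )
        if self.lipase_subfamily is not None and self.lipase_class is None:
            raise ValueError(
                f"protein {self.protein_id!r}: lipase_subfamily set without lipase_class"
            )


@dataclass
class SSPCluster:
    """A cluster of small-secreted proteins.

    ``members`` are (protein_id, species) pairs; the representative is the
    founding (longest) member. For clusters loaded from the packaged
    published table only membership is known, so ``representative`` may be
    empty and ``length_range`` carries the printed min/max lengths.
    """

    cluster_id: int
    representative: str
    members: list[tuple[str, str]]
    length_range: tuple[int, int] = (0, 0)
    pfam_label: str = "None"

    @property
    def member_species(self) -> set[str]:
        return {species for _, species in self.members}

    @property
    def n_species(self) -> int:
        return len(self.member_species)


@dataclass(frozen=True)
class IdentityResult:
    """Pairwise global-alignment identity between two sequences."""

    query: str
    subject: str
    identity: float
    aligned_matches: int
    denominator: int


@dataclass(frozen=True)
class LifestyleProfile:
    """Lifestyle composition of an SSP cluster under a grouping scheme."""

    cluster_id: int
    lifestyles: frozenset[str]
    region: tuple[str, ...]
    specificity: str  # ECM_only, shared_ECM_saprotroph, saprotroph_only, other


@dataclass(frozen=True)
class EnrichmentResult:
    """One PFAM-domain over-representation test for one lifestyle."""

    lifestyle: str
    pfam: str
    a: int  # in lifestyle, has domain
    b: int  # in lifestyle, lacks domain
    c: int  # elsewhere, has domain
    d: int  # elsewhere, lacks domain
    p_value: float
    adjusted_p: float
    enriched: bool
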
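"""Seed-controlled generator of synthetic multi-species proteomes.

The generator plants a known ground truth — which proteins are secreted,
which are SSPs, which belong to cross-species SSP families at a controlled
identity level — and emits evidence tables that reflect that truth exactly,
so every pipeline stage can be tested end to end without external data or
licensed predictors.

Secreted proteins receive a generated classical signal peptide (positively
charged n-region, 8-12 residue hydrophobic h-region, A-X-A cleavage
context). Decoy classes exercise each rejection rule: proteins with 1-7
planted transmembrane helices, and signal-peptide-bearing proteins with a
C-terminal KDEL. Planting is exact (deterministic rounding) by default so
counts are sharp; a Bernoulli sampling mode exists for statistical tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    AMINO_ACIDS,
    ConfigError,
    EvidenceRecord,
    ProteinRecord,
    ReferenceHit,
    SpeciesRecord,
)
from .prediction import scan_cterm_retention

HYDROPHOBIC_CORE = "AILMFV"  # helix/h-region residues (strongly hydrophobic)

#: Default lifestyle cycle for synthetic species.
_DEFAULT_LIFESTYLE_CYCLE = (
    "Ectomycorrhizal",
    "White rot",
    "Brown rot",
    "Litter decayers",
)

#: Default lifestyle patterns for planted SSP families (cycled).
_DEFAULT_FAMILY_PATTERNS = (
    frozenset({"Ectomycorrhizal"}),
    frozenset({"Ectomycorrhizal", "White rot", "Brown rot"}),
    frozenset({"White rot", "Brown rot", "Litter decayers"}),
    frozenset({"Ectomycorrhizal", "White rot", "Brown rot", "Litter decayers"}),
)

#: Reference-database label vocabularies for planted category hits.
CAZY_LABELS = ("GH5", "GH16", "GH18", "GH61", "GH3", "GH25")
MEROPS_LABELS = ("A01", "M36", "S53", "S28", "S08", "S09", "M28")
LED_LABELS = (
    "GGGX.carboxylesterase",
    "GGGX.Candida-rugosa-lipase-like",
    "GX.thioesterase",
    "GX.lysophospholipase",
    "GX.filamentous-fungal-lipase",
)
#: Default PFAM vocabulary with background per-protein occurrence rates.
DEFAULT_PFAM_RATES = {
    "PF00082": 0.06,
    "PF00026": 0.05,
    "PF01183": 0.04,
    "PF07249": 0.03,
    "PF10342": 0.03,
    "PF00160": 0.04,
    "PF03443": 0.05,
    "PF01185": 0.03,
    "PF00135": 0.04,
    "PF00704": 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generator; one integer seed drives everything."""

    seed: int = 0
    n_species: int = 6
    lifestyle_assignment: dict[str, str] | None = None
    proteome_size: int = 500
    secreted_fraction: float = 0.08
    ssp_fraction_of_secreted: float = 0.5
    tm_protein_fraction: float = 0.12
    kdel_fraction_of_secreted: float = 0.05
    sp_overlap_helix_fraction: float = 0.1
    n_planted_families: int = 4
    family_identity: float = 0.85  # target expected pairwise identity
    family_lifestyle_patterns: tuple[frozenset[str], ...] | None = None
    domain_enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    # reference-hit planting (fractions of each secretome)
    cazyme_fraction: float = 0.20
    protease_fraction: float = 0.10
    lipase_fraction: float = 0.04
    pfam_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PFAM_RATES))
    background_freqs: str = "uniform"  # or "robinson"
    exact_planting: bool = True
    ssp_length: tuple[int, int] = (60, 299)
    large_secreted_length: tuple[int, int] = (300, 700)
    background_length: tuple[int, int] = (100, 600)

    def validate(self) -> None:
        for name in (
            "secreted_fraction",
            "ssp_fraction_of_secreted",
            "tm_protein_fraction",
            "kdel_fraction_of_secreted",
            "sp_overlap_helix_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not 0 < self.family_identity <= 1:
            raise ConfigError("family_identity must be in (0, 1]")
        # exclusive classes: secreted, KDEL decoys (counted off the secreted
        # quota) and TM decoys must fit in the proteome
        budget = self.secreted_fraction * (1 + self.kdel_fraction_of_secreted) + (
            self.tm_protein_fraction
        )
        if budget > 1:
            raise ConfigError(
                "secreted, KDEL and TM fractions exceed the proteome "
                f"(total {budget:.3f} > 1)"
            )


# Robinson & Robinson-style amino-acid background frequencies.
_ROBINSON = {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0226, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0225, "F": 0.0385, "P": 0.0520,
    "S": 0.0712, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0645,
}


def _background_probs(mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.full(20, 1 / 20)
    if mode == "robinson":
        probs = np.array([_ROBINSON[a] for a in AMINO_ACIDS])
        return probs / probs.sum()
    raise ConfigError(f"unknown background frequency mode {mode!r}")


def _random_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def make_signal_peptide(rng: np.random.Generator) -> str:
    """Classical signal peptide: M, charged n-region, h-region, A-X-A c-region.

    The last residue returned is the final signal-peptide residue (cleavage
    occurs after it).
    """
    n_region = "M" + "".join(rng.choice(list("KR"), size=int(rng.integers(1, 3))))
    h_len = int(rng.integers(8, 13))
    h_region = "".join(rng.choice(list(HYDROPHOBIC_CORE), size=h_len))
    x = AMINO_ACIDS[int(rng.integers(20))]
    c_region = "A" + x + "A"
    return n_region + h_region + c_region


def mutate(
    sequence: str, rng: np.random.Generator, per_site_rate: float, start: int = 0
) -> str:
    """Substitute residues independently at ``per_site_rate`` from ``start`` on.

    Substitutions always change the residue (uniform over the 19 others).
    """
    out = list(sequence)
    for i in range(start, len(out)):
        if rng.random() < per_site_rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[int(rng.integers(19))]
    return "".join(out)


def ancestor_identity_for_pairwise(pairwise: float) -> float:
    """Per-member identity to the ancestor giving an expected pairwise identity.

    Under independent uniform substitution at rate 1-t per member, two
    members match at a site with probability t^2 + (1-t)^2/19; this inverts
    that relation.
    """
    if not 0 < pairwise <= 1:
        raise ConfigError("pairwise identity must be in (0, 1]")
    if pairwise == 1.0:
        return 1.0
    a = 20.0 / 19.0
    b = -2.0 / 19.0
    c = 1.0 / 19.0 - pairwise
    t = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(min(t, 1.0))


@dataclass
class PlantedFamily:
    """Ground truth for one planted SSP family."""

    family_id: int
    members: list[ProteinRecord]
    ancestor: str
    target_identity: float  # per-member identity to the ancestor
    lifestyles: frozenset[str] = frozenset()


def plant_ssp_family(
    ancestor_length: int,
    n_members: int,
    species_set: list[str],
    target_identity: float,
    seed: int,
    one_per_species: bool = True,
) -> PlantedFamily:
    """Diverge ``n_members`` copies of one random ancestor to a target identity.

    ``target_identity`` is each member's expected identity to the ancestor;
    expected pairwise identity between members is approximately
    ``target_identity**2 + (1 - target_identity)**2 / 19``.
    """
    if not 0 < target_identity <= 1:
        raise ConfigError("target_identity must be in (0, 1]")
    if ancestor_length >= 300:
        raise ConfigError("SSP family ancestors must be shorter than 300 residues")
    if one_per_species and n_members > len(species_set):
        raise ConfigError(
            f"cannot place {n_members} members one-per-species across "
            f"{len(species_set)} species"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = _background_probs("uniform")
    ancestor = _random_sequence(rng, ancestor_length, probs)
    rate = 1.0 - target_identity
    members = []
    for i in range(n_members):
        species = species_set[i % len(species_set)]
        seq = mutate(ancestor, rng, rate)
        members.append(
            ProteinRecord(protein_id=f"fam{seed}_m{i:02d}", sequence=seq, species=species)
        )
    return PlantedFamily(
        family_id=seed,
        members=members,
        ancestor=ancestor,
        target_identity=target_identity,
    )


@dataclass
class GroundTruth:
    """Planted per-protein and per-family truth of a synthetic dataset."""

    secreted: dict[str, bool] = field(default_factory=dict)
    ssp: dict[str, bool] = field(default_factory=dict)
    family_of: dict[str, int | None] = field(default_factory=dict)
    families: dict[int, PlantedFamily] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)  # filled by hit planting

    def secreted_ids(self) -> set[str]:
        return {pid for pid, flag in self.secreted.items() if flag}

    def ssp_ids(self) -> set[str]:
        return {pid for pid, flag in self.ssp.items() if flag}


@dataclass
class SyntheticDataset:
    """A generated multi-species proteome with evidence and ground truth."""

    config: SimulationConfig
    species: list[SpeciesRecord]
    proteins: list[ProteinRecord]
    evidence: list[EvidenceRecord]
    truth: GroundTruth

    def ssp_records(self) -> list[ProteinRecord]:
        ids = self.truth.ssp_ids()
        return [p for p in self.proteins if p.protein_id in ids]

    def write(self, outdir: str | Path) -> None:
        from . import registry_io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        registry_io.write_species_registry(self.species, outdir / "species.tsv")
        for sp in self.species:
            safe = sp.name.replace(" ", "_")
            registry_io.write_fasta(
                [p for p in self.proteins if p.species == sp.name],
                outdir / f"{safe}.fasta",
            )
        registry_io.write_evidence_table(self.evidence, outdir / "evidence.tsv")
        import pandas as pd

        rows = [
            (
                p.protein_id,
                p.species,
                self.truth.secreted[p.protein_id],
                self.truth.ssp[p.protein_id],
                self.truth.family_of[p.protein_id]
                if self.truth.family_of[p.protein_id] is not None
                else "",
                self.truth.category.get(p.protein_id, ""),
            )
            for p in self.proteins
        ]
        pd.DataFrame(
            rows,
            columns=["protein_id", "species", "secreted", "ssp", "family_id", "category"],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _count(fraction: float, total: int, exact: bool, rng: np.random.Generator) -> int:
    if exact:
        return round(fraction * total)
    return int(rng.binomial(total, fraction))


def _strip_retention_tail(sequence: str) -> str:
    """Ensure a sequence carries no C-terminal ER-retention motif (PS00014)."""
    if scan_cterm_retention(sequence, "ps00014"):
        return sequence[:-1] + "G"
    return sequence


def generate_proteome(config: SimulationConfig) -> SyntheticDataset:
    """Generate species, proteomes, ground-truth evidence and planted families.

    All randomness flows from ``config.seed`` through per-species spawned
    streams, so regeneration with the same config is byte-identical.
    """
    config.validate()
    # species roster
    if config.lifestyle_assignment is None:
        assignment = {
            f"Simulatus species{i + 1:02d}": _DEFAULT_LIFESTYLE_CYCLE[
                i % len(_DEFAULT_LIFESTYLE_CYCLE)
            ]
            for i in range(config.n_species)
        }
    else:
        assignment = dict(config.lifestyle_assignment)
    species = [
        SpeciesRecord(name, lifestyle, "Basidiomycota", "Simulated")
        for name, lifestyle in sorted(assignment.items())
    ]

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(species) + 1)
    family_rng = np.random.default_rng(streams[-1])
    probs = _background_probs(config.background_freqs)

    # --- plant families first so SSP quotas can absorb them -----------------
    patterns = (
        config.family_lifestyle_patterns
        if config.family_lifestyle_patterns is not None
        else _DEFAULT_FAMILY_PATTERNS
    )
    anc_identity = ancestor_identity_for_pairwise(config.family_identity)
    mature_rate = 1.0 - anc_identity
    families: dict[int, PlantedFamily] = {}
    members_per_species: dict[str, list[tuple[int, str]]] = {s.name: [] for s in species}
    for fam_id in range(config.n_planted_families):
        pattern = patterns[fam_id % len(patterns)]
        hosts = [s.name for s in species if s.lifestyle in pattern]
        if not hosts:
            raise ConfigError(
                f"planted family {fam_id}: no species with lifestyles {sorted(pattern)}"
            )
        sp = make_signal_peptide(family_rng)
        mature_len = int(family_rng.integers(80, 280 - len(sp)))
        ancestor = sp + _random_sequence(family_rng, mature_len, probs)
        members = []
        for i, host in enumerate(hosts):
            seq = mutate(ancestor, family_rng, mature_rate, start=len(sp))
            seq = _strip_retention_tail(seq)
            members_per_species[host].append((fam_id, seq))
            members.append(ProteinRecord(f"pending_fam{fam_id}_{i}", seq, host))
        families[fam_id] = PlantedFamily(
            family_id=fam_id,
            members=members,  # placeholder ids, rewritten below
            ancestor=ancestor,
            target_identity=anc_identity,
            lifestyles=frozenset(pattern),
        )
        families[fam_id].members = []

    # --- per-species proteomes ----------------------------------------------
    truth = GroundTruth()
    proteins: list[ProteinRecord] = []
    evidence: list[EvidenceRecord] = []
    for sp_record, stream in zip(species, streams):
        rng = np.random.default_rng(stream)
        name = sp_record.name
        tag = name.replace(" ", "_")
        n = config.proteome_size
        n_secreted = _count(config.secreted_fraction, n, config.exact_planting, rng)
        n_ssp = _count(
            config.ssp_fraction_of_secreted, n_secreted, config.exact_planting, rng
        )
        n_kdel = _count(
            config.kdel_fraction_of_secreted, n_secreted, config.exact_planting, rng
        )
        n_tm = _count(config.tm_protein_fraction, n, config.exact_planting, rng)
        planted_members = members_per_species[name]
        if len(planted_members) > n_ssp:
            raise ConfigError(
                f"species {name}: {len(planted_members)} family members exceed "
                f"the SSP quota of {n_ssp}"
            )
        n_background = n - n_secreted - n_kdel - n_tm
        if n_background < 0:
            raise ConfigError(f"species {name}: planted classes exceed proteome size")

        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{tag}|p{counter:05d}"

        def add(protein: ProteinRecord, ev: EvidenceRecord, secreted: bool, ssp: bool, fam: int | None) -> None:
            proteins.append(protein)
            evidence.append(ev)
            truth.secreted[protein.protein_id] = secreted
            truth.ssp[protein.protein_id] = ssp
            truth.family_of[protein.protein_id] = fam

        # secreted proteins: family members first, then free SSPs, then large
        for slot in range(n_secreted):
            pid = next_id()
            fam_id: int | None = None
            if slot < len(planted_members):
                fam_id, seq = planted_members[slot]
                cleavage = _cleavage_of(seq)
            elif slot < n_ssp:
                sp_seq = make_signal_peptide(rng)
                mature = int(rng.integers(*config.ssp_length)) - len(sp_seq)
                mature = max(mature, 10)
                seq = _strip_retention_tail(sp_seq + _random_sequence(rng, mature, probs))
                cleavage = len(sp_seq)
            else:
                sp_seq = make_signal_peptide(rng)
                mature = int(rng.integers(*config.large_secreted_length)) - len(sp_seq)
                seq = _strip_retention_tail(sp_seq + _random_sequence(rng, mature, probs))
                cleavage = len(sp_seq)
            helices: tuple[tuple[int, int], ...] = ()
            if rng.random() < config.sp_overlap_helix_fraction:
                helices = ((2, min(2 + 18, len(seq))),)  # inside the signal peptide
            protein = ProteinRecord(pid, seq, name)
            ev = EvidenceRecord(
                protein_id=pid,
                sp_present=True,
                sp_cleavage_pos=cleavage,
                sp_dscore=float(rng.uniform(0.5, 0.9)),
                tm_helices=helices,
                targetp_loc="S",
                wolfpsort_top="extr 20, cyto 3",
                kdel_cterm=False,
            )
            add(protein, ev, True, len(seq) < 300, fam_id)
            if fam_id is not None:
                families[fam_id].members.append(protein)

        # KDEL decoys: signal peptide + ER-retention tail
        for _ in range(n_kdel):
            pid = next_id()
            sp_seq = make_signal_peptide(rng)
            mature = int(rng.integers(*config.ssp_length)) - len(sp_seq)
            seq = sp_seq + _random_sequence(rng, max(mature, 10), probs) + "KDEL"
            protein = ProteinRecord(pid, seq, name)
            ev = EvidenceRecord(
                protein_id=pid,
                sp_present=True,
                sp_cleavage_pos=len(sp_seq),
                sp_dscore=float(rng.uniform(0.5, 0.9)),
                tm_helices=(),
                targetp_loc="S",
                wolfpsort_top="extr 20, cyto 3",
                kdel_cterm=True,
            )
            add(protein, ev, False, False, None)

        # transmembrane decoys: 1-7 planted helices, no signal peptide
        for _ in range(n_tm):
            pid = next_id()
            length = int(rng.integers(*config.background_length))
            n_helices = int(rng.integers(1, 8))
            seq, helices = _plant_helices(rng, length, n_helices, probs)
            protein = ProteinRecord(pid, seq, name)
            ev = EvidenceRecord(
                protein_id=pid,
                sp_present=False,
                sp_cleavage_pos=0,
                sp_dscore=float(rng.uniform(0.0, 0.35)),
                tm_helices=helices,
                targetp_loc="O",
                wolfpsort_top="plas 14, cyto 6",
                kdel_cterm=scan_cterm_retention(seq, "ps00014"),
            )
            add(protein, ev, False, False, None)

        # plain intracellular background
        for _ in range(n_background):
            pid = next_id()
            seq = _random_sequence(rng, int(rng.integers(*config.background_length)), probs)
            protein = ProteinRecord(pid, seq, name)
            ev = EvidenceRecord(
                protein_id=pid,
                sp_present=False,
                sp_cleavage_pos=0,
                sp_dscore=float(rng.uniform(0.0, 0.35)),
                tm_helices=(),
                targetp_loc="M" if rng.random() < 0.15 else "O",
                wolfpsort_top="cyto 20, extr 1",
                kdel_cterm=scan_cterm_retention(seq, "ps00014"),
            )
            add(protein, ev, False, False, None)

    truth.families = families
    return SyntheticDataset(
        config=config,
        species=species,
        proteins=proteins,
        evidence=evidence,
        truth=truth,
    )


def _cleavage_of(seq: str) -> int:
    """Recover the c-region end of a generated signal peptide (A-X-A ending)."""
    # generated SPs are M + 1-2 K/R + 8-12 hydrophobics + A-X-A
    for i in range(10, min(len(seq), 20)):
        if seq[i] == "A" and seq[i - 2] == "A":
            return i + 1
    raise ValueError("sequence does not start with a generated signal peptide")


def _plant_helices(
    rng: np.random.Generator, length: int, n_helices: int, probs: np.ndarray
) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Random sequence with ``n_helices`` hydrophobic stretches at known coords."""
    helix_len = 21
    spacing = 12
    needed = n_helices * (helix_len + spacing) + spacing
    length = max(length, needed)
    seq = list(_random_sequence(rng, length, probs))
    helices = []
    pos = spacing
    for _ in range(n_helices):
        core = rng.choice(list(HYDROPHOBIC_CORE), size=helix_len)
        seq[pos : pos + helix_len] = core
        helices.append((pos + 1, pos + helix_len))  # 1-based inclusive
        pos += helix_len + spacing
    return "".join(seq), tuple(helices)


# ---------------------------------------------------------------------------
# Reference hit tables
# ---------------------------------------------------------------------------

def generate_hit_tables(
    dataset: SyntheticDataset,
    domain_enrichment: dict[tuple[str, str], float] | None = None,
    seed: int | None = None,
) -> list[ReferenceHit]:
    """Plant reference-database hits consistent with the dataset's truth.

    Per species, deterministic fractions of the secreted set receive a best
    hit in CAZy, MEROPS or LED (recorded in ``truth.category``); every
    secreted protein then draws PFAM domains at the configured background
    rates times any (lifestyle, domain) enrichment multiplier.
    """
    config = dataset.config
    if domain_enrichment is None:
        domain_enrichment = config.domain_enrichment
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lifestyle_of = {s.name: s.lifestyle for s in dataset.species}
    dataset.truth.category = {}  # reflects the most recent hit planting only
    hits: list[ReferenceHit] = []
    for sp in dataset.species:
        secreted = [
            p
            for p in dataset.proteins
            if p.species == sp.name and dataset.truth.secreted[p.protein_id]
        ]
        n_caz = round(config.cazyme_fraction * len(secreted))
        n_pro = round(config.protease_fraction * len(secreted))
        n_lip = round(config.lipase_fraction * len(secreted))
        if n_caz + n_pro + n_lip > len(secreted):
            raise ConfigError("category fractions exceed the secretome")
        order = rng.permutation(len(secreted))
        assignments = (
            [("CAZy", CAZY_LABELS)] * n_caz
            + [("MEROPS", MEROPS_LABELS)] * n_pro
            + [("LED", LED_LABELS)] * n_lip
        )
        for idx, (db, labels) in zip(order, assignments):
            protein = secreted[idx]
            label = labels[int(rng.integers(len(labels)))]
            evalue = 10.0 ** -float(rng.uniform(8, 40))
            hits.append(
                ReferenceHit(protein.protein_id, db, label, evalue, float(rng.uniform(60, 300)))
            )
            dataset.truth.category[protein.protein_id] = {
                "CAZy": "CAZyme",
                "MEROPS": "Protease",
                "LED": "Lipase",
            }[db]
        lifestyle = lifestyle_of[sp.name]
        for protein in secreted:
            for domain, base_rate in config.pfam_rates.items():
                rate = base_rate * domain_enrichment.get((lifestyle, domain), 1.0)
                if rng.random() < min(rate, 1.0):
                    hits.append(
                        ReferenceHit(
                            protein.protein_id,
                            "PFAM",
                            domain,
                            10.0 ** -float(rng.uniform(6, 30)),
                            float(rng.uniform(40, 200)),
                        )
                    )
    return hits
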
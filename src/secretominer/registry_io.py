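"""Readers and writers for every external format the pipeline touches.

Covers protein FASTA, the species registry, the short-output dialects of the
four localization predictors, reference hit tables, plain-TSV exchange of
evidence/decision tables, and the packaged fixtures (species registry and the
published SSP cluster table).
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    EvidenceRecord,
    FormatError,
    ProteinRecord,
    ReferenceHit,
    SSPCluster,
    SpeciesRecord,
)

logger = logging.getLogger(__name__)

_DATA = resources.files("secretominer") / "data"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the protein id;
    sequences are upper-cased and trailing ``*`` stop characters stripped.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        # pre-scan so format errors carry a line number
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first FASTA header"
                    )
                break
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq, species=species))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (one line per sequence)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqs, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# Species registry
# ---------------------------------------------------------------------------

def load_species_registry(path: str | Path | None = None) -> list[SpeciesRecord]:
    """Load a species registry TSV (default: the packaged 49-species table).

    Required columns: name, lifestyle, phylum, family. Duplicate names and
    lifestyle labels outside the closed set are rejected.
    """
    if path is None:
        source = _DATA / "species_registry.tsv"
        frame = pd.read_csv(source.open(), sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "lifestyle", "phylum", "family"} - set(frame.columns)
    if missing:
        raise FormatError(f"species registry missing columns: {sorted(missing)}")
    if frame["name"].duplicated().any():
        dupes = frame.loc[frame["name"].duplicated(), "name"].tolist()
        raise FormatError(f"duplicate species names in registry: {dupes}")
    return [
        SpeciesRecord(row["name"], row["lifestyle"], row["phylum"], row["family"])
        for _, row in frame.iterrows()
    ]


def registry_frame(registry: Iterable[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.name, s.lifestyle, s.phylum, s.family) for s in registry],
        columns=["name", "lifestyle", "phylum", "family"],
    )


def write_species_registry(registry: Iterable[SpeciesRecord], path: str | Path) -> None:
    registry_frame(registry).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged SSP cluster table
# ---------------------------------------------------------------------------

def load_abbreviation_map() -> dict[str, str]:
    """Explicit abbreviation -> registry-name map for the cluster fixture."""
    source = _DATA / "species_abbreviations.tsv"
    frame = pd.read_csv(source.open(), sep="\t", comment="#")
    return dict(zip(frame["abbreviation"], frame["name"]))


def load_cluster_fixture(
    registry: list[SpeciesRecord] | None = None,
) -> list[SSPCluster]:
    """Load the packaged published SSP cluster table (membership only).

    Member species abbreviations are expanded to full registry names via the
    packaged abbreviation map; unresolvable abbreviations raise, naming the
    offending abbreviation. The printed species count is checked against the
    expanded member list.
    """
    if registry is None:
        registry = load_species_registry()
    names = {s.name for s in registry}
    abbrev = load_abbreviation_map()
    source = _DATA / "ssp_clusters.tsv"
    # keep_default_na=False so the printed PFAM label "None" survives as text
    frame = pd.read_csv(source.open(), sep="\t", comment="#", keep_default_na=False)
    clusters: list[SSPCluster] = []
    for _, row in frame.iterrows():
        members: list[tuple[str, str]] = []
        for token in str(row["members"]).split(";"):
            token = token.strip()
            full = abbrev.get(token)
            if full is None or full not in names:
                raise FormatError(
                    f"cluster {row['cluster_id']}: member abbreviation {token!r} "
                    "does not resolve to a registry species"
                )
            members.append((f"{full}|cluster{row['cluster_id']}", full))
        cluster = SSPCluster(
            cluster_id=int(row["cluster_id"]),
            representative="",
            members=members,
            length_range=(int(row["length_min"]), int(row["length_max"])),
            pfam_label=str(row["pfam"]),
        )
        if cluster.n_species != int(row["n_species"]):
            raise FormatError(
                f"cluster {row['cluster_id']}: printed species count "
                f"{row['n_species']} != expanded count {cluster.n_species}"
            )
        clusters.append(cluster)
    return clusters


# ---------------------------------------------------------------------------
# Predictor-output dialects
# ---------------------------------------------------------------------------

_TOPOLOGY_RE = re.compile(r"(\d+)-(\d+)")


def parse_signalp(path: str | Path) -> dict[str, tuple[bool, int, float]]:
    """Parse SignalP 4.1 *short* output.

    Columns: name, Cmax, pos, Ymax, pos, Smax, pos, Smean, D, ?, Dcutoff,
    network. The ``?`` column is the Y/N signal-peptide call; the position
    printed for Ymax is the first mature residue, so the last signal-peptide
    residue stored here is that position minus one.
    """
    out: dict[str, tuple[bool, int, float]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 10:
            raise FormatError(f"{path}:{lineno}: unparseable SignalP line")
        try:
            name = fields[0]
            ymax_pos = int(fields[4])
            dscore = float(fields[8])
            present = fields[9] == "Y"
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable SignalP line") from exc
        out[name] = (present, ymax_pos - 1 if present else 0, dscore)
    return out


def parse_tmhmm(path: str | Path) -> dict[str, tuple[tuple[int, int], ...]]:
    """Parse TMHMM *short* one-line-per-protein output.

    Example: ``prot1 len=500 ExpAA=43.1 First60=0.0 PredHel=2
    Topology=i7-29o44-66i`` -> helices ((7, 29), (44, 66)).
    """
    out: dict[str, tuple[tuple[int, int], ...]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        kv = {}
        for token in fields[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                kv[key] = value
        if "PredHel" not in kv or "Topology" not in kv:
            raise FormatError(f"{path}:{lineno}: unparseable TMHMM line")
        helices = tuple(
            (int(a), int(b)) for a, b in _TOPOLOGY_RE.findall(kv["Topology"])
        )
        if len(helices) != int(kv["PredHel"]):
            raise FormatError(
                f"{path}:{lineno}: PredHel={kv['PredHel']} disagrees with topology"
            )
        out[fields[0]] = helices
    return out


def parse_targetp(path: str | Path) -> dict[str, str]:
    """Parse a TargetP v1.1 (non-plant) table: Name Len mTP SP other Loc RC.

    Localization is mapped onto {S, M, O}; the table's ``_`` ("other")
    prints as O. Ruler lines of dashes are skipped.
    """
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        if set(line.strip()) <= {"-"}:
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: unparseable TargetP line")
        loc = fields[5]
        if loc in ("S", "M"):
            out[fields[0]] = loc
        elif loc in ("_", "O", "*"):
            out[fields[0]] = "O"
        else:
            raise FormatError(f"{path}:{lineno}: unknown TargetP location {loc!r}")
    return out


def parse_wolfpsort(path: str | Path) -> dict[str, str]:
    """Parse WoLF PSORT one-line output: ``name comp1 score1, comp2 score2...``.

    The full ranked string is kept so rank-1 score ties stay visible.
    """
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        name, _, rest = line.strip().partition(" ")
        rest = rest.strip()
        if not rest:
            raise FormatError(f"{path}:{lineno}: unparseable WoLF PSORT line")
        for pair in rest.split(","):
            bits = pair.split()
            if len(bits) != 2:
                raise FormatError(f"{path}:{lineno}: unparseable WoLF PSORT line")
            try:
                float(bits[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable WoLF PSORT score {bits[1]!r}"
                ) from exc
        out[name] = rest
    return out


def _data_lines(path: str | Path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def parse_predictor_outputs(
    signalp_path: str | Path,
    tmhmm_path: str | Path,
    targetp_path: str | Path,
    wolfpsort_path: str | Path,
) -> list[EvidenceRecord]:
    """Merge the four predictor outputs into one evidence record per protein.

    Only proteins present in all four files are kept; the rest are logged and
    excluded. C-terminal ER-retention is not reported by any of these tools,
    so ``kdel_cterm`` is left False here and the decision rule rescans the
    sequence itself.
    """
    sp = parse_signalp(signalp_path)
    tm = parse_tmhmm(tmhmm_path)
    tp = parse_targetp(targetp_path)
    wp = parse_wolfpsort(wolfpsort_path)
    common = set(sp) & set(tm) & set(tp) & set(wp)
    if not common:
        raise FormatError("no protein ids shared by all four predictor outputs")
    dropped = (set(sp) | set(tm) | set(tp) | set(wp)) - common
    for pid in sorted(dropped):
        logger.warning("protein %s missing from at least one predictor output; excluded", pid)
    records = []
    for pid in sorted(common):
        present, cleave, dscore = sp[pid]
        records.append(
            EvidenceRecord(
                protein_id=pid,
                sp_present=present,
                sp_cleavage_pos=cleave,
                sp_dscore=dscore,
                tm_helices=tm[pid],
                targetp_loc=tp[pid],
                wolfpsort_top=wp[pid],
                kdel_cterm=False,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Evidence / hit-table TSV exchange format
# ---------------------------------------------------------------------------

def _helices_to_str(helices: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{a}-{b}" for a, b in helices)


def _helices_from_str(text: str) -> tuple[tuple[int, int], ...]:
    text = str(text).strip()
    if not text or text in ("nan", "-"):
        return ()
    return tuple((int(a), int(b)) for a, b in _TOPOLOGY_RE.findall(text))


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (
                r.protein_id,
                r.sp_present,
                r.sp_cleavage_pos,
                r.sp_dscore,
                _helices_to_str(r.tm_helices),
                r.targetp_loc,
                r.wolfpsort_top,
                r.kdel_cterm,
            )
            for r in records
        ],
        columns=[
            "protein_id",
            "sp_present",
            "sp_cleavage_pos",
            "sp_dscore",
            "tm_helices",
            "targetp_loc",
            "wolfpsort_top",
            "kdel_cterm",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    frame = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False,
        float_precision="round_trip",
    )
    records = []
    for _, row in frame.iterrows():
        records.append(
            EvidenceRecord(
                protein_id=str(row["protein_id"]),
                sp_present=_to_bool(row["sp_present"]),
                sp_cleavage_pos=int(row["sp_cleavage_pos"]),
                sp_dscore=float(row["sp_dscore"]),
                tm_helices=_helices_from_str(row["tm_helices"]),
                targetp_loc=str(row["targetp_loc"]),
                wolfpsort_top=str(row["wolfpsort_top"]),
                kdel_cterm=_to_bool(row["kdel_cterm"]),
            )
        )
    return records


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n", ""):
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def write_hit_table(hits: Iterable[ReferenceHit], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(h.protein_id, h.database, h.subject_label, h.evalue, h.bitscore) for h in hits],
        columns=["protein_id", "database", "subject_label", "evalue", "bitscore"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[ReferenceHit]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        ReferenceHit(
            protein_id=str(row["protein_id"]),
            database=str(row["database"]),
            subject_label=str(row["subject_label"]),
            evalue=float(row["evalue"]),
            bitscore=float(row["bitscore"]),
        )
        for _, row in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# Config data files
# ---------------------------------------------------------------------------

def load_protease_types(path: str | Path | None = None) -> dict[str, str]:
    """MEROPS family -> endo/exo mapping (default: packaged table)."""
    if path is None:
        source = _DATA / "protease_types.tsv"
        frame = pd.read_csv(source.open(), sep="\t", comment="#")
    else:
        frame = pd.read_csv(path, sep="\t", comment="#")
    mapping = dict(zip(frame["family"], frame["type"]))
    bad = set(mapping.values()) - {"endo", "exo"}
    if bad:
        raise FormatError(f"protease types must be endo or exo, got {sorted(bad)}")
    return mapping


def load_lifestyle_groups(path: str | Path | None = None) -> dict[str, str]:
    """Lifestyle -> comparison-group mapping (default: packaged YAML)."""
    if path is None:
        text = (_DATA / "lifestyle_groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise FormatError("lifestyle grouping file must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


# ---------------------------------------------------------------------------
# Generic '#'-headed TSV output
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"# {key}: {value}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_table_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta
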
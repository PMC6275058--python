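"""Domain types and file I/O for the P450 census pipeline.

All genomic coordinates are 1-based inclusive (GenBank convention).
Tabular I/O is UTF-8 TSV with a header row and no quoting dialects, so
files round-trip bit-exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "CYP_NAME_RE",
    "FormatError",
    "ValidationError",
    "JoinError",
    "ProteinGeneRecord",
    "ReferenceEntry",
    "NomenclatureThresholds",
    "BgcCluster",
    "AssociationRecord",
    "parse_cyp_name",
    "family_of_p450_name",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "read_gene_table_gff3",
    "write_gene_table",
    "read_reference_library",
    "read_bgc_table",
    "write_bgc_table",
    "read_association_table",
    "write_association_table",
    "load_published_associations",
]

#: The 20 proteinogenic amino acids plus X (unknown residue).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: CYP nomenclature grammar: CYP + family number + subfamily letter(s) +
#: optional member number (e.g. CYP107K1, CYP1179A4, CYP102A).
CYP_NAME_RE = re.compile(r"^CYP([0-9]+)([A-Z]+)([0-9]+)?$")

#: Placeholder names allocated to novel families (official numbers require
#: the nomenclature committee): prefix + counter + subfamily + member.
_NOVEL_NAME_RE = re.compile(r"^(CYP[A-Z]+[0-9]+)([A-Z]+)([0-9]+)?$")

REPLICON_KINDS = ("chromosome", "plasmid")
STRANDS = ("+", "-")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class JoinError(ValueError):
    """Identifiers fail to join across input tables."""


def parse_cyp_name(name: str) -> tuple[str, str, int | None]:
    """Split a CYP name into (family, subfamily letters, member number).

    >>> parse_cyp_name("CYP107K1")
    ('CYP107', 'K', 1)
    """
    m = CYP_NAME_RE.match(name)
    if m is None:
        raise ValidationError(f"not a valid CYP name: {name!r}")
    member = int(m.group(3)) if m.group(3) is not None else None
    return "CYP" + m.group(1), m.group(2), member


def family_of_p450_name(name: str) -> str:
    """Family of a P450 name, accepting novel-family placeholder names."""
    m = CYP_NAME_RE.match(name)
    if m is not None:
        return "CYP" + m.group(1)
    m = _NOVEL_NAME_RE.match(name)
    if m is not None:
        return m.group(1)
    raise ValidationError(f"cannot derive a family from P450 name {name!r}")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValidationError("sequence must be non-empty")
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValidationError(
            f"sequence contains non-amino-acid characters: {sorted(bad)}"
        )


@dataclass(frozen=True)
class ProteinGeneRecord:
    """One protein with its genomic coordinates and replicon kind."""

    protein_id: str
    species_code: str
    replicon_id: str
    replicon_kind: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.replicon_kind not in REPLICON_KINDS:
            raise ValidationError(
                f"unknown replicon kind {self.replicon_kind!r} "
                f"(expected one of {REPLICON_KINDS})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        _check_sequence(self.sequence)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReferenceEntry:
    """A named P450 used as a nomenclature anchor."""

    cyp_name: str
    sequence: str
    family: str = ""
    subfamily_letter: str = ""

    def __post_init__(self) -> None:
        family, sub, _member = parse_cyp_name(self.cyp_name)
        if not self.family:
            object.__setattr__(self, "family", family)
        elif self.family != family:
            raise ValidationError(
                f"family {self.family!r} inconsistent with name {self.cyp_name!r}"
            )
        if not self.subfamily_letter:
            object.__setattr__(self, "subfamily_letter", sub)
        elif self.subfamily_letter != sub:
            raise ValidationError(
                f"subfamily {self.subfamily_letter!r} inconsistent with "
                f"name {self.cyp_name!r}"
            )
        _check_sequence(self.sequence)

    @property
    def member_number(self) -> int | None:
        return parse_cyp_name(self.cyp_name)[2]


@dataclass(frozen=True)
class NomenclatureThresholds:
    """Family/subfamily identity cut-offs (strict inequalities).

    Sequences sharing >40% identity belong to the same family and >55%
    to the same subfamily; identity at or below a threshold falls to the
    lower tier.
    """

    family_min_identity: float = 40.0
    subfamily_min_identity: float = 55.0

    def __post_init__(self) -> None:
        if not (0 < self.family_min_identity < self.subfamily_min_identity <= 100):
            raise ValidationError(
                "thresholds must satisfy 0 < family < subfamily <= 100, got "
                f"{self.family_min_identity}/{self.subfamily_min_identity}"
            )


@dataclass(frozen=True)
class BgcCluster:
    """One predicted secondary-metabolite biosynthetic gene cluster.

    ``cluster_type`` is a hyphen-joined string of standard anti-SMASH type
    tokens (e.g. "Nrps-Transatpks-Otherks") and is treated as opaque.
    """

    species_code: str
    replicon_id: str
    replicon_kind: str
    cluster_number: int
    cluster_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.replicon_kind not in REPLICON_KINDS:
            raise ValidationError(
                f"unknown replicon kind {self.replicon_kind!r}"
            )
        if self.cluster_number < 1:
            raise ValidationError("cluster_number must be >= 1")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.species_code, self.replicon_id, self.cluster_number)


@dataclass(frozen=True)
class AssociationRecord:
    """One P450-in-cluster association (species, cluster, type, P450 name).

    ``replicon_kind`` is recorded when the association was computed from
    coordinates and is None when loaded from a bare association table.
    """

    species_name: str
    cluster_number: int
    cluster_type: str
    p450_name: str
    replicon_kind: str | None = None

    def __post_init__(self) -> None:
        if self.cluster_number < 1:
            raise ValidationError("cluster_number must be >= 1")
        family_of_p450_name(self.p450_name)  # raises if unparseable


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ordered (id, uppercase sequence) pairs.

    Wrapping is irrelevant; sequence data before the first header is a
    format error reported with its line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: sequence data before first "
                    "FASTA header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# gene-coordinate tables
# --------------------------------------------------------------------------

_GENE_COLUMNS = [
    "protein_id",
    "species_code",
    "replicon_id",
    "replicon_kind",
    "start",
    "end",
    "strand",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _join_sequences(
    rows: list[dict], fasta_records: Sequence[tuple[str, str]], path
) -> list[ProteinGeneRecord]:
    seq_by_id = dict(fasta_records)
    missing = [r["protein_id"] for r in rows if r["protein_id"] not in seq_by_id]
    if missing:
        raise JoinError(
            f"{path}: protein ids absent from FASTA: {sorted(missing)}"
        )
    out = []
    seen: set[tuple[str, str]] = set()
    for r in rows:
        key = (r["species_code"], r["protein_id"])
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate protein_id {r['protein_id']!r} within "
                f"species {r['species_code']!r}"
            )
        seen.add(key)
        out.append(ProteinGeneRecord(sequence=seq_by_id[r["protein_id"]], **r))
    return out


def read_gene_table(
    path: str | Path, fasta_records: Sequence[tuple[str, str]]
) -> list[ProteinGeneRecord]:
    """Read a TSV of gene coordinates, joining sequences from FASTA records.

    Required columns: protein_id, species_code, replicon_id, replicon_kind,
    start, end, strand.
    """
    df = _read_tsv(path, _GENE_COLUMNS)
    rows = []
    for rec in df.to_dict("records"):
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer coordinate: {exc}")
        rows.append(
            dict(
                protein_id=rec["protein_id"],
                species_code=rec["species_code"],
                replicon_id=rec["replicon_id"],
                replicon_kind=rec["replicon_kind"],
                start=start,
                end=end,
                strand=rec["strand"],
            )
        )
    return _join_sequences(rows, fasta_records, path)


_GFF_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def read_gene_table_gff3(
    path: str | Path,
    fasta_records: Sequence[tuple[str, str]],
    species_code: str,
    replicon_kinds: dict[str, str] | None = None,
) -> list[ProteinGeneRecord]:
    """Read CDS features from a GFF3 file as gene-coordinate records.

    The ``protein_id`` attribute (fallback: ID) names each protein;
    ``replicon_kinds`` maps seqid to chromosome/plasmid (default chromosome).
    """
    replicon_kinds = replicon_kinds or {}
    rows = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            pid = attr.get("protein_id") or attr.get("ID")
            if pid is None:
                raise FormatError(
                    f"{path}: line {lineno}: CDS without protein_id/ID attribute"
                )
            rows.append(
                dict(
                    protein_id=pid,
                    species_code=species_code,
                    replicon_id=seqid,
                    replicon_kind=replicon_kinds.get(seqid, "chromosome"),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return _join_sequences(rows, fasta_records, path)


def write_gene_table(records: Iterable[ProteinGeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "species_code": r.species_code,
                "replicon_id": r.replicon_id,
                "replicon_kind": r.replicon_kind,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
            }
            for r in records
        ],
        columns=_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# reference library
# --------------------------------------------------------------------------


def read_reference_library(path: str | Path) -> list[ReferenceEntry]:
    """Read a FASTA of named P450s; each header must begin with a CYP name."""
    entries = []
    seen: set[str] = set()
    for header, seq in read_fasta(path):
        name = header.split()[0]
        try:
            parse_cyp_name(name)
        except ValidationError:
            raise FormatError(
                f"{path}: header {header!r} does not begin with a parseable "
                "CYP name"
            )
        if name in seen:
            raise ValidationError(f"{path}: duplicate CYP name {name!r}")
        seen.add(name)
        entries.append(ReferenceEntry(cyp_name=name, sequence=seq))
    return entries


# --------------------------------------------------------------------------
# BGC cluster and association tables
# --------------------------------------------------------------------------

_BGC_COLUMNS = [
    "species_code",
    "replicon_id",
    "replicon_kind",
    "cluster_number",
    "cluster_type",
    "start",
    "end",
]


def read_bgc_table(path: str | Path) -> list[BgcCluster]:
    """Read a TSV of predicted BGC regions (anti-SMASH region shape)."""
    df = _read_tsv(path, _BGC_COLUMNS)
    clusters = []
    seen: set[tuple[str, str, int]] = set()
    for rec in df.to_dict("records"):
        cluster = BgcCluster(
            species_code=rec["species_code"],
            replicon_id=rec["replicon_id"],
            replicon_kind=rec["replicon_kind"],
            cluster_number=int(rec["cluster_number"]),
            cluster_type=rec["cluster_type"],
            start=int(rec["start"]),
            end=int(rec["end"]),
        )
        if cluster.key in seen:
            raise ValidationError(
                f"{path}: duplicate cluster {cluster.key}"
            )
        seen.add(cluster.key)
        clusters.append(cluster)
    return clusters


def write_bgc_table(clusters: Iterable[BgcCluster], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species_code": c.species_code,
                "replicon_id": c.replicon_id,
                "replicon_kind": c.replicon_kind,
                "cluster_number": c.cluster_number,
                "cluster_type": c.cluster_type,
                "start": c.start,
                "end": c.end,
            }
            for c in clusters
        ],
        columns=_BGC_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_ASSOC_COLUMNS = ["species_name", "cluster_number", "cluster_type", "p450_name"]


def read_association_table(path: str | Path) -> list[AssociationRecord]:
    """Read a TSV of P450-in-cluster associations."""
    df = _read_tsv(path, _ASSOC_COLUMNS)
    records = []
    for rec in df.to_dict("records"):
        records.append(
            AssociationRecord(
                species_name=rec["species_name"],
                cluster_number=int(rec["cluster_number"]),
                cluster_type=rec["cluster_type"],
                p450_name=rec["p450_name"],
                replicon_kind=rec.get("replicon_kind") or None,
            )
        )
    return records


def write_association_table(
    records: Iterable[AssociationRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            {
                "species_name": r.species_name,
                "cluster_number": r.cluster_number,
                "cluster_type": r.cluster_type,
                "p450_name": r.p450_name,
            }
            for r in records
        ],
        columns=_ASSOC_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_published_associations() -> list[AssociationRecord]:
    """Load the packaged table of 112 published Bacillus P450-in-BGC rows."""
    ref = resources.files("cypcensus.data").joinpath("published_bgc_p450_associations.tsv")
    with resources.as_file(ref) as path:
        return read_association_table(path)
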
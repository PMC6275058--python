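"""Cross-referencing P450 genes with biosynthetic gene clusters.

A P450 gene is associated with a BGC when its coordinates fall inside the
cluster's interval on the same replicon (1-based inclusive arithmetic).
The default policy counts any overlap, mirroring how predicted cluster
regions include boundary-spanning genes; full containment is available
for strictness studies.  A gene overlapping two clusters contributes one
association per cluster (no deduplication), so association totals count
gene-cluster pairs; distinct-gene counts are reported alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .census import round_half_up
from .classifier import Assignment
from .seq_io import (
    AssociationRecord,
    BgcCluster,
    JoinError,
    ProteinGeneRecord,
    ValidationError,
    family_of_p450_name,
)

__all__ = [
    "OverlapPolicy",
    "AssociationSummary",
    "gene_in_cluster",
    "link_p450s_to_clusters",
    "summarize_associations",
    "BgcCensus",
    "bgc_census",
    "fraction_of_cypome",
]


@dataclass(frozen=True)
class OverlapPolicy:
    """How much of a gene must lie inside a cluster to count as a member."""

    mode: str = "any_overlap"  # any_overlap | full_containment
    min_fraction: float = 0.0  # of gene length, under any_overlap

    def __post_init__(self) -> None:
        if self.mode not in ("any_overlap", "full_containment"):
            raise ValidationError(f"unknown overlap mode {self.mode!r}")
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValidationError("min_fraction must be in [0, 1]")


def gene_in_cluster(
    gene: ProteinGeneRecord,
    cluster: BgcCluster,
    policy: OverlapPolicy = OverlapPolicy(),
) -> bool:
    """Is this gene a member of this cluster under the overlap policy?

    Different species or replicon ids are never members (returns False,
    no error).
    """
    if (
        gene.species_code != cluster.species_code
        or gene.replicon_id != cluster.replicon_id
    ):
        return False
    if policy.mode == "full_containment":
        return cluster.start <= gene.start and gene.end <= cluster.end
    overlap = min(gene.end, cluster.end) - max(gene.start, cluster.start) + 1
    if overlap < 1:
        return False
    return overlap / gene.length_bp >= policy.min_fraction


def link_p450s_to_clusters(
    assignments: Sequence[Assignment],
    genes: Sequence[ProteinGeneRecord],
    clusters: Sequence[BgcCluster],
    policy: OverlapPolicy = OverlapPolicy(),
    species_names: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """One association per (P450 gene, cluster) pair passing the policy.

    Assignments are joined to coordinates by protein_id; a P450 without
    coordinates is an error.  ``species_names`` optionally maps species
    codes to display names.  Output is sorted by (species, cluster number,
    P450 name).
    """
    gene_by_id = {g.protein_id: g for g in genes}
    missing = sorted(
        a.protein_id for a in assignments if a.protein_id not in gene_by_id
    )
    if missing:
        raise JoinError(f"assignments without gene coordinates: {missing}")
    species_names = species_names or {}
    records = []
    for a in assignments:
        gene = gene_by_id[a.protein_id]
        for cluster in clusters:
            if gene_in_cluster(gene, cluster, policy):
                records.append(
                    AssociationRecord(
                        species_name=species_names.get(
                            gene.species_code, gene.species_code
                        ),
                        cluster_number=cluster.cluster_number,
                        cluster_type=cluster.cluster_type,
                        p450_name=a.assigned_name,
                        replicon_kind=cluster.replicon_kind,
                    )
                )
    records.sort(key=lambda r: (r.species_name, r.cluster_number, r.p450_name))
    return records


@dataclass(frozen=True)
class AssociationSummary:
    """Aggregate statistics over P450-in-BGC associations.

    ``per_family_percent`` carries one-decimal detail percentages;
    ``per_family_percent_headline`` the integer-rounded headline figures.
    Association counts are gene-cluster pairs; ``distinct_p450_genes``
    counts distinct (species, P450 name) pairs for transparency.
    """

    total_associations: int
    per_family_counts: Mapping[str, int]
    per_family_percent: Mapping[str, float]
    per_family_percent_headline: Mapping[str, int]
    distinct_species: int
    distinct_families: int
    distinct_p450_genes: int
    family_by_type: Mapping[tuple[str, str], int]
    replicon_split: Mapping[str, int]


def summarize_associations(
    records: Sequence[AssociationRecord],
) -> AssociationSummary:
    """Aggregate association records; an empty input gives an all-zero
    summary rather than an error."""
    total = len(records)
    fam_counts: Counter[str] = Counter()
    by_type: Counter[tuple[str, str]] = Counter()
    replicons: Counter[str] = Counter()
    for r in records:
        fam = family_of_p450_name(r.p450_name)
        fam_counts[fam] += 1
        by_type[(fam, r.cluster_type.strip().lower())] += 1
        if r.replicon_kind is not None:
            replicons[r.replicon_kind] += 1
    percent = {
        fam: round_half_up(100.0 * n / total, 1) for fam, n in fam_counts.items()
    }
    headline = {
        fam: int(round_half_up(100.0 * n / total, 0))
        for fam, n in fam_counts.items()
    }
    return AssociationSummary(
        total_associations=total,
        per_family_counts=dict(fam_counts),
        per_family_percent=percent,
        per_family_percent_headline=headline,
        distinct_species=len({r.species_name for r in records}),
        distinct_families=len(fam_counts),
        distinct_p450_genes=len({(r.species_name, r.p450_name) for r in records}),
        family_by_type=dict(by_type),
        replicon_split=dict(replicons),
    )


@dataclass(frozen=True)
class BgcCensus:
    """Per-species cluster counts and type sets stratified by replicon."""

    per_species_counts: Mapping[str, Mapping[str, int]]  # species -> kind -> n
    chromosome_types: frozenset[str]
    plasmid_types: frozenset[str]

    @property
    def shared_types(self) -> frozenset[str]:
        return self.chromosome_types & self.plasmid_types

    @property
    def chromosome_only_types(self) -> frozenset[str]:
        return self.chromosome_types - self.plasmid_types

    @property
    def plasmid_only_types(self) -> frozenset[str]:
        return self.plasmid_types - self.chromosome_types


def bgc_census(clusters: Sequence[BgcCluster]) -> BgcCensus:
    """Count clusters per species/replicon kind and compare type sets.

    Type strings are compared exactly (case-insensitively, trimmed) as
    opaque tokens; no ontology mapping.
    """
    per_species: dict[str, dict[str, int]] = {}
    chrom_types: set[str] = set()
    plasmid_types: set[str] = set()
    for c in clusters:
        kinds = per_species.setdefault(c.species_code, {"chromosome": 0, "plasmid": 0})
        kinds[c.replicon_kind] += 1
        token = c.cluster_type.strip().lower()
        if c.replicon_kind == "chromosome":
            chrom_types.add(token)
        else:
            plasmid_types.add(token)
    return BgcCensus(
        per_species_counts=per_species,
        chromosome_types=frozenset(chrom_types),
        plasmid_types=frozenset(plasmid_types),
    )


def fraction_of_cypome(
    summary: AssociationSummary | int, total_p450s: int
) -> int:
    """Share of the CYPome found inside BGCs, as an integer headline %."""
    if total_p450s <= 0:
        raise ValidationError("total_p450s must be positive")
    n = (
        summary.total_associations
        if isinstance(summary, AssociationSummary)
        else int(summary)
    )
    return int(round_half_up(100.0 * n / total_p450s, 0))
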
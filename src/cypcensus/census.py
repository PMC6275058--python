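"""Genus-level CYPome census statistics.

Covers per-species P450 counts, family/subfamily profiles, the diversity
percentage (number of P450 families as a percentage of the total P450
count), the presence/absence heatmap encoding (-3 = family present,
3 = absent) with Euclidean hierarchical clustering on both axes, and an
internal-consistency validator for reported census numbers.

Printed percentages are rounded half-up to one decimal, matching the
reporting granularity of published censuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .classifier import Assignment
from .seq_io import ValidationError

__all__ = [
    "round_half_up",
    "SpeciesCensus",
    "GenusCensus",
    "HeatmapMatrix",
    "build_census",
    "diversity_percentage",
    "family_percentages",
    "dominant_subfamily",
    "presence_matrix",
    "cluster_matrix",
    "linkage_to_newick",
    "write_heatmap",
    "ConsistencyReport",
    "validate_census",
]

PRESENT = -3
ABSENT = 3


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 2.25 -> 2.3 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpeciesCensus:
    """P450 tallies for one species."""

    species_code: str
    p450_count: int
    family_counts: Mapping[str, int]
    subfamily_counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        if sum(self.family_counts.values()) != self.p450_count:
            raise ValidationError(
                f"{self.species_code}: family counts do not sum to p450_count"
            )
        per_family: dict[str, int] = {}
        for (fam, _sub), n in self.subfamily_counts.items():
            per_family[fam] = per_family.get(fam, 0) + n
        if per_family != dict(self.family_counts):
            raise ValidationError(
                f"{self.species_code}: subfamily counts inconsistent with "
                "family counts"
            )


@dataclass(frozen=True)
class GenusCensus:
    """Census across all species, with global family/subfamily sets."""

    species: tuple[SpeciesCensus, ...]
    total_p450s: int
    family_set: frozenset[str]
    subfamily_set: frozenset[tuple[str, str]]

    @property
    def diversity_percent(self) -> float:
        if self.total_p450s == 0:
            raise ValidationError(
                "diversity percentage is undefined for an empty census"
            )
        return diversity_percentage(len(self.family_set), self.total_p450s)

    @property
    def total_families(self) -> int:
        return len(self.family_set)

    @property
    def total_subfamilies(self) -> int:
        return len(self.subfamily_set)


def build_census(
    assignments_by_species: Mapping[str, Sequence[Assignment]],
) -> GenusCensus:
    """Tally assignments per species; zero-P450 species are retained.

    Species without P450s still matter: they appear as all-absent columns
    in the presence/absence heatmap.
    """
    species = []
    families: set[str] = set()
    subfamilies: set[tuple[str, str]] = set()
    total = 0
    for code, assigns in assignments_by_species.items():
        fam_counts: dict[str, int] = {}
        sub_counts: dict[tuple[str, str], int] = {}
        for a in assigns:
            fam_counts[a.family] = fam_counts.get(a.family, 0) + 1
            key = (a.family, a.subfamily_label)
            sub_counts[key] = sub_counts.get(key, 0) + 1
            families.add(a.family)
            subfamilies.add(key)
        species.append(
            SpeciesCensus(
                species_code=code,
                p450_count=len(assigns),
                family_counts=fam_counts,
                subfamily_counts=sub_counts,
            )
        )
        total += len(assigns)
    return GenusCensus(
        species=tuple(species),
        total_p450s=total,
        family_set=frozenset(families),
        subfamily_set=frozenset(subfamilies),
    )


def diversity_percentage(n_families: int, n_p450s: int) -> float:
    """100 * families / total P450s, rounded half-up to one decimal."""
    if n_p450s <= 0:
        raise ValidationError("diversity percentage requires n_p450s > 0")
    return round_half_up(100.0 * n_families / n_p450s, 1)


def family_percentages(census: GenusCensus) -> list[tuple[str, int, float]]:
    """(family, count, percent-of-total) sorted by count desc, then name."""
    if census.total_p450s == 0:
        raise ValidationError("family percentages require a non-empty census")
    totals: dict[str, int] = {}
    for sp in census.species:
        for fam, n in sp.family_counts.items():
            totals[fam] = totals.get(fam, 0) + n
    rows = [
        (fam, n, round_half_up(100.0 * n / census.total_p450s, 1))
        for fam, n in totals.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def dominant_subfamily(census: GenusCensus, family: str) -> str:
    """Most populous subfamily of a family (ties: alphabetically first)."""
    totals: dict[str, int] = {}
    for sp in census.species:
        for (fam, sub), n in sp.subfamily_counts.items():
            if fam == family:
                totals[sub] = totals.get(sub, 0) + n
    if not totals:
        raise ValidationError(f"family {family!r} absent from census")
    return min(totals, key=lambda s: (-totals[s], s))


# --------------------------------------------------------------------------
# presence/absence heatmap
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatmapMatrix:
    """Family-by-species presence/absence matrix in the -3/3 encoding."""

    row_labels: tuple[str, ...]  # families
    col_labels: tuple[str, ...]  # species
    values: np.ndarray  # PRESENT (-3) or ABSENT (3)
    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def to_frame(self, ordered: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )
        if ordered:
            df = df.iloc[list(self.row_order), list(self.col_order)]
        return df


def presence_matrix(census: GenusCensus) -> HeatmapMatrix:
    """Encode family presence per species as -3 (present) / 3 (absent).

    Families are sorted by name; species keep census order.  Orders are
    identity permutations until :func:`cluster_matrix` is applied.
    """
    families = sorted(census.family_set)
    species = [sp.species_code for sp in census.species]
    if not families or not species:
        raise ValidationError("presence matrix requires >=1 family and species")
    values = np.full((len(families), len(species)), ABSENT, dtype=np.int64)
    for j, sp in enumerate(census.species):
        for i, fam in enumerate(families):
            if sp.family_counts.get(fam, 0) > 0:
                values[i, j] = PRESENT
    return HeatmapMatrix(
        row_labels=tuple(families),
        col_labels=tuple(species),
        values=values,
        row_order=tuple(range(len(families))),
        col_order=tuple(range(len(species))),
    )


def _axis_order(data: np.ndarray, method: str) -> tuple[tuple[int, ...], np.ndarray | None]:
    n = data.shape[0]
    if n < 2:
        return tuple(range(n)), None
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method=method)
    return tuple(int(i) for i in hierarchy.leaves_list(link)), link


def cluster_matrix(matrix: HeatmapMatrix, method: str = "average") -> HeatmapMatrix:
    """Cluster both axes (Euclidean distance, agglomerative linkage).

    Distances are computed on the -3/3 encoded values exactly as exported.
    Leaf order is deterministic (scipy's tie handling is input-order
    stable).  Single-row or single-column axes keep identity order.
    """
    if method not in ("single", "complete", "average"):
        raise ValidationError(f"unsupported linkage method {method!r}")
    row_order, row_link = _axis_order(matrix.values.astype(float), method)
    col_order, col_link = _axis_order(matrix.values.T.astype(float), method)
    return HeatmapMatrix(
        row_labels=matrix.row_labels,
        col_labels=matrix.col_labels,
        values=matrix.values,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def linkage_to_newick(link: np.ndarray | None, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    if link is None:
        if len(labels) != 1:
            raise ValidationError("no linkage for a multi-leaf axis")
        return f"{labels[0]};"
    tree = hierarchy.to_tree(link)

    def render(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"


def write_heatmap(matrix: HeatmapMatrix, out_dir: str | Path) -> None:
    """Export the matrix TSV, axis orders, and newick dendrograms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_frame(ordered=True).to_csv(
        out / "heatmap_matrix.tsv", sep="\t", index_label="family"
    )
    pd.Series([matrix.row_labels[i] for i in matrix.row_order]).to_csv(
        out / "heatmap_row_order.tsv", sep="\t", index=False, header=["family"]
    )
    pd.Series([matrix.col_labels[i] for i in matrix.col_order]).to_csv(
        out / "heatmap_col_order.tsv", sep="\t", index=False, header=["species"]
    )
    (out / "heatmap_rows.nwk").write_text(
        linkage_to_newick(matrix.row_linkage, matrix.row_labels) + "\n"
    )
    (out / "heatmap_cols.nwk").write_text(
        linkage_to_newick(matrix.col_linkage, matrix.col_labels) + "\n"
    )


# --------------------------------------------------------------------------
# consistency validation of reported census numbers
# --------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    """Discrepancies found between reported totals and their own breakdown."""

    discrepancies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def validate_census(
    reported_total: int,
    reported_species_with_p450s: int,
    count_distribution: Mapping[int, int],
    census: GenusCensus | None = None,
) -> ConsistencyReport:
    """Check a reported census for internal arithmetic consistency.

    ``count_distribution`` maps per-species P450 count -> number of
    species.  Verifies that the distribution sums to the reported total
    P450s and the reported number of P450-bearing species; optionally
    compares against a computed census.  Reports discrepancies, never
    raises.
    """
    report = ConsistencyReport()
    dist_p450s = sum(count * n for count, n in count_distribution.items())
    dist_species = sum(
        n for count, n in count_distribution.items() if count > 0
    )
    if dist_p450s != reported_total:
        report.discrepancies.append(
            f"count distribution sums to {dist_p450s} P450s but the "
            f"reported total is {reported_total}"
        )
    if dist_species != reported_species_with_p450s:
        report.discrepancies.append(
            f"count distribution covers {dist_species} species but "
            f"{reported_species_with_p450s} species were reported to carry "
            "P450s"
        )
    if census is not None:
        if census.total_p450s != reported_total:
            report.discrepancies.append(
                f"computed census has {census.total_p450s} P450s, "
                f"reported total is {reported_total}"
            )
        computed_species = sum(1 for sp in census.species if sp.p450_count > 0)
        if computed_species != reported_species_with_p450s:
            report.discrepancies.append(
                f"computed census has {computed_species} P450-bearing "
                f"species, reported {reported_species_with_p450s}"
            )
    return report


def write_census_tables(census: GenusCensus, out_dir: str | Path) -> None:
    """Write per-species counts, family profile and subfamily profile TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"species_code": sp.species_code, "p450_count": sp.p450_count}
            for sp in census.species
        ]
    ).to_csv(out / "species_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        family_percentages(census) if census.total_p450s else [],
        columns=["family", "count", "percent"],
    ).to_csv(out / "family_profile.tsv", sep="\t", index=False)
    sub_totals: dict[tuple[str, str], int] = {}
    for sp in census.species:
        for key, n in sp.subfamily_counts.items():
            sub_totals[key] = sub_totals.get(key, 0) + n
    pd.DataFrame(
        [
            {"family": fam, "subfamily": sub, "count": n}
            for (fam, sub), n in sorted(sub_totals.items())
        ],
        columns=["family", "subfamily", "count"],
    ).to_csv(out / "subfamily_profile.tsv", sep="\t", index=False)
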
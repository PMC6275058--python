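"""Synthetic genus generator with exact ground truth.

Emulates the inputs of a genus-wide CYPome census — a reference library
of named P450s, per-species proteomes with planted P450s at controlled
identity to chosen references, decoy proteins, gene coordinates on one or
two replicons, and BGC intervals — while recording the planted truth so
every pipeline stage can be checked without downloads.

Mutation is substitution-only (no indels): substituting exactly
k = round((1 - target) * L) positions, each to a different residue,
realizes an ungapped identity of (L - k)/L exactly, which the global
aligner recovers, so threshold tests are sharp.  Detector motif windows
are locked against substitution so planted P450s always stay detectable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detector import DEFAULT_EXXR_REGEX, DEFAULT_HEME_REGEX
from .seq_io import (
    AMINO_ACIDS,
    BgcCluster,
    NomenclatureThresholds,
    ProteinGeneRecord,
    ReferenceEntry,
    ValidationError,
    write_bgc_table,
    write_fasta,
    write_gene_table,
)

__all__ = [
    "HEME_MOTIF",
    "EXXR_MOTIF",
    "PlantedP450",
    "SyntheticTruth",
    "GenusDataset",
    "make_reference_library",
    "mutate_to_identity",
    "mutate_to_exact_identity",
    "make_genus",
    "write_genus",
]

#: Concrete motif instances planted at fixed offsets in every synthetic
#: P450 (both match the detector's default patterns).
HEME_MOTIF = "FGAGRHCLG"
EXXR_MOTIF = "EGLR"
_HEME_OFFSET_FROM_END = 60  # motif start, counted back from the C-terminus
_EXXR_OFFSET_FROM_END = 120

#: Synthetic family numbering starts high above real bacterial families.
_FAMILY_NUMBER_BASE = 9000

_CLUSTER_TYPES = (
    "Nrps",
    "Transatpks",
    "Transatpks-Nrps",
    "Nrps-Transatpks-Otherks",
    "Lantipeptide",
    "Bacteriocin",
    "Terpene",
    "Sactipeptide",
    "Arylpolyene",
    "Other",
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA[rng.integers(0, len(_AA), size=length)]).decode()


def _plant_motifs(seq: str) -> tuple[str, tuple[int, ...]]:
    """Overwrite fixed windows with the heme and ExxR motifs.

    Returns the motif-bearing sequence and the locked (0-based) positions.
    """
    length = len(seq)
    heme_at = length - _HEME_OFFSET_FROM_END
    exxr_at = length - _EXXR_OFFSET_FROM_END
    chars = list(seq)
    chars[exxr_at : exxr_at + len(EXXR_MOTIF)] = EXXR_MOTIF
    chars[heme_at : heme_at + len(HEME_MOTIF)] = HEME_MOTIF
    locked = tuple(range(exxr_at, exxr_at + len(EXXR_MOTIF))) + tuple(
        range(heme_at, heme_at + len(HEME_MOTIF))
    )
    return "".join(chars), locked


def locked_motif_positions(length: int) -> tuple[int, ...]:
    """0-based positions held fixed under mutation (the planted motifs)."""
    heme_at = length - _HEME_OFFSET_FROM_END
    exxr_at = length - _EXXR_OFFSET_FROM_END
    return tuple(range(exxr_at, exxr_at + len(EXXR_MOTIF))) + tuple(
        range(heme_at, heme_at + len(HEME_MOTIF))
    )


def mutate_to_identity(
    reference_seq: str,
    target_identity: float,
    seed: int | np.random.Generator,
    lock_positions: Sequence[int] = (),
) -> str:
    """Substitute exactly round((1-target)*L) unlocked positions.

    ``target_identity`` is a fraction in (0, 1].  Every substitution
    changes the residue, so the realized ungapped identity is (L-k)/L
    exactly; with no indels the global alignment recovers it.
    """
    if not (0 < target_identity <= 1):
        raise ValidationError("target identity must be in (0, 1]")
    length = len(reference_seq)
    k = round((1 - target_identity) * length)
    locked = set(lock_positions)
    unlocked = [i for i in range(length) if i not in locked]
    if k > len(unlocked):
        raise ValidationError(
            f"{k} substitutions requested but only {len(unlocked)} unlocked "
            "positions available"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    positions = rng.choice(len(unlocked), size=k, replace=False)
    chars = list(reference_seq)
    for idx in sorted(int(p) for p in positions):
        pos = unlocked[idx]
        alternatives = AMINO_ACIDS.replace(chars[pos], "")
        chars[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def mutate_to_exact_identity(
    reference_seq: str,
    target_identity: float,
    seed: int,
    lock_positions: Sequence[int] = (),
    max_attempts: int = 2000,
) -> str:
    """Substitution-only mutant whose *measured* global identity is exact.

    At low identity the optimal global alignment of a substitution-only
    mutant can include gaps and recover extra matches, so the realized
    identity drifts off (1-k/L).  This constructor draws deterministic
    variants (sub-streams of ``seed``) until the aligner reports exactly
    ``100 * target_identity`` percent, which is required for sharp
    threshold-boundary experiments.
    """
    from .classifier import percent_identity  # deferred: avoids cycle

    want = 100.0 * target_identity
    for attempt in range(max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        candidate = mutate_to_identity(
            reference_seq, target_identity, rng, lock_positions
        )
        if abs(percent_identity(candidate, reference_seq) - want) < 1e-9:
            return candidate
    raise ValidationError(
        f"no substitution-only mutant realized exactly {want}% identity "
        f"in {max_attempts} draws"
    )


def make_reference_library(
    n_families: int,
    subfamilies_per_family: int = 1,
    length: int = 400,
    seed: int = 0,
    max_cross_family_identity: float = 30.0,
    max_attempts: int = 50,
) -> list[ReferenceEntry]:
    """Random reference P450s: one base per family, one member per subfamily.

    Motifs are planted at fixed offsets; subfamily variants beyond "A" are
    50%-identity mutants of the family base.  Pairwise identity between
    family bases is verified to stay at or below
    ``max_cross_family_identity`` (offending bases are redrawn).
    """
    from .classifier import percent_identity  # deferred: avoids cycle at import

    if n_families < 1:
        raise ValidationError("n_families must be >= 1")
    if length < 300:
        raise ValidationError("reference length must be >= 300")
    rng = np.random.default_rng(seed)
    bases: list[str] = []
    for _fam in range(n_families):
        for _attempt in range(max_attempts):
            candidate, _locked = _plant_motifs(_random_protein(rng, length))
            if all(
                percent_identity(candidate, other) <= max_cross_family_identity
                for other in bases
            ):
                bases.append(candidate)
                break
        else:
            raise ValidationError(
                "could not draw sufficiently divergent family bases"
            )
    entries = []
    locked = locked_motif_positions(length)
    for fam_idx, base in enumerate(bases):
        family_number = _FAMILY_NUMBER_BASE + 1 + fam_idx
        for sub_idx in range(subfamilies_per_family):
            letter = chr(65 + sub_idx)
            seq = (
                base
                if sub_idx == 0
                else mutate_to_identity(base, 0.50, rng, locked)
            )
            entries.append(
                ReferenceEntry(cyp_name=f"CYP{family_number}{letter}1", sequence=seq)
            )
    return entries


# --------------------------------------------------------------------------
# genus generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedP450:
    """Ground truth for one planted P450."""

    true_family: str
    true_subfamily: str
    target_identity: float  # percent, to source_ref
    source_ref: str

    def expected_call(
        self, thresholds: NomenclatureThresholds = NomenclatureThresholds()
    ) -> str:
        """Expected classifier tier: known_subfamily | novel_subfamily |
        novel_family."""
        if self.target_identity > thresholds.subfamily_min_identity:
            return "known_subfamily"
        if self.target_identity > thresholds.family_min_identity:
            return "novel_subfamily"
        return "novel_family"


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed by protein id."""

    planted_assignments: dict[str, PlantedP450]
    planted_memberships: dict[str, list[tuple[str, str, int]]]  # cluster keys
    decoy_ids: frozenset[str]
    seed: int
    generator_params: dict = field(default_factory=dict)


@dataclass
class GenusDataset:
    """A full synthetic genus: proteomes, coordinates, clusters, truth."""

    proteomes: dict[str, list[tuple[str, str]]]  # species -> (id, seq)
    genes: list[ProteinGeneRecord]
    clusters: list[BgcCluster]
    library: list[ReferenceEntry]
    truth: SyntheticTruth


def _resolve_counts(
    spec_counts: int | Sequence[int] | Mapping[int, float],
    n_species: int,
    rng: np.random.Generator,
) -> list[int]:
    if isinstance(spec_counts, int):
        return [spec_counts] * n_species
    if isinstance(spec_counts, Mapping):
        counts = sorted(spec_counts)
        probs = np.array([spec_counts[c] for c in counts], dtype=float)
        probs = probs / probs.sum()
        return [int(c) for c in rng.choice(counts, size=n_species, p=probs)]
    counts = [int(c) for c in spec_counts]
    if len(counts) != n_species:
        raise ValidationError(
            f"per-species count list has {len(counts)} entries for "
            f"{n_species} species"
        )
    return counts


def _place_clusters(
    rng: np.random.Generator,
    species: str,
    replicon: str,
    kind: str,
    n_clusters: int,
    overlapping: bool,
) -> list[BgcCluster]:
    clusters = []
    cursor = 1
    for number in range(1, n_clusters + 1):
        gap = int(rng.integers(5_000, 50_000))
        size = int(rng.integers(10_000, 80_001))
        if overlapping and number > 1 and clusters:
            # overlap the tail of the previous cluster by half its span
            prev = clusters[-1]
            start = prev.start + (prev.end - prev.start) // 2
        else:
            start = cursor + gap
        end = start + size - 1
        clusters.append(
            BgcCluster(
                species_code=species,
                replicon_id=replicon,
                replicon_kind=kind,
                cluster_number=number,
                cluster_type=str(rng.choice(_CLUSTER_TYPES)),
                start=start,
                end=end,
            )
        )
        cursor = max(cursor, end + 1)
    return clusters


def make_genus(
    n_species: int = 10,
    p450s_per_species: int | Sequence[int] | Mapping[int, float] = 3,
    identity_levels: Sequence[float] = (70.0, 50.0, 25.0),
    clusters_per_species: int = 3,
    in_cluster_fraction: float = 0.5,
    plasmid_probability: float = 0.45,
    decoys_per_species: int = 5,
    library: Sequence[ReferenceEntry] | None = None,
    n_families: int = 5,
    subfamilies_per_family: int = 1,
    protein_length: int = 400,
    overlapping_clusters: bool = False,
    seed: int = 0,
) -> GenusDataset:
    """Generate a synthetic genus with planted P450s and BGC intervals.

    Each planted P450 derives from a random library reference at an
    identity level cycled from ``identity_levels``.  Exactly
    round(in_cluster_fraction * total planted) P450 genes are placed
    inside cluster intervals (chosen by a seeded permutation); the rest
    land outside every cluster.  Decoy proteins never contain the heme
    motif.  All outputs are pure functions of (parameters, seed).
    """
    import re

    rng = np.random.default_rng(seed)
    if library is None:
        library = make_reference_library(
            n_families, subfamilies_per_family, protein_length, seed=seed
        )
    locked = locked_motif_positions(protein_length)
    counts = _resolve_counts(p450s_per_species, n_species, rng)
    species_codes = [f"SYN{i:03d}" for i in range(1, n_species + 1)]

    # plan planted P450s first so in-cluster membership is a global draw
    planted: list[tuple[str, str, float, ReferenceEntry]] = []
    for code, n_p450 in zip(species_codes, counts):
        for i in range(n_p450):
            ref = library[int(rng.integers(0, len(library)))]
            level = float(identity_levels[i % len(identity_levels)])
            planted.append((f"{code}_p450_{i + 1}", code, level, ref))
    n_in_cluster = round(in_cluster_fraction * len(planted))
    in_cluster_ids = {
        planted[int(i)][0]
        for i in rng.permutation(len(planted))[:n_in_cluster]
    }

    proteomes: dict[str, list[tuple[str, str]]] = {c: [] for c in species_codes}
    genes: list[ProteinGeneRecord] = []
    clusters: list[BgcCluster] = []
    truth_assign: dict[str, PlantedP450] = {}
    memberships: dict[str, list[tuple[str, str, int]]] = {}
    decoy_ids: set[str] = set()
    heme_re = re.compile(DEFAULT_HEME_REGEX)

    by_species: dict[str, list[tuple[str, float, ReferenceEntry]]] = {
        c: [] for c in species_codes
    }
    for pid, code, level, ref in planted:
        by_species[code].append((pid, level, ref))

    for code in species_codes:
        chrom = f"{code}_chr"
        sp_clusters = _place_clusters(
            rng, code, chrom, "chromosome", clusters_per_species, overlapping_clusters
        )
        clusters.extend(sp_clusters)
        has_plasmid = rng.random() < plasmid_probability
        if has_plasmid:
            plasmid = f"{code}_p1"
            if rng.random() < 0.3:
                clusters.extend(
                    _place_clusters(rng, code, plasmid, "plasmid", 1, False)
                )
        # coordinates outside every cluster start well past the cluster zone
        outside_cursor = 2_000_000
        for pid, level, ref in by_species[code]:
            seq = mutate_to_identity(ref.sequence, level / 100.0, rng, locked)
            proteomes[code].append((pid, seq))
            gene_bp = 3 * len(seq)
            if pid in in_cluster_ids and sp_clusters:
                host = sp_clusters[int(rng.integers(0, len(sp_clusters)))]
                start = host.start + int(
                    rng.integers(0, host.end - host.start + 1 - gene_bp)
                )
                memberships[pid] = [host.key]
                if overlapping_clusters:
                    memberships[pid] = [
                        c.key
                        for c in sp_clusters
                        if min(start + gene_bp - 1, c.end) - max(start, c.start) >= 0
                    ]
            else:
                start = outside_cursor
                outside_cursor += gene_bp + int(rng.integers(500, 5_000))
                memberships[pid] = []
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                ProteinGeneRecord(
                    protein_id=pid,
                    species_code=code,
                    replicon_id=chrom,
                    replicon_kind="chromosome",
                    start=start,
                    end=start + gene_bp - 1,
                    strand=strand,
                    sequence=seq,
                )
            )
            truth_assign[pid] = PlantedP450(
                true_family=ref.family,
                true_subfamily=ref.subfamily_letter,
                target_identity=level,
                source_ref=ref.cyp_name,
            )
        for d in range(decoys_per_species):
            pid = f"{code}_decoy_{d + 1}"
            while True:
                seq = _random_protein(rng, int(rng.integers(150, 451)))
                if heme_re.search(seq) is None:
                    break
            proteomes[code].append((pid, seq))
            decoy_ids.add(pid)
            gene_bp = 3 * len(seq)
            on_plasmid = has_plasmid and rng.random() < 0.3
            replicon = f"{code}_p1" if on_plasmid else chrom
            start = outside_cursor
            outside_cursor += gene_bp + int(rng.integers(500, 5_000))
            genes.append(
                ProteinGeneRecord(
                    protein_id=pid,
                    species_code=code,
                    replicon_id=replicon,
                    replicon_kind="plasmid" if on_plasmid else "chromosome",
                    start=start if not on_plasmid else 1_000 + d * 5_000,
                    end=(start if not on_plasmid else 1_000 + d * 5_000)
                    + gene_bp
                    - 1,
                    strand="+",
                    sequence=seq,
                )
            )
    truth = SyntheticTruth(
        planted_assignments=truth_assign,
        planted_memberships=memberships,
        decoy_ids=frozenset(decoy_ids),
        seed=seed,
        generator_params=dict(
            n_species=n_species,
            p450s_per_species=str(p450s_per_species),
            identity_levels=list(identity_levels),
            clusters_per_species=clusters_per_species,
            in_cluster_fraction=in_cluster_fraction,
            plasmid_probability=plasmid_probability,
            decoys_per_species=decoys_per_species,
            n_families=n_families,
            subfamilies_per_family=subfamilies_per_family,
            protein_length=protein_length,
            overlapping_clusters=overlapping_clusters,
        ),
    )
    return GenusDataset(
        proteomes=proteomes,
        genes=genes,
        clusters=clusters,
        library=list(library),
        truth=truth,
    )


def write_genus(dataset: GenusDataset, out_dir: str | Path) -> None:
    """Write FASTA + TSV + truth JSON for a generated genus."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for code, records in dataset.proteomes.items():
        write_fasta(records, out / f"proteome_{code}.fasta")
    write_fasta(
        [(e.cyp_name, e.sequence) for e in dataset.library],
        out / "references.fasta",
    )
    write_gene_table(dataset.genes, out / "genes.tsv")
    write_bgc_table(dataset.clusters, out / "clusters.tsv")
    truth = dataset.truth
    payload = {
        "seed": truth.seed,
        "generator_params": truth.generator_params,
        "planted_assignments": {
            pid: dataclasses.asdict(p)
            for pid, p in sorted(truth.planted_assignments.items())
        },
        "planted_memberships": {
            pid: [list(k) for k in keys]
            for pid, keys in sorted(truth.planted_memberships.items())
        },
        "decoy_ids": sorted(truth.decoy_ids),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
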
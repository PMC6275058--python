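"""Family/subfamily assignment by global pairwise percent identity.

The nomenclature convention groups P450s sharing >40% amino-acid identity
into the same family and >55% into the same subfamily (strict
inequalities; identity at a threshold falls to the lower tier).  Identity
is measured on a Needleman-Wunsch/Gotoh global alignment with affine gap
penalties, and the denominator is the total number of alignment columns,
gaps included — the strictest and symmetric convention.

Score-optimal global alignments are generally not unique and co-optimal
alignments can disagree on identity.  To make percent identity a pure
function of its inputs, the aligner optimizes the lexicographic tuple
(score, identical columns, -alignment length): among score-optimal
alignments it reports the one with the most identical columns, breaking
remaining ties toward the shortest alignment.  End gaps are penalized; a
gap of length k costs open + (k-1)*extend.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .seq_io import (
    NomenclatureThresholds,
    ReferenceEntry,
    ValidationError,
    parse_cyp_name,
)

__all__ = [
    "AlignmentParams",
    "Assignment",
    "NovelNamer",
    "percent_identity",
    "align_stats",
    "classify",
    "classify_proteome",
]

logger = logging.getLogger(__name__)

_NEG = -(10**12)


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment recipe (EMBOSS-needle-style defaults)."""

    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "alignment_columns"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValidationError(
                f"require gap_open >= gap_extend >= 0, got "
                f"{self.gap_open}/{self.gap_extend}"
            )
        if self.identity_denominator != "alignment_columns":
            raise ValidationError(
                "identity_denominator must be 'alignment_columns'"
            )


@lru_cache(maxsize=8)
def _scoring(matrix_name: str) -> np.ndarray:
    """Doubled integer substitution matrix indexed by ord(residue)-65.

    Scores are stored at 2x scale so that half-point gap extensions stay
    in exact integer arithmetic.
    """
    mat = substitution_matrices.load(matrix_name)
    scores = np.full((26, 26), _NEG, dtype=np.int64)
    for a in mat.alphabet:
        if not a.isalpha():
            continue
        for b in mat.alphabet:
            if not b.isalpha():
                continue
            scores[ord(a) - 65, ord(b) - 65] = int(round(2 * mat[a][b]))
    return scores


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65


@njit(cache=True)
def _gotoh(a, b, scores, open2, ext2):  # pragma: no cover - jitted
    """Affine-gap global alignment maximizing (score, identities, -length).

    Three Gotoh states (diagonal, gap-in-b, gap-in-a), each carrying the
    lexicographically best (score2x, identical columns, columns) triple.
    Returns the triple for the best full alignment.
    """
    n, m = a.shape[0], b.shape[0]
    Ms = np.full((n + 1, m + 1), _NEG, np.int64)
    Mi = np.zeros((n + 1, m + 1), np.int64)
    Ml = np.zeros((n + 1, m + 1), np.int64)
    Xs = np.full((n + 1, m + 1), _NEG, np.int64)
    Xi = np.zeros((n + 1, m + 1), np.int64)
    Xl = np.zeros((n + 1, m + 1), np.int64)
    Ys = np.full((n + 1, m + 1), _NEG, np.int64)
    Yi = np.zeros((n + 1, m + 1), np.int64)
    Yl = np.zeros((n + 1, m + 1), np.int64)
    Ms[0, 0] = 0
    for i in range(1, n + 1):
        Xs[i, 0] = -(open2 + (i - 1) * ext2)
        Xl[i, 0] = i
    for j in range(1, m + 1):
        Ys[0, j] = -(open2 + (j - 1) * ext2)
        Yl[0, j] = j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            # diagonal state: consume ai and bj
            s = scores[ai, bj]
            eq = 1 if ai == bj else 0
            bs, bi, bl = Ms[i - 1, j - 1], Mi[i - 1, j - 1], Ml[i - 1, j - 1]
            cs, ci, cl = Xs[i - 1, j - 1], Xi[i - 1, j - 1], Xl[i - 1, j - 1]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            cs, ci, cl = Ys[i - 1, j - 1], Yi[i - 1, j - 1], Yl[i - 1, j - 1]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            Ms[i, j] = bs + s
            Mi[i, j] = bi + eq
            Ml[i, j] = bl + 1
            # gap in b: consume ai against a gap column
            bs, bi, bl = Ms[i - 1, j] - open2, Mi[i - 1, j], Ml[i - 1, j]
            cs, ci, cl = Xs[i - 1, j] - ext2, Xi[i - 1, j], Xl[i - 1, j]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            cs, ci, cl = Ys[i - 1, j] - open2, Yi[i - 1, j], Yl[i - 1, j]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            Xs[i, j] = bs
            Xi[i, j] = bi
            Xl[i, j] = bl + 1
            # gap in a: consume bj against a gap column
            bs, bi, bl = Ms[i, j - 1] - open2, Mi[i, j - 1], Ml[i, j - 1]
            cs, ci, cl = Ys[i, j - 1] - ext2, Yi[i, j - 1], Yl[i, j - 1]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            cs, ci, cl = Xs[i, j - 1] - open2, Xi[i, j - 1], Xl[i, j - 1]
            if cs > bs or (cs == bs and (ci > bi or (ci == bi and cl < bl))):
                bs, bi, bl = cs, ci, cl
            Ys[i, j] = bs
            Yi[i, j] = bi
            Yl[i, j] = bl + 1
    bs, bi, bl = Ms[n, m], Mi[n, m], Ml[n, m]
    if Xs[n, m] > bs or (
        Xs[n, m] == bs and (Xi[n, m] > bi or (Xi[n, m] == bi and Xl[n, m] < bl))
    ):
        bs, bi, bl = Xs[n, m], Xi[n, m], Xl[n, m]
    if Ys[n, m] > bs or (
        Ys[n, m] == bs and (Yi[n, m] > bi or (Yi[n, m] == bi and Yl[n, m] < bl))
    ):
        bs, bi, bl = Ys[n, m], Yi[n, m], Yl[n, m]
    return bs, bi, bl


def align_stats(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> tuple[float, int, int]:
    """Global-alignment (score, identical columns, alignment columns)."""
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    scores = _scoring(params.substitution_matrix_name)
    a, b = _encode(seq_a), _encode(seq_b)
    if scores[a, a].min() <= _NEG or scores[b, b].min() <= _NEG:
        raise ValidationError("sequence contains residues outside the matrix")
    s2, ident, length = _gotoh(
        a,
        b,
        scores,
        int(round(2 * params.gap_open)),
        int(round(2 * params.gap_extend)),
    )
    return s2 / 2.0, int(ident), int(length)


def percent_identity(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    identity = 100 * (identical aligned residue pairs) / (alignment
    columns, gaps included).  Symmetric and deterministic.
    """
    _score, ident, length = align_stats(seq_a, seq_b, params)
    return 100.0 * ident / length


# --------------------------------------------------------------------------
# name allocation and classification
# --------------------------------------------------------------------------


def _letters(index: int) -> str:
    """Subfamily letter sequence A..Z, AA, AB, ... for 0-based index."""
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = chr(65 + rem) + out
    return out


class NovelNamer:
    """Run-scoped allocator for novel names and member numbers.

    Novel families receive placeholder names (prefix + counter, official
    numbers require the nomenclature committee); novel subfamilies get the
    next unused letter in their family; member numbers continue after the
    largest member present in the reference library for that (family,
    subfamily).
    """

    def __init__(
        self,
        library: Sequence[ReferenceEntry],
        novel_family_prefix: str = "CYPNOVEL",
    ) -> None:
        self.novel_family_prefix = novel_family_prefix
        self._novel_family_count = 0
        self._used_subfamilies: dict[str, set[str]] = {}
        self._next_member: dict[tuple[str, str], int] = {}
        for entry in library:
            fam, sub, member = parse_cyp_name(entry.cyp_name)
            self._used_subfamilies.setdefault(fam, set()).add(sub)
            key = (fam, sub)
            nxt = (member or 0) + 1
            self._next_member[key] = max(self._next_member.get(key, 1), nxt)

    def next_member_number(self, family: str, subfamily: str) -> int:
        key = (family, subfamily)
        n = self._next_member.get(key, 1)
        self._next_member[key] = n + 1
        return n

    def new_subfamily(self, family: str) -> str:
        used = self._used_subfamilies.setdefault(family, set())
        i = 0
        while _letters(i) in used:
            i += 1
        letter = _letters(i)
        used.add(letter)
        return letter

    def new_family(self) -> str:
        self._novel_family_count += 1
        family = f"{self.novel_family_prefix}{self._novel_family_count}"
        self._used_subfamilies.setdefault(family, set())
        return family


@dataclass(frozen=True)
class Assignment:
    """Classification of one candidate P450 against the reference library."""

    protein_id: str
    best_hit: str
    best_identity: float
    family: str
    subfamily_label: str
    is_novel_family: bool
    is_novel_subfamily: bool
    assigned_name: str


def classify(
    protein_id: str,
    sequence: str,
    reference_library: Sequence[ReferenceEntry],
    thresholds: NomenclatureThresholds = NomenclatureThresholds(),
    params: AlignmentParams = AlignmentParams(),
    namer: NovelNamer | None = None,
) -> Assignment:
    """Assign family/subfamily to one query by the percent-identity rule.

    Best hit is the reference maximizing percent identity (ties broken by
    lexicographically smallest CYP name).  Identity > subfamily threshold
    inherits family and subfamily of the best hit; identity in the family
    band gets a new subfamily letter in the best hit's family; identity at
    or below the family threshold founds a novel (placeholder) family.
    """
    if not reference_library:
        raise ValidationError("reference library is empty")
    if namer is None:
        namer = NovelNamer(reference_library)
    best_entry = None
    best_pid = -1.0
    for entry in sorted(reference_library, key=lambda e: e.cyp_name):
        pid = percent_identity(sequence, entry.sequence, params)
        if pid > best_pid:
            best_pid = pid
            best_entry = entry
    assert best_entry is not None
    if best_pid > thresholds.subfamily_min_identity:
        family, sub = best_entry.family, best_entry.subfamily_letter
        novel_family = novel_subfamily = False
    elif best_pid > thresholds.family_min_identity:
        family = best_entry.family
        sub = namer.new_subfamily(family)
        novel_family, novel_subfamily = False, True
    else:
        family = namer.new_family()
        sub = namer.new_subfamily(family)
        novel_family, novel_subfamily = True, True
    member = namer.next_member_number(family, sub)
    return Assignment(
        protein_id=protein_id,
        best_hit=best_entry.cyp_name,
        best_identity=best_pid,
        family=family,
        subfamily_label=sub,
        is_novel_family=novel_family,
        is_novel_subfamily=novel_subfamily,
        assigned_name=f"{family}{sub}{member}",
    )


def classify_proteome(
    candidates: Iterable[tuple[str, str]],
    reference_library: Sequence[ReferenceEntry],
    thresholds: NomenclatureThresholds = NomenclatureThresholds(),
    params: AlignmentParams = AlignmentParams(),
    novel_family_prefix: str = "CYPNOVEL",
) -> list[Assignment]:
    """Classify (protein_id, sequence) candidates in input order.

    Novel labels are allocated in input order from one shared namer, so
    the output is deterministic.  A per-family count report is logged.
    """
    namer = NovelNamer(reference_library, novel_family_prefix)
    assignments = [
        classify(pid, seq, reference_library, thresholds, params, namer)
        for pid, seq in candidates
    ]
    counts = Counter(a.family for a in assignments)
    logger.info(
        "classified %d candidates: %s",
        len(assignments),
        dict(sorted(counts.items())),
    )
    return assignments
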
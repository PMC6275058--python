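"""Candidate P450 detection.

Cytochrome P450s carry a conserved heme-ligand signature around the axial
cysteine (the PROSITE PS00086 region) and, upstream, the ExxR salt-bridge
motif of the K-helix.  A regex scan for the heme signature plus a length
gate is used here as a desk-scale detector; externally produced
superfamily hit tables (e.g. from CD-Search or an HMM scan) can be
imported instead and take precedence over the motif scan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seq_io import FormatError, JoinError, ProteinGeneRecord, _check_sequence

__all__ = [
    "DEFAULT_HEME_REGEX",
    "DEFAULT_EXXR_REGEX",
    "DetectorParams",
    "DetectionReport",
    "detect_p450",
    "scan_proteome",
    "import_external_hits",
]

#: Heme-ligand signature: aromatic anchor, the invariant cysteine that
#: ligates the heme iron, and the conserved flanking classes.  X never
#: matches a motif position (conservative detection).
DEFAULT_HEME_REGEX = r"[FW][SGNH][^X][GD][^X][RKHPT]C[LIVMFAP][GAD]"

#: K-helix ExxR motif (confidence annotation only, not required).
DEFAULT_EXXR_REGEX = r"E[^X][^X]R"


@dataclass(frozen=True)
class DetectorParams:
    """Detection knobs: length gate and motif patterns."""

    min_length: int = 250
    heme_regex: str = DEFAULT_HEME_REGEX
    exxr_regex: str = DEFAULT_EXXR_REGEX
    require_exxr: bool = False


@dataclass(frozen=True)
class DetectionReport:
    """Outcome of P450 candidacy screening for one protein."""

    protein_id: str
    is_candidate: bool
    heme_motif_span: tuple[int, int] | None  # 1-based inclusive, in protein
    exxr_motif_span: tuple[int, int] | None
    length_ok: bool
    source: str  # motif_scan | external_hits


def _first_span(pattern: str, sequence: str) -> tuple[int, int] | None:
    m = re.search(pattern, sequence)
    if m is None:
        return None
    return (m.start() + 1, m.end())  # 1-based inclusive


def detect_p450(
    record: ProteinGeneRecord, params: DetectorParams = DetectorParams()
) -> DetectionReport:
    """Screen one protein: candidate iff long enough and heme motif present.

    The ExxR span is recorded when found; it is only required when
    ``params.require_exxr`` is set.  Pure function of its inputs.
    """
    _check_sequence(record.sequence)
    length_ok = len(record.sequence) >= params.min_length
    heme = _first_span(params.heme_regex, record.sequence)
    exxr = _first_span(params.exxr_regex, record.sequence)
    is_candidate = length_ok and heme is not None
    if params.require_exxr:
        is_candidate = is_candidate and exxr is not None
    return DetectionReport(
        protein_id=record.protein_id,
        is_candidate=is_candidate,
        heme_motif_span=heme,
        exxr_motif_span=exxr,
        length_ok=length_ok,
        source="motif_scan",
    )


def scan_proteome(
    records: Iterable[ProteinGeneRecord],
    params: DetectorParams = DetectorParams(),
) -> list[DetectionReport]:
    """Apply :func:`detect_p450` to every protein, preserving input order."""
    return [detect_p450(r, params) for r in records]


def import_external_hits(
    path: str | Path, proteome: Sequence[ProteinGeneRecord]
) -> list[DetectionReport]:
    """Ingest an external superfamily hit table (TSV: protein_id, hit_flag).

    Candidates are the flagged ids; every flagged id must exist in the
    proteome.  Reports carry source="external_hits" and no motif spans.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_id", "hit_flag"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    truthy = {"1", "true", "yes", "y"}
    flagged = {
        rec["protein_id"]
        for rec in df.to_dict("records")
        if rec["hit_flag"].strip().lower() in truthy
    }
    known = {r.protein_id for r in proteome}
    missing = sorted(flagged - known)
    if missing:
        raise JoinError(f"{path}: flagged ids absent from proteome: {missing}")
    return [
        DetectionReport(
            protein_id=r.protein_id,
            is_candidate=r.protein_id in flagged,
            heme_motif_span=None,
            exxr_motif_span=None,
            length_ok=True,
            source="external_hits",
        )
        for r in proteome
    ]
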
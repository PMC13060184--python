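"""In-silico tryptic digestion and peptide-to-protein coordinate mapping.

Trypsin cleaves C-terminal to K or R except when the following residue is
proline (the Keil rule, the default of mainstream search engines).  The
theoretical digest is used for coverage expectations and simulation;
mapping of observed peptides is plain substring search so that semi-tryptic
evidence is never discarded by theory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import PsmRecord, ProteinRecord, ModObservation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide located on the protein, 1-based inclusive coordinates."""

    start: int
    end: int
    missed_cleavages: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    def covers(self, residue_index: int) -> bool:
        return self.start <= residue_index <= self.end


@dataclass(frozen=True)
class MappedPsm:
    """A PSM placed on the target protein.

    ``site_positions`` holds (absolute residue index, ModObservation) for
    the phospho modifications only; absolute index = span.start +
    peptide_position - 1.
    """

    psm: PsmRecord
    span: PeptideSpan
    site_positions: tuple[tuple[int, ModObservation], ...]
    multi_mapped: bool = False


def cleavage_points(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
) -> list[PeptideSpan]:
    """All tryptic peptides with up to ``max_missed`` missed cleavages.

    Returns spans sorted by (start, end) after length filtering.  The zero
    missed-cleavage peptides partition the sequence; a peptide with m missed
    cleavages is the concatenation of m+1 adjacent fragments.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")

    cuts = cleavage_points(sequence)
    boundaries = [0] + [c + 1 for c in cuts] + [len(sequence)]
    spans: list[PeptideSpan] = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m
            if j >= n_frag:
                break
            start, end = boundaries[i], boundaries[j + 1]
            if min_len <= end - start <= max_len:
                spans.append(
                    PeptideSpan(
                        start=start + 1,
                        end=end,
                        missed_cleavages=m,
                        sequence=sequence[start:end],
                    )
                )
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def map_peptide(peptide: str, protein: ProteinRecord) -> list[tuple[int, int]]:
    """All exact (possibly overlapping) matches of a peptide in the protein.

    1-based inclusive spans, ascending by start; empty list when absent.
    I and L are distinct (exact matching only).
    """
    if not peptide:
        raise ValueError("empty peptide")
    matches = []
    seq = protein.sequence
    pos = seq.find(peptide)
    while pos != -1:
        matches.append((pos + 1, pos + len(peptide)))
        pos = seq.find(peptide, pos + 1)
    return matches


@dataclass
class MappingReport:
    """Accounting from map_psms: how many PSMs were dropped or ambiguous."""

    n_input: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    unmapped_peptides: list[str] = field(default_factory=list)


def _build_mapped(psm: PsmRecord, start: int, end: int, n_cuts_inside: int,
                  multi: bool) -> MappedPsm:
    span = PeptideSpan(
        start=start, end=end, missed_cleavages=n_cuts_inside,
        sequence=psm.peptide_sequence,
    )
    sites = tuple(
        (start + m.peptide_position - 1, m) for m in psm.mods if m.is_phospho
    )
    return MappedPsm(psm=psm, span=span, site_positions=sites, multi_mapped=multi)


def map_psms(
    psms: list[PsmRecord],
    protein: ProteinRecord,
    ambiguity_policy: str = "first",
) -> tuple[list[MappedPsm], MappingReport]:
    """Place each PSM's peptide on the protein and lift phospho positions.

    ``ambiguity_policy`` governs peptides occurring more than once in the
    target: "first" keeps the left-most match (logged), "all" emits one
    MappedPsm per match flagged multi-mapped, "drop" excludes the PSM.
    Unmapped PSMs are excluded and counted.
    """
    if ambiguity_policy not in {"first", "all", "drop"}:
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")

    report = MappingReport(n_input=len(psms))
    internal_cuts = set(cleavage_points(protein.sequence))
    mapped: list[MappedPsm] = []
    for psm in psms:
        matches = map_peptide(psm.peptide_sequence, protein)
        if not matches:
            report.n_unmapped += 1
            report.unmapped_peptides.append(psm.peptide_sequence)
            continue
        if len(matches) > 1:
            report.n_ambiguous += 1
            if ambiguity_policy == "drop":
                continue
            if ambiguity_policy == "first":
                matches = matches[:1]
        multi = len(matches) > 1
        for start, end in matches:
            n_inside = sum(1 for c in internal_cuts if start - 1 <= c < end - 1)
            mapped.append(_build_mapped(psm, start, end, n_inside, multi))
        report.n_mapped += 1
    if report.n_unmapped:
        logger.info("%d/%d PSMs did not map to %s",
                    report.n_unmapped, report.n_input, protein.accession)
    if report.n_ambiguous:
        logger.info("%d PSMs matched the target more than once (policy=%s)",
                    report.n_ambiguous, ambiguity_policy)
    return mapped, report
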
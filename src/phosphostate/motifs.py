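"""MELT-class motif annotation and per-condition phospho-motif counts.

MELT motifs are degenerate Met-Glu-Leu-Thr repeats whose threonine, once
phosphorylated, recruits spindle-assembly-checkpoint proteins.  Because the
motif class is degenerate, the default scan pattern ``[MILV][ED][MILV]T``
is a convenience only: a curated coordinate file (motifs.tsv), when given,
is authoritative and overrides scanning.  SHT or any other motif class runs
through the same engine with a different pattern/coordinate set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import FormatError, PHOSPHO_ACCEPTORS, ProteinRecord

#: Degenerate MELT-class pattern; the trailing T is the phospho-acceptor.
DEFAULT_MELT_PATTERN = "[MILV][ED][MILV]T"
#: 0-based offset of the acceptor within a pattern match.
DEFAULT_ACCEPTOR_OFFSET = 3


@dataclass(frozen=True)
class MotifAnnotation:
    """One motif instance on the target, 1-based inclusive coordinates."""

    motif_id: str
    start: int
    end: int
    acceptor_position: int

    def __post_init__(self) -> None:
        if not self.start <= self.acceptor_position <= self.end:
            raise ValueError(
                f"{self.motif_id}: acceptor {self.acceptor_position} outside "
                f"[{self.start}, {self.end}]"
            )


def scan_motifs(
    protein: ProteinRecord,
    pattern: str = DEFAULT_MELT_PATTERN,
    acceptor_offset: int = DEFAULT_ACCEPTOR_OFFSET,
    motif_prefix: str = "MELT",
) -> list[MotifAnnotation]:
    """Non-overlapping left-to-right regex scan for a motif class.

    ``acceptor_offset`` is the 0-based position of the phospho-acceptor
    within each match; the acceptor residue must be S, T, or Y.
    """
    if acceptor_offset < 0:
        raise ValueError("pattern must define a non-negative acceptor offset")
    out = []
    for i, m in enumerate(re.finditer(pattern, protein.sequence), start=1):
        start0 = m.start()
        if acceptor_offset >= m.end() - start0:
            raise ValueError("acceptor offset beyond pattern match length")
        acceptor = start0 + acceptor_offset
        if protein.sequence[acceptor] not in PHOSPHO_ACCEPTORS:
            raise ValueError(
                f"acceptor residue {protein.sequence[acceptor]!r} at "
                f"{acceptor + 1} is not S/T/Y"
            )
        out.append(
            MotifAnnotation(
                motif_id=f"{motif_prefix}{i}",
                start=start0 + 1,
                end=m.end(),
                acceptor_position=acceptor + 1,
            )
        )
    return out


def load_motifs(path: str | Path, protein: ProteinRecord) -> list[MotifAnnotation]:
    """Read a curated motifs.tsv (motif_id, start, end, acceptor_position).

    Coordinates are validated against the protein; an acceptor that is not
    S/T/Y raises.  An empty table yields an empty list (scan fallback).
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    required = ["motif_id", "start", "end", "acceptor_position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"motifs table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        start, end, acc = int(row.start), int(row.end), int(row.acceptor_position)
        if not 1 <= start <= end <= len(protein):
            raise FormatError(
                f"{row.motif_id}: span ({start}, {end}) outside protein"
            )
        letter = protein.residue(acc)
        if letter not in PHOSPHO_ACCEPTORS:
            raise FormatError(
                f"{row.motif_id}: acceptor residue {letter!r} at {acc} is not S/T/Y"
            )
        out.append(MotifAnnotation(row.motif_id, start, end, acc))
    return out


def phosphorylated_motif_counts(
    condition_sets: Mapping[str, set[int]],
    motifs: Sequence[MotifAnnotation],
    mode: str = "acceptor_only",
) -> tuple[dict[str, int], int]:
    """Count motifs phosphorylated in each condition and overall.

    mode="acceptor_only" (default): a motif counts when its acceptor residue
    is in the condition's site set.  mode="any_in_window": any residue
    within [start, end] counts.  Overall = motifs hit in the union of all
    condition sets (distinct motifs, so overall >= every per-condition
    count).
    """
    if mode not in {"acceptor_only", "any_in_window"}:
        raise ValueError(f"unknown motif count mode {mode!r}")

    def hit(motif: MotifAnnotation, sites: set[int]) -> bool:
        if mode == "acceptor_only":
            return motif.acceptor_position in sites
        return any(p in sites for p in range(motif.start, motif.end + 1))

    per_condition = {
        condition: sum(hit(m, sites) for m in motifs)
        for condition, sites in condition_sets.items()
    }
    union: set[int] = set().union(*condition_sets.values()) if condition_sets else set()
    overall = sum(hit(m, union) for m in motifs)
    return per_condition, overall


def motif_counts_table(
    per_condition: Mapping[str, int],
    overall: int,
    n_motifs: int,
    condition_order: Iterable[str],
) -> pd.DataFrame:
    rows = [
        {"condition": c, "phosphorylated_motifs": per_condition[c],
         "total_motifs": n_motifs}
        for c in condition_order
    ]
    rows.append({"condition": "any", "phosphorylated_motifs": overall,
                 "total_motifs": n_motifs})
    return pd.DataFrame(rows)
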
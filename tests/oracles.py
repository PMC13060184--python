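"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: digestion enumerates
cleavage-boundary pairs directly, depth counts residues one by one, and the
site filter tests every (residue, condition, replicate) triple.
"""

from __future__ import annotations


def brute_force_digest(sequence: str, max_missed: int, min_len: int,
                       max_len: int) -> set[tuple[int, int, int]]:
    """All (start, end, missed) tryptic peptides by boundary enumeration.

    Trypsin cuts after K/R unless the next residue is P.  A peptide is any
    pair of cleavage boundaries with at most max_missed retained cut sites
    between them, length-filtered.  Coordinates 1-based inclusive.
    """
    boundaries = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(sequence))
    out = set()
    for a in range(len(boundaries) - 1):
        for b in range(a + 1, len(boundaries)):
            missed = b - a - 1
            if missed > max_missed:
                break
            start, end = boundaries[a], boundaries[b]
            if min_len <= end - start <= max_len:
                out.add((start + 1, end, missed))
    return out


def brute_force_depth(spans: list[tuple[int, int]], length: int) -> list[int]:
    """Per-residue span count by direct membership testing."""
    return [
        sum(1 for s, e in spans if s <= pos <= e) for pos in range(1, length + 1)
    ]


def brute_force_condition_sets(
    table: list[tuple[int, str, int, int, float | None]],
    conditions: list[str],
    min_conf: float,
    min_psms: int,
) -> dict[str, set[int]]:
    """Site sets from raw (residue, condition, replicate, count, conf) rows.

    Tests every triple directly: a residue is in a condition's set iff some
    replicate row has count >= min_psms and confidence strictly > min_conf.
    """
    sets: dict[str, set[int]] = {c: set() for c in conditions}
    for residue, condition, _replicate, count, conf in table:
        if count >= min_psms and conf is not None and conf > min_conf:
            sets[condition].add(residue)
    return sets
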
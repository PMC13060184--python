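"""Interactor spectral-count fold changes against the reference condition.

For each protein recovered in the purification, the per-condition average
PSM count (mean over replicates, zeros filled for absent replicates) is
compared with the reference (vehicle) condition through a pseudocount
ratio:

    FC = (avg_condition + 1) / (avg_reference + 1)

The +1 pseudocount keeps the ratio defined when a protein is absent from
the reference.  The analysis is semi-quantitative — no enrichment model or
contaminant scoring is applied; the protein panel is a reporting choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import ExperimentDesign, PsmRecord

logger = logging.getLogger(__name__)


@dataclass
class InteractorMatrix:
    """Tidy per-(protein, condition) averages and fold changes."""

    table: pd.DataFrame  # protein_accession, condition, avg_psms, fold_change
    design: ExperimentDesign

    def fold_change(self, protein: str, condition: str) -> float:
        t = self.table
        row = t[(t.protein_accession == protein) & (t.condition == condition)]
        if row.empty:
            raise KeyError((protein, condition))
        return float(row.fold_change.iloc[0])


def psm_count_table(
    psms: Sequence[PsmRecord],
    design: ExperimentDesign,
    panel: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Raw PSM counts per (protein, condition, replicate) from a PSM list.

    ``panel`` restricts and orders the protein rows; by default every
    accession seen in the PSMs is included, in first-seen order.
    """
    counts: dict[tuple[str, str, int], int] = {}
    seen: list[str] = []
    for p in psms:
        if p.protein_accession not in seen:
            seen.append(p.protein_accession)
        key = (p.protein_accession, p.condition, p.replicate)
        counts[key] = counts.get(key, 0) + 1
    proteins = list(panel) if panel is not None else seen
    rows = [
        {
            "protein_accession": acc,
            "condition": condition,
            "replicate": r,
            "psm_count": counts.get((acc, condition, r), 0),
        }
        for acc in proteins
        for condition in design.conditions
        for r in design.replicates
    ]
    return pd.DataFrame(rows)


def fold_change_matrix(
    psm_counts: pd.DataFrame,
    design: ExperimentDesign,
    pseudocount_stage: str = "after_average",
) -> InteractorMatrix:
    """Pseudocount fold-change matrix from raw replicate counts.

    ``psm_counts`` is tidy: protein_accession, condition, replicate,
    psm_count.  Averages are taken over the design's declared replicates
    with zeros for missing cells.  pseudocount_stage="after_average"
    (default) computes (avg+1)/(avg_ref+1); "per_replicate" computes the
    ratio (count+1)/(count_ref+1) replicate by replicate and averages the
    ratios.  A protein missing from the reference condition averages 0
    there, so its fold change is avg+1 (logged).
    """
    if pseudocount_stage not in {"after_average", "per_replicate"}:
        raise ValueError(f"unknown pseudocount stage {pseudocount_stage!r}")
    required = {"protein_accession", "condition", "replicate", "psm_count"}
    missing = required - set(psm_counts.columns)
    if missing:
        raise ValueError(f"psm_counts missing columns: {sorted(missing)}")
    if (psm_counts.psm_count < 0).any():
        raise ValueError("negative PSM counts")

    proteins = list(dict.fromkeys(psm_counts.protein_accession))
    counts: dict[tuple[str, str, int], float] = {
        (r.protein_accession, r.condition, int(r.replicate)): float(r.psm_count)
        for r in psm_counts.itertuples(index=False)
    }

    def rep_counts(acc: str, condition: str) -> list[float]:
        return [counts.get((acc, condition, r), 0.0) for r in design.replicates]

    rows = []
    ref = design.reference_condition
    for acc in proteins:
        ref_reps = rep_counts(acc, ref)
        avg_ref = sum(ref_reps) / design.n_replicates
        if avg_ref == 0.0:
            logger.info("%s absent from reference %s; fold change = avg + 1",
                        acc, ref)
        for condition in design.conditions:
            reps = rep_counts(acc, condition)
            avg = sum(reps) / design.n_replicates
            if pseudocount_stage == "after_average":
                fc = (avg + 1.0) / (avg_ref + 1.0)
            else:
                fc = sum(
                    (c + 1.0) / (cr + 1.0) for c, cr in zip(reps, ref_reps)
                ) / design.n_replicates
            rows.append(
                {
                    "protein_accession": acc,
                    "condition": condition,
                    "avg_psms": avg,
                    "fold_change": fc,
                }
            )
    return InteractorMatrix(table=pd.DataFrame(rows), design=design)


def interactor_table(matrix: InteractorMatrix) -> pd.DataFrame:
    """interactors.tsv layout: averages at 2 d.p., fold changes at 4 d.p."""
    t = matrix.table.copy()
    t["avg_psms"] = t.avg_psms.round(2)
    t["fold_change"] = t.fold_change.round(4)
    return t
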
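from __future__ import annotations

import pytest

from phosphostate import (
    ExperimentDesign,
    ModObservation,
    ProteinRecord,
    PsmRecord,
    default_design,
)


@pytest.fixture
def design() -> ExperimentDesign:
    return default_design()


@pytest.fixture
def protein() -> ProteinRecord:
    # 40 residues; tryptic cut sites after K6, R12 (R13 followed by P blocks
    # nothing here), K20, R30
    return ProteinRecord("P1", "MELTSKAQSTYRSPELTTPKSSYMELTAGRMELTSQWEYK")


def make_psm(
    peptide: str,
    condition: str = "DMSO",
    replicate: int = 1,
    phospho: list[tuple[int, float | None]] | None = None,
    accession: str = "P1",
    fdr: float | None = None,
) -> PsmRecord:
    """Build a PSM with phospho mods given as (peptide_position, confidence)."""
    mods = []
    for pos, conf in phospho or []:
        mods.append(ModObservation(peptide[pos - 1], pos, "Phospho", conf))
    return PsmRecord(
        sample_id=f"{condition}_r{replicate}",
        condition=condition,
        replicate=replicate,
        peptide_sequence=peptide,
        protein_accession=accession,
        mods=tuple(mods),
        peptide_fdr=fdr,
    )
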
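"""Readers and writers for the pipeline's external formats.

The package defines its own thin tab-separated PSM dialect (one row per
peptide-spectrum match) rather than parsing any search engine's native
export; an upstream adapter can map a vendor export onto it.  FASTA goes
through Biopython.  All downstream modules consume validated in-memory
records produced here and never touch files themselves.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino acids plus X for unknown residues.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Controlled modification vocabulary.
MOD_NAMES = frozenset({"Phospho", "Oxidation", "Carbamidomethyl"})

#: Residues that can carry a phospho group.
PHOSPHO_ACCEPTORS = frozenset("STY")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with a unique accession.

    Residue numbering throughout the package is 1-based on this sequence,
    so e.g. "S32" names ``sequence[31]`` which must be ``S``.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.accession}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise FormatError(
                    f"{self.accession}: illegal residue {aa!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, index: int) -> str:
        """1-based residue lookup."""
        return self.sequence[index - 1]


@dataclass(frozen=True)
class ModObservation:
    """One modification on one residue of a peptide.

    ``localization_confidence`` is a percent in [0, 100] (the search
    engine's site-localization score, treated as opaque) and may be absent
    for non-phospho modifications.
    """

    residue_letter: str
    peptide_position: int  # 1-based within the peptide
    mod_name: str
    localization_confidence: float | None = None

    def __post_init__(self) -> None:
        if self.peptide_position < 1:
            raise FormatError(f"modification position {self.peptide_position} < 1")
        if self.mod_name not in MOD_NAMES:
            raise FormatError(f"unknown modification name {self.mod_name!r}")
        c = self.localization_confidence
        if c is not None and not 0.0 <= c <= 100.0:
            raise FormatError(f"confidence {c} outside [0, 100]")

    @property
    def is_phospho(self) -> bool:
        return self.mod_name == "Phospho"


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match from one replicate of one condition."""

    sample_id: str
    condition: str
    replicate: int
    peptide_sequence: str
    protein_accession: str
    mods: tuple[ModObservation, ...] = ()
    peptide_fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise FormatError("empty peptide sequence")
        if self.replicate < 1:
            raise FormatError(f"replicate {self.replicate} < 1")
        for m in self.mods:
            if m.peptide_position > len(self.peptide_sequence):
                raise FormatError(
                    f"mod position {m.peptide_position} beyond peptide "
                    f"{self.peptide_sequence!r}"
                )
            actual = self.peptide_sequence[m.peptide_position - 1]
            if actual != m.residue_letter:
                raise FormatError(
                    f"mod claims {m.residue_letter} at peptide position "
                    f"{m.peptide_position} but peptide has {actual}"
                )


@dataclass(frozen=True)
class ExperimentDesign:
    """The condition/replicate layout of the experiment.

    ``arrested_conditions`` is the subset of treatments that arrest cells in
    mitosis (the non-vehicle compound treatments); the reference condition
    (vehicle) is never a member.
    """

    conditions: tuple[str, ...]
    reference_condition: str
    arrested_conditions: tuple[str, ...]
    n_replicates: int

    def __post_init__(self) -> None:
        if self.reference_condition not in self.conditions:
            raise ValueError("reference condition not among conditions")
        unknown = set(self.arrested_conditions) - set(self.conditions)
        if unknown:
            raise ValueError(f"arrested conditions not in design: {sorted(unknown)}")
        if self.reference_condition in self.arrested_conditions:
            raise ValueError("reference condition cannot be arrested")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition names")

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_replicates + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            conditions=tuple(raw["conditions"]),
            reference_condition=raw["reference_condition"],
            arrested_conditions=tuple(raw["arrested_conditions"]),
            n_replicates=int(raw["n_replicates"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "conditions": list(self.conditions),
                    "reference_condition": self.reference_condition,
                    "arrested_conditions": list(self.arrested_conditions),
                    "n_replicates": self.n_replicates,
                },
                sort_keys=False,
            )
        )


def default_design() -> ExperimentDesign:
    """Vehicle plus three mitotic-arrest treatments, three replicates each."""
    return ExperimentDesign(
        conditions=("DMSO", "nocodazole", "paclitaxel", "STLC"),
        reference_condition="DMSO",
        arrested_conditions=("nocodazole", "paclitaxel", "STLC"),
        n_replicates=3,
    )


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA into ProteinRecords, preserving order.

    Sequences are uppercased and whitespace-stripped; illegal residues raise
    a FormatError naming the record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("*", "")
        records.append(
            ProteinRecord(accession=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def find_protein(records: Sequence[ProteinRecord], accession: str) -> ProteinRecord:
    for rec in records:
        if rec.accession == accession:
            return rec
    raise KeyError(f"accession {accession!r} not found in FASTA")


# --------------------------------------------------------------------------
# Modification-string grammar:  zero or more semicolon-separated terms,
# each  <AA><pepPos>(<ModName>[,<confPercent>])

_MOD_TERM = re.compile(
    r"^(?P<aa>[A-Z])(?P<pos>\d+)\((?P<name>[A-Za-z]+)(?:,\s*(?P<conf>[0-9.]+))?\)$"
)


def parse_modification_string(text: str) -> list[ModObservation]:
    """Parse the mods field of a PSM row; '' yields an empty list."""
    text = text.strip()
    if not text:
        return []
    out = []
    for term in text.split(";"):
        term = term.strip()
        m = _MOD_TERM.match(term)
        if m is None:
            raise FormatError(f"malformed modification term {term!r}")
        conf = m.group("conf")
        out.append(
            ModObservation(
                residue_letter=m.group("aa"),
                peptide_position=int(m.group("pos")),
                mod_name=m.group("name"),
                localization_confidence=float(conf) if conf is not None else None,
            )
        )
    return out


def format_modification_string(mods: Iterable[ModObservation]) -> str:
    terms = []
    for m in mods:
        if m.localization_confidence is None:
            terms.append(f"{m.residue_letter}{m.peptide_position}({m.mod_name})")
        else:
            terms.append(
                f"{m.residue_letter}{m.peptide_position}"
                f"({m.mod_name},{m.localization_confidence:g})"
            )
    return "; ".join(terms)


# --------------------------------------------------------------------------
# PSM table

PSM_COLUMNS = (
    "sample_id",
    "condition",
    "replicate",
    "peptide_sequence",
    "protein_accession",
    "mods",
    "peptide_fdr",
)


@dataclass
class PsmReadReport:
    """Row accounting from one read_psm_table call."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_fdr: int = 0


def read_psm_table(
    path: str | Path,
    design: ExperimentDesign,
    fdr_threshold: float | None = 0.01,
) -> tuple[list[PsmRecord], PsmReadReport]:
    """Read and validate a psm.tsv table.

    Rows whose ``peptide_fdr`` exceeds ``fdr_threshold`` are dropped and
    counted (the upstream search's high-confidence pre-filter, peptide
    FDR < 1% by default).  Rows without a peptide_fdr are assumed
    pre-filtered.  Unknown conditions or replicates raise FormatError.
    """
    df = pd.read_csv(
        str(path), sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = [c for c in PSM_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise FormatError(f"psm table missing columns: {missing}")
    has_fdr = "peptide_fdr" in df.columns

    report = PsmReadReport(n_rows=len(df))
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        condition = row.condition
        if condition not in design.conditions:
            raise FormatError(f"line {i}: unknown condition {condition!r}")
        try:
            replicate = int(row.replicate)
        except ValueError as exc:
            raise FormatError(f"line {i}: bad replicate {row.replicate!r}") from exc
        if not 1 <= replicate <= design.n_replicates:
            raise FormatError(f"line {i}: replicate {replicate} outside design")

        fdr: float | None = None
        if has_fdr and row.peptide_fdr != "":
            fdr = float(row.peptide_fdr)
            if fdr_threshold is not None and fdr > fdr_threshold:
                report.n_dropped_fdr += 1
                continue
        try:
            mods = tuple(parse_modification_string(row.mods))
            rec = PsmRecord(
                sample_id=row.sample_id,
                condition=condition,
                replicate=replicate,
                peptide_sequence=row.peptide_sequence,
                protein_accession=row.protein_accession,
                mods=mods,
                peptide_fdr=fdr,
            )
        except FormatError as exc:
            raise FormatError(f"line {i}: {exc}") from exc
        records.append(rec)

    report.n_kept = len(records)
    if report.n_dropped_fdr:
        logger.info(
            "dropped %d/%d PSM rows above FDR threshold %s",
            report.n_dropped_fdr, report.n_rows, fdr_threshold,
        )
    return records, report


def psms_to_frame(psms: Iterable[PsmRecord]) -> pd.DataFrame:
    """Serialize PsmRecords to the psm.tsv column layout."""
    rows = []
    for p in psms:
        rows.append(
            {
                "sample_id": p.sample_id,
                "condition": p.condition,
                "replicate": p.replicate,
                "peptide_sequence": p.peptide_sequence,
                "protein_accession": p.protein_accession,
                "mods": format_modification_string(p.mods),
                "peptide_fdr": "" if p.peptide_fdr is None else f"{p.peptide_fdr:g}",
            }
        )
    return pd.DataFrame(rows, columns=list(PSM_COLUMNS))


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    psms_to_frame(psms).to_csv(str(path), sep="\t", index=False)


# --------------------------------------------------------------------------
# Report tables

def write_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write named report DataFrames as TSVs under ``out_dir``.

    Deterministic: callers are responsible for stable row sort and column
    order; this writer adds nothing non-reproducible.  Existing files are
    only replaced when ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        target = out_dir / f"{name}.tsv"
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
        df.to_csv(target, sep="\t", index=False)
        written[name] = target
    return written
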
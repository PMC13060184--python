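"""End-to-end orchestration: from FASTA + psm.tsv to the report tables.

Runs the whole analysis in memory first and only then writes files, so a
failed run leaves no partial outputs.  Every semantic the underlying
modules expose as a switch (per-replicate vs pooled filtering, star-rule
evidence, pseudocount stage, ambiguity policy, bin edges) is a named field
of PipelineConfig with the module's default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import coverage as cov
from . import interactors as inter
from . import io as fio
from . import motifs as mot
from . import sites as st
from .digest import MappedPsm, map_psms

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str | Path
    psm: str | Path
    out_dir: str | Path
    target_accession: str
    design: fio.ExperimentDesign = field(default_factory=fio.default_design)
    motifs: str | Path | None = None
    thresholds: st.FilterThresholds = field(default_factory=st.FilterThresholds)
    fdr_threshold: float | None = 0.01
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 50
    ambiguity_policy: str = "first"
    site_set_mode: str = "per_replicate"
    star_mode: str = "any_evidence"
    motif_count_mode: str = "acceptor_only"
    motif_pattern: str = mot.DEFAULT_MELT_PATTERN
    pseudocount_stage: str = "after_average"
    bin_edges: tuple[float, float] = (5.0, 10.0)
    panel: Sequence[str] | None = None
    overwrite: bool = False

    def __post_init__(self) -> None:
        low, high = self.bin_edges
        if not low < high:
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("design"), dict):
            d = raw["design"]
            raw["design"] = fio.ExperimentDesign(
                conditions=tuple(d["conditions"]),
                reference_condition=d["reference_condition"],
                arrested_conditions=tuple(d["arrested_conditions"]),
                n_replicates=int(d["n_replicates"]),
            )
        if isinstance(raw.get("thresholds"), dict):
            raw["thresholds"] = st.FilterThresholds(**raw["thresholds"])
        if "bin_edges" in raw:
            raw["bin_edges"] = tuple(raw["bin_edges"])
        return cls(**raw)


def bin_for_schematic(avg_phospho_psms: float,
                      edges: tuple[float, float] = (5.0, 10.0)) -> str:
    """Three-way binning of a site's average phospho-PSM count.

    The middle bin is closed on both ends: avg < low -> "low",
    low <= avg <= high -> "mid", avg > high -> "high".
    """
    low, high = edges
    if not low < high:
        raise ValueError("bin edges must be strictly increasing")
    if avg_phospho_psms < low:
        return "low"
    if avg_phospho_psms <= high:
        return "mid"
    return "high"


def schematic_rows(
    summaries: Sequence[st.SiteSummary],
    design: fio.ExperimentDesign,
    edges: tuple[float, float] = (5.0, 10.0),
) -> pd.DataFrame:
    """One row per (detected residue, condition) for the linear schematic.

    A starred site is starred only in the row of its unique condition.
    Rows sort by position, then design condition order.
    """
    rows = []
    for summary in sorted(summaries, key=lambda s: s.residue_index):
        for condition in design.conditions:
            stats = summary.per_condition[condition]
            if not stats.detected_in_condition:
                continue
            rows.append(
                {
                    "position": summary.residue_index,
                    "condition": condition,
                    "avg_phospho_psms": round(stats.avg_phospho_psms, 2),
                    "bin": bin_for_schematic(stats.avg_phospho_psms, edges),
                    "starred": summary.starred
                    and summary.unique_condition == condition,
                }
            )
    return pd.DataFrame(
        rows, columns=["position", "condition", "avg_phospho_psms", "bin",
                       "starred"],
    )


def sites_table(summaries: Sequence[st.SiteSummary],
                design: fio.ExperimentDesign) -> pd.DataFrame:
    rows = []
    for s in sorted(summaries, key=lambda x: x.residue_index):
        row: dict = {
            "residue_index": s.residue_index,
            "residue_letter": s.residue_letter,
        }
        for condition in design.conditions:
            stats = s.per_condition[condition]
            row[f"{condition}_rep_counts"] = ";".join(
                str(c) for c in stats.replicate_counts
            )
            row[f"{condition}_qualifying_reps"] = stats.qualifying_replicate_count
            row[f"{condition}_avg"] = round(stats.avg_phospho_psms, 2)
            row[f"{condition}_in_set"] = stats.detected_in_condition
        row["classification"] = s.classification
        row["starred"] = s.starred
        row["unique_condition"] = s.unique_condition or ""
        rows.append(row)
    columns = ["residue_index", "residue_letter"]
    for condition in design.conditions:
        columns += [f"{condition}_rep_counts", f"{condition}_qualifying_reps",
                    f"{condition}_avg", f"{condition}_in_set"]
    columns += ["classification", "starred", "unique_condition"]
    return pd.DataFrame(rows, columns=columns)


def venn_table(cells: dict[tuple[str, ...], int], total: int,
               design: fio.ExperimentDesign) -> pd.DataFrame:
    order = {c: i for i, c in enumerate(design.conditions)}
    patterns = sorted(cells, key=lambda p: (len(p), [order[c] for c in p]))
    rows = [
        {"membership_pattern": "&".join(p), "count": cells[p]} for p in patterns
    ]
    rows.append({"membership_pattern": "any", "count": total})
    return pd.DataFrame(rows, columns=["membership_pattern", "count"])


@dataclass
class PipelineResult:
    protein: fio.ProteinRecord
    mapped: list[MappedPsm]
    condition_sets: dict[str, set[int]]
    summaries: list[st.SiteSummary]
    venn_cells: dict[tuple[str, ...], int]
    total_sites: int
    coverage_by_condition: dict[str, cov.ConditionCoverage]
    motif_annotations: list[mot.MotifAnnotation]
    motif_counts: dict[str, int]
    motif_overall: int
    interactor_matrix: inter.InteractorMatrix
    tables: dict[str, pd.DataFrame]
    written: dict[str, Path]
    log_lines: list[str]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report TSVs plus run.log."""
    log: list[str] = []

    proteins = fio.read_fasta(config.fasta)
    target = fio.find_protein(proteins, config.target_accession)
    log.append(f"target {target.accession}: {len(target)} residues")

    psms, read_report = fio.read_psm_table(
        config.psm, config.design, config.fdr_threshold
    )
    log.append(
        f"psm rows: {read_report.n_rows} read, {read_report.n_kept} kept, "
        f"{read_report.n_dropped_fdr} dropped by FDR filter"
    )

    target_psms = [p for p in psms if p.protein_accession == target.accession]
    mapped, map_report = map_psms(target_psms, target, config.ambiguity_policy)
    log.append(
        f"mapping: {map_report.n_mapped}/{map_report.n_input} PSMs mapped, "
        f"{map_report.n_unmapped} unmapped, {map_report.n_ambiguous} ambiguous "
        f"(policy={config.ambiguity_policy})"
    )

    mapped_by: dict[str, dict[int, list[MappedPsm]]] = {
        c: {r: [] for r in config.design.replicates}
        for c in config.design.conditions
    }
    for m in mapped:
        mapped_by[m.psm.condition][m.psm.replicate].append(m)

    coverage_by = cov.condition_coverage(mapped_by, len(target), config.design)
    depth_by_replicate = {
        (c, r): coverage_by[c].replicate_profiles[r].depth
        for c in config.design.conditions
        for r in config.design.replicates
    }

    observations = st.extract_site_observations(
        mapped, config.design, depth_by_replicate
    )
    condition_sets = st.condition_site_set(
        observations, config.thresholds, config.design, config.site_set_mode
    )
    summaries = st.classify_sites(
        condition_sets, config.design, observations, config.thresholds,
        config.star_mode,
    )
    venn_cells, total_sites = st.venn_counts(condition_sets)
    log.append(
        "site sets: "
        + ", ".join(f"{c}={len(s)}" for c, s in condition_sets.items())
        + f"; total distinct={total_sites}"
    )

    if config.motifs is not None:
        motif_annotations = mot.load_motifs(config.motifs, target)
        log.append(f"motifs: {len(motif_annotations)} loaded from file")
    else:
        motif_annotations = mot.scan_motifs(target, config.motif_pattern)
        log.append(f"motifs: {len(motif_annotations)} found by scan")
    motif_counts, motif_overall = mot.phosphorylated_motif_counts(
        condition_sets, motif_annotations, config.motif_count_mode
    )

    counts = inter.psm_count_table(psms, config.design, config.panel)
    matrix = inter.fold_change_matrix(
        counts, config.design, config.pseudocount_stage
    )

    tables = {
        "sites": sites_table(summaries, config.design),
        "coverage": cov.coverage_table(coverage_by, config.design),
        "interactors": inter.interactor_table(matrix),
        "venn": venn_table(venn_cells, total_sites, config.design),
        "schematic": schematic_rows(summaries, config.design, config.bin_edges),
        "motif_counts": mot.motif_counts_table(
            motif_counts, motif_overall, len(motif_annotations),
            config.design.conditions,
        ),
    }

    written = fio.write_tables(tables, config.out_dir, config.overwrite)
    log_path = Path(config.out_dir) / "run.log"
    if log_path.exists() and not config.overwrite:
        raise FileExistsError(f"{log_path} exists; pass overwrite=True")
    log_path.write_text("\n".join(log) + "\n")
    written["run_log"] = log_path

    return PipelineResult(
        protein=target,
        mapped=mapped,
        condition_sets=condition_sets,
        summaries=summaries,
        venn_cells=venn_cells,
        total_sites=total_sites,
        coverage_by_condition=coverage_by,
        motif_annotations=motif_annotations,
        motif_counts=motif_counts,
        motif_overall=motif_overall,
        interactor_matrix=matrix,
        tables=tables,
        written=written,
        log_lines=log,
    )
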
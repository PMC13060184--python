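"""Per-residue PSM depth and sequence-coverage summaries.

Depth at a residue is the number of PSMs whose mapped span contains it;
percent coverage is the fraction of residues with depth >= 1.  Mean depth is
averaged over *covered* residues only, so a coverage/depth pair reads as
"X% of the protein was seen, and where seen, to a mean depth of Y PSMs".
Replicates are summarized individually and then averaged per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import MappedPsm
from .io import ExperimentDesign


@dataclass
class CoverageProfile:
    """Depth vector plus scalar summaries for one replicate."""

    depth: np.ndarray
    percent_coverage: float
    mean_depth_covered: float
    any_covered: bool


def per_position_depth(mapped: Sequence[MappedPsm], protein_length: int) -> np.ndarray:
    """Count PSM spans overlapping each residue (1-based spans -> 0-based vector).

    A multi-mapped PSM kept under policy="all" contributes once per span.
    """
    depth = np.zeros(protein_length, dtype=np.int64)
    for m in mapped:
        if m.span.start < 1 or m.span.end > protein_length:
            raise ValueError(
                f"span ({m.span.start}, {m.span.end}) outside [1, {protein_length}]"
            )
        depth[m.span.start - 1 : m.span.end] += 1
    return depth


def coverage_stats(depth: np.ndarray) -> CoverageProfile:
    """Percent coverage and mean depth over covered residues.

    With nothing covered the mean is undefined; it is reported as 0.0 with
    ``any_covered`` False so downstream tables stay numeric.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    covered = depth >= 1
    n_cov = int(covered.sum())
    percent = 100.0 * n_cov / depth.size
    if n_cov == 0:
        return CoverageProfile(depth, 0.0, 0.0, False)
    return CoverageProfile(depth, percent, float(depth[covered].mean()), True)


@dataclass
class ConditionCoverage:
    """Replicate-wise coverage for one condition plus replicate averages."""

    condition: str
    replicate_profiles: dict[int, CoverageProfile]
    avg_percent_coverage: float
    avg_mean_depth_covered: float
    mean_depth_vector: np.ndarray


def condition_coverage(
    mapped_by_replicate: Mapping[str, Mapping[int, Sequence[MappedPsm]]],
    protein_length: int,
    design: ExperimentDesign,
) -> dict[str, ConditionCoverage]:
    """Per-condition average of replicate coverage statistics.

    Each declared replicate of each condition yields a CoverageProfile (a
    replicate with no PSMs contributes zeros); the condition's summary is
    the arithmetic mean of the replicate percents and covered-mean depths,
    plus the residue-wise mean depth vector for coverage maps.
    """
    out: dict[str, ConditionCoverage] = {}
    for condition in design.conditions:
        reps = mapped_by_replicate.get(condition, {})
        profiles: dict[int, CoverageProfile] = {}
        for r in design.replicates:
            depth = per_position_depth(reps.get(r, []), protein_length)
            profiles[r] = coverage_stats(depth)
        if not profiles:
            raise ValueError(f"condition {condition} has no replicates")
        percents = [p.percent_coverage for p in profiles.values()]
        means = [p.mean_depth_covered for p in profiles.values()]
        stack = np.stack([p.depth for p in profiles.values()])
        out[condition] = ConditionCoverage(
            condition=condition,
            replicate_profiles=profiles,
            avg_percent_coverage=float(np.mean(percents)),
            avg_mean_depth_covered=float(np.mean(means)),
            mean_depth_vector=stack.mean(axis=0),
        )
    return out


def coverage_table(per_condition: Mapping[str, ConditionCoverage],
                   design: ExperimentDesign) -> pd.DataFrame:
    """coverage.tsv layout: one row per replicate plus an 'avg' row, 2 d.p."""
    rows = []
    for condition in design.conditions:
        cc = per_condition[condition]
        for r in design.replicates:
            p = cc.replicate_profiles[r]
            rows.append(
                {
                    "condition": condition,
                    "replicate": str(r),
                    "percent_coverage": round(p.percent_coverage, 2),
                    "mean_depth_covered": round(p.mean_depth_covered, 2),
                }
            )
        rows.append(
            {
                "condition": condition,
                "replicate": "avg",
                "percent_coverage": round(cc.avg_percent_coverage, 2),
                "mean_depth_covered": round(cc.avg_mean_depth_covered, 2),
            }
        )
    return pd.DataFrame(rows)


def coverage_map_table(per_condition: Mapping[str, ConditionCoverage],
                       design: ExperimentDesign) -> pd.DataFrame:
    """Long-format per-residue mean depth, for rendering coverage maps."""
    rows = []
    for condition in design.conditions:
        vec = per_condition[condition].mean_depth_vector
        for pos in range(1, len(vec) + 1):
            rows.append(
                {"position": pos, "condition": condition,
                 "mean_depth": round(float(vec[pos - 1]), 4)}
            )
    return pd.DataFrame(rows)
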
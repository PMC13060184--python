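"""Per-residue phospho-site aggregation, filtering, and classification.

The analysis follows spectral-count conventions for semi-quantitative
phospho-profiling of a single bait protein:

* every phospho observation is aggregated per (residue, condition,
  replicate) — the phospho-PSM count plus the best localization confidence;
* a site *qualifies* in a replicate when its best confidence is strictly
  above the threshold (default 75%) and it has at least ``min_phospho_psms``
  (default 2) phospho-PSMs;
* a condition's site set is the union of its qualifying replicates;
* sites are classified across conditions as shared by all, shared by the
  mitotically arrested (non-reference) conditions only, unique to a single
  condition, or other;
* per-site averages are raw means over all declared replicates, zeros
  included and independent of qualification — so two phospho-PSMs seen in
  one of three replicates average 0.67.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import MappedPsm
from .io import ExperimentDesign

logger = logging.getLogger(__name__)

CLASS_SHARED_ALL = "shared_all"
CLASS_ARRESTED_SHARED = "arrested_shared"
CLASS_CONDITION_UNIQUE = "condition_unique"
CLASS_OTHER = "other"


@dataclass(frozen=True)
class FilterThresholds:
    """Site qualification filter: strict >min_confidence_percent AND
    >=min_phospho_psms phospho-PSMs, applied per replicate."""

    min_confidence_percent: float = 75.0
    min_phospho_psms: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence_percent <= 100.0:
            raise ValueError("confidence threshold outside [0, 100]")
        if self.min_phospho_psms < 1:
            raise ValueError("min_phospho_psms must be >= 1")


@dataclass(frozen=True)
class SiteObservation:
    """Phospho evidence for one residue in one replicate of one condition."""

    residue_index: int
    residue_letter: str
    condition: str
    replicate: int
    phospho_psm_count: int
    best_confidence: float | None
    total_psm_count_at_position: int = 0


@dataclass
class ConditionSiteStats:
    """Per-condition slice of a SiteSummary."""

    replicate_counts: tuple[int, ...]
    qualifying_replicate_count: int
    avg_phospho_psms: float
    detected_in_condition: bool


@dataclass
class SiteSummary:
    """Cross-condition record for one phospho-site."""

    residue_index: int
    residue_letter: str
    per_condition: dict[str, ConditionSiteStats]
    classification: str
    starred: bool
    unique_condition: str | None


def extract_site_observations(
    mapped: Sequence[MappedPsm],
    design: ExperimentDesign,
    depth_by_replicate: Mapping[tuple[str, int], np.ndarray] | None = None,
) -> list[SiteObservation]:
    """Aggregate phospho evidence per (residue, condition, replicate).

    For every residue with phospho evidence anywhere in the experiment,
    zero-count observations are synthesized for all remaining
    (condition, replicate) cells of the design so that downstream averages
    include zeros.  ``depth_by_replicate`` (condition, replicate) -> depth
    vector supplies the total PSM count covering each residue.
    """
    counts: dict[tuple[int, str, int], int] = {}
    best: dict[tuple[int, str, int], float | None] = {}
    letters: dict[int, str] = {}

    for m in mapped:
        key_cr = (m.psm.condition, m.psm.replicate)
        for pos, mod in m.site_positions:
            key = (pos, *key_cr)
            counts[key] = counts.get(key, 0) + 1
            prev = best.get(key)
            conf = mod.localization_confidence
            if conf is not None and (prev is None or conf > prev):
                best[key] = conf
            else:
                best.setdefault(key, prev)
            letters.setdefault(pos, mod.residue_letter)

    observations: list[SiteObservation] = []
    for pos in sorted(letters):
        for condition in design.conditions:
            for replicate in design.replicates:
                key = (pos, condition, replicate)
                total = 0
                if depth_by_replicate is not None:
                    vec = depth_by_replicate.get((condition, replicate))
                    if vec is not None and pos <= len(vec):
                        total = int(vec[pos - 1])
                observations.append(
                    SiteObservation(
                        residue_index=pos,
                        residue_letter=letters[pos],
                        condition=condition,
                        replicate=replicate,
                        phospho_psm_count=counts.get(key, 0),
                        best_confidence=best.get(key),
                        total_psm_count_at_position=total,
                    )
                )
    return observations


def qualifies(obs: SiteObservation, thresholds: FilterThresholds) -> bool:
    """Per-replicate filter: strictly >threshold confidence AND enough PSMs."""
    if obs.phospho_psm_count < thresholds.min_phospho_psms:
        return False
    if obs.best_confidence is None:
        if obs.phospho_psm_count > 0:
            logger.debug(
                "site %d (%s, rep %d): phospho evidence without confidence",
                obs.residue_index, obs.condition, obs.replicate,
            )
        return False
    return obs.best_confidence > thresholds.min_confidence_percent


def condition_site_set(
    observations: Iterable[SiteObservation],
    thresholds: FilterThresholds,
    design: ExperimentDesign,
    mode: str = "per_replicate",
) -> dict[str, set[int]]:
    """Residues qualifying in each condition.

    mode="per_replicate" (default): a residue enters a condition's set when
    it qualifies in at least one replicate (filter per replicate, union over
    replicates).  mode="pooled": replicate counts are summed and confidences
    maxed across replicates before the filter is applied once.
    """
    if mode not in {"per_replicate", "pooled"}:
        raise ValueError(f"unknown site-set mode {mode!r}")
    sets: dict[str, set[int]] = {c: set() for c in design.conditions}
    if mode == "per_replicate":
        for obs in observations:
            if qualifies(obs, thresholds):
                sets[obs.condition].add(obs.residue_index)
        return sets

    pooled: dict[tuple[int, str], SiteObservation] = {}
    for obs in observations:
        key = (obs.residue_index, obs.condition)
        prev = pooled.get(key)
        if prev is None:
            pooled[key] = obs
        else:
            confs = [c for c in (prev.best_confidence, obs.best_confidence)
                     if c is not None]
            pooled[key] = SiteObservation(
                residue_index=obs.residue_index,
                residue_letter=obs.residue_letter,
                condition=obs.condition,
                replicate=prev.replicate,
                phospho_psm_count=prev.phospho_psm_count + obs.phospho_psm_count,
                best_confidence=max(confs) if confs else None,
                total_psm_count_at_position=(
                    prev.total_psm_count_at_position
                    + obs.total_psm_count_at_position
                ),
            )
    for (pos, condition), obs in pooled.items():
        if qualifies(obs, thresholds):
            sets[condition].add(pos)
    return sets


def site_averages(
    observations: Iterable[SiteObservation],
    design: ExperimentDesign,
) -> dict[tuple[int, str], float]:
    """Mean raw phospho-PSM count over all declared replicates.

    Zeros count; qualification is ignored.  Division is by the design's
    replicate number, so replicates with no observation record still
    contribute zero.
    """
    totals: dict[tuple[int, str], int] = {}
    for obs in observations:
        key = (obs.residue_index, obs.condition)
        totals[key] = totals.get(key, 0) + obs.phospho_psm_count
    return {k: v / design.n_replicates for k, v in totals.items()}


def classify_membership(
    members: set[str], design: ExperimentDesign
) -> tuple[str, str | None]:
    """Label a cross-condition membership pattern.

    Returns (classification, unique_condition-or-None).  The labels are
    mutually exclusive: membership in every condition wins over membership
    in the arrested subset, which wins over single-condition uniqueness.
    """
    if members == set(design.conditions):
        return CLASS_SHARED_ALL, None
    if members == set(design.arrested_conditions):
        return CLASS_ARRESTED_SHARED, None
    if len(members) == 1:
        return CLASS_CONDITION_UNIQUE, next(iter(members))
    return CLASS_OTHER, None


def _star_evidence_replicates(
    observations: Sequence[SiteObservation],
    residue: int,
    condition: str,
    thresholds: FilterThresholds,
    star_mode: str,
) -> int:
    n = 0
    for obs in observations:
        if obs.residue_index != residue or obs.condition != condition:
            continue
        if star_mode == "qualifying":
            ok = qualifies(obs, thresholds)
        else:  # any_evidence: count criterion only, confidence not required
            ok = obs.phospho_psm_count >= thresholds.min_phospho_psms
        if ok:
            n += 1
    return n


def classify_sites(
    condition_sets: Mapping[str, set[int]],
    design: ExperimentDesign,
    observations: Sequence[SiteObservation],
    thresholds: FilterThresholds = FilterThresholds(),
    star_mode: str = "any_evidence",
) -> list[SiteSummary]:
    """Label every detected site by its cross-condition membership pattern.

    shared_all: in every condition's set.  arrested_shared: in all arrested
    conditions' sets and absent from the reference set.  condition_unique:
    in exactly one set.  Everything else: other.  A condition_unique site is
    *starred* when it shows per-replicate evidence (mode "any_evidence":
    phospho-PSM count >= the filter's minimum, confidence not required;
    mode "qualifying": the full per-replicate filter) in at least 2
    replicates of its condition.
    """
    if star_mode not in {"any_evidence", "qualifying"}:
        raise ValueError(f"unknown star mode {star_mode!r}")

    letters = {o.residue_index: o.residue_letter for o in observations}
    averages = site_averages(observations, design)
    counts_by: dict[tuple[int, str], dict[int, int]] = {}
    qual_by: dict[tuple[int, str], int] = {}
    for obs in observations:
        key = (obs.residue_index, obs.condition)
        counts_by.setdefault(key, {})[obs.replicate] = obs.phospho_psm_count
        if qualifies(obs, thresholds):
            qual_by[key] = qual_by.get(key, 0) + 1

    union = sorted(set().union(*condition_sets.values())) if condition_sets else []
    summaries: list[SiteSummary] = []
    for pos in union:
        members = {c for c, s in condition_sets.items() if pos in s}
        label, unique = classify_membership(members, design)

        starred = False
        if label == CLASS_CONDITION_UNIQUE:
            n_reps = _star_evidence_replicates(
                observations, pos, unique, thresholds, star_mode
            )
            starred = n_reps >= 2

        per_condition = {}
        for condition in design.conditions:
            key = (pos, condition)
            reps = counts_by.get(key, {})
            per_condition[condition] = ConditionSiteStats(
                replicate_counts=tuple(
                    reps.get(r, 0) for r in design.replicates
                ),
                qualifying_replicate_count=qual_by.get(key, 0),
                avg_phospho_psms=averages.get(key, 0.0),
                detected_in_condition=condition in members,
            )
        summaries.append(
            SiteSummary(
                residue_index=pos,
                residue_letter=letters.get(pos, "?"),
                per_condition=per_condition,
                classification=label,
                starred=starred,
                unique_condition=unique,
            )
        )
    return summaries


def venn_counts(
    condition_sets: Mapping[str, set[int]],
) -> tuple[dict[tuple[str, ...], int], int]:
    """Exact partition of the site union over membership patterns.

    Returns ({pattern tuple -> count} for occupied patterns, total distinct
    sites).  Pattern tuples preserve the mapping's condition order.
    """
    conditions = list(condition_sets)
    union: set[int] = set().union(*condition_sets.values()) if condition_sets else set()
    cells: dict[tuple[str, ...], int] = {}
    for pos in union:
        pattern = tuple(c for c in conditions if pos in condition_sets[c])
        cells[pattern] = cells.get(pattern, 0) + 1
    return cells, len(union)
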
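"""Synthetic PSM datasets with planted phospho-sites and ground truth.

The generator emulates the statistical structure of a single-bait AP-MS
phospho-profiling experiment: a long, lysine/arginine-rich bait protein
digested with trypsin, log-normal peptide abundances driving Poisson
spectral counts per replicate, planted phospho-sites whose occupancy
depends on the treatment condition, imperfect site-localization confidence
(true sites drawn high, decoy placements drawn low, with overlap so the
confidence filter is genuinely exercised), and a low rate of spurious
phospho assignments.

Ground truth is emitted alongside the PSM table: for every planted site,
its per-condition occupancy and the classification the aggregation pipeline
is expected to assign under the default thresholds.  Expected membership is
computed analytically from the occupancies and the realized expected depth
at the site, using the same union-over-replicates membership semantics as
the pipeline, so recovery tests are a round trip rather than a
re-derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import PeptideSpan, digest
from .io import (
    ExperimentDesign,
    ModObservation,
    ProteinRecord,
    PsmRecord,
    default_design,
)
from .sites import classify_membership

# Background residue frequencies (bait-like: Ser/Thr-rich scaffold).
# K+R mass is replaced by the configured kr_frequency at sampling time.
_BACKGROUND = {
    "S": 0.09, "T": 0.07, "P": 0.045, "K": 0.05, "R": 0.05,
}
_OTHER_LETTERS = "ACDEFGHILMNQVWY"


@dataclass(frozen=True)
class PlannedSite:
    """One phospho-site to plant: residue class and condition occupancies."""

    residue_class: str  # S, T, or Y
    occupancy: dict[str, float]
    residue_index: int | None = None  # assigned when the protein is built

    def active_conditions(self) -> set[str]:
        return {c for c, occ in self.occupancy.items() if occ > 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror a deep single-bait experiment on a >2000-residue
    scaffold: 4 conditions x 3 replicates, a mean per-residue PSM depth of
    20, and 40 planted sites spanning the shared-all, arrested-shared and
    single-condition designs.
    """

    protein_length: int = 2342
    kr_frequency: float = 0.10
    design: ExperimentDesign = field(default_factory=default_design)
    site_plan: tuple[PlannedSite, ...] | None = None
    mean_depth: float = 20.0
    abundance_sigma: float = 0.6
    true_conf_beta: tuple[float, float] = (9.0, 1.0)
    decoy_conf_beta: tuple[float, float] = (2.0, 4.0)
    decoy_rate: float = 0.01
    oxidation_rate: float = 0.05
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 30
    accession: str = "SYN_TARGET"
    seed: int = 0

    def resolved_site_plan(self) -> tuple[PlannedSite, ...]:
        return self.site_plan if self.site_plan is not None else default_site_plan(
            self.design
        )


def default_site_plan(design: ExperimentDesign) -> tuple[PlannedSite, ...]:
    """40 planted sites: 14 shared-all, 14 arrested-shared, 12 unique.

    Occupancies are moderate (0.55-0.6) in active conditions and exactly 0
    elsewhere; unique sites are spread over all conditions (3 each for a
    4-condition design).  Residue classes alternate S/T with an occasional
    Y, as in S/T-dominated phospho-proteomes.
    """
    classes = ["S", "T", "S", "T", "S", "Y"]  # mostly S/T, some Y
    plan: list[PlannedSite] = []

    def cls(i: int) -> str:
        return classes[i % len(classes)]

    all_conds = design.conditions
    arrested = design.arrested_conditions
    i = 0
    for _ in range(14):
        plan.append(PlannedSite(cls(i), {c: 0.6 for c in all_conds}))
        i += 1
    for _ in range(14):
        occ = {c: 0.6 if c in arrested else 0.0 for c in all_conds}
        plan.append(PlannedSite(cls(i), occ))
        i += 1
    for j in range(12):
        target = all_conds[j % len(all_conds)]
        occ = {c: 0.55 if c == target else 0.0 for c in all_conds}
        plan.append(PlannedSite(cls(i), occ))
        i += 1
    return tuple(plan)


def _sample_background(length: int, kr_frequency: float,
                       rng: np.random.Generator) -> list[str]:
    letters = list(_BACKGROUND) + list(_OTHER_LETTERS)
    probs = dict(_BACKGROUND)
    probs["K"] = kr_frequency / 2.0
    probs["R"] = kr_frequency / 2.0
    fixed = sum(probs.values())
    each = (1.0 - fixed) / len(_OTHER_LETTERS)
    weights = [probs.get(l, each) for l in letters]
    return list(rng.choice(letters, size=length, p=weights))


def simulate_protein(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProteinRecord, tuple[PlannedSite, ...]]:
    """Build the bait sequence and plant the configured phospho-sites.

    Planted positions are chosen among residues covered by the theoretical
    digest (so each site is observable) whose letter is not K, R or P (so
    overwriting it with S/T/Y cannot change the cleavage pattern).  Returns
    the protein together with the site plan resolved to residue indices.
    """
    if config.protein_length < 50:
        raise ValueError("protein_length must be >= 50")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    seq = _sample_background(config.protein_length, config.kr_frequency, rng)
    spans = digest("".join(seq), config.max_missed, config.min_len, config.max_len)
    coverable = np.zeros(config.protein_length, dtype=bool)
    for s in spans:
        coverable[s.start - 1 : s.end] = True
    eligible = [
        i for i in range(config.protein_length)
        if coverable[i] and seq[i] not in "KRP"
    ]
    plan = config.resolved_site_plan()
    if len(eligible) < len(plan):
        raise ValueError("protein too short/K-R-rich to plant all sites")
    positions = rng.choice(len(eligible), size=len(plan), replace=False)
    resolved = []
    for site, k in zip(plan, positions):
        idx0 = eligible[int(k)]
        seq[idx0] = site.residue_class
        resolved.append(replace(site, residue_index=idx0 + 1))
    resolved.sort(key=lambda s: s.residue_index)
    protein = ProteinRecord(
        accession=config.accession,
        sequence="".join(seq),
        description="synthetic bait",
    )
    return protein, tuple(resolved)


def _poisson_ge2(lam: float) -> float:
    return 1.0 - math.exp(-lam) * (1.0 + lam)


def _expected_truth(
    site: PlannedSite,
    expected_depth: float,
    config: SimulationConfig,
    min_phospho_psms: int = 2,
    min_conf: float = 75.0,
) -> tuple[dict[str, bool], str, bool]:
    """Analytic expected membership/classification for one planted site.

    Per replicate, the phospho-PSM count at the site is approximately
    Poisson(depth x occupancy); the site is expected in a condition's set
    when the probability of qualifying in at least one of the replicates
    exceeds one half.  The same membership-pattern rule as the pipeline
    yields the expected classification.
    """
    a, b = config.true_conf_beta
    # P(a true-site confidence draw <= threshold); Beta(a, 1) has cdf x^a
    if b == 1.0:
        p_low = (min_conf / 100.0) ** a
    else:  # generic fallback via coarse numeric cdf
        xs = np.linspace(0, min_conf / 100.0, 200)
        from math import gamma
        dens = xs ** (a - 1) * (1 - xs) ** (b - 1)
        p_low = float(np.trapezoid(dens, xs) * gamma(a + b) / (gamma(a) * gamma(b)))

    membership: dict[str, bool] = {}
    p_star_rep = 0.0
    for condition in config.design.conditions:
        lam = expected_depth * site.occupancy.get(condition, 0.0)
        p_count = _poisson_ge2(lam) if min_phospho_psms == 2 else (
            1.0 - math.exp(-lam)
        )
        p_conf = 1.0 - p_low ** max(min_phospho_psms, 1)
        p_rep = p_count * p_conf
        p_in_set = 1.0 - (1.0 - p_rep) ** config.design.n_replicates
        membership[condition] = p_in_set >= 0.5
        if site.occupancy.get(condition, 0.0) > 0.0:
            p_star_rep = max(p_star_rep, p_count)

    members = {c for c, m in membership.items() if m}
    label, unique = classify_membership(members, config.design)
    starred = False
    if label == "condition_unique":
        n = config.design.n_replicates
        # P(detected in >= 2 of n replicates), detection = count criterion
        p = p_star_rep
        p_ge2 = sum(
            math.comb(n, k) * p ** k * (1 - p) ** (n - k) for k in range(2, n + 1)
        )
        starred = p_ge2 >= 0.5
    return membership, label, starred


def simulate_psm_dataset(
    config: SimulationConfig,
    protein: ProteinRecord,
    plan: tuple[PlannedSite, ...],
    rng: np.random.Generator | None = None,
) -> tuple[list[PsmRecord], pd.DataFrame]:
    """Draw the PSM table and its ground-truth table.

    Peptide abundances are log-normal and fixed across conditions and
    replicates; spectral counts per (peptide, condition, replicate) are
    Poisson with the abundance as rate, globally scaled so the mean
    per-residue depth hits ``config.mean_depth``.  Peptides containing a
    planted site have their abundance floored at the log-normal median so
    planted sites sit in regions of at least typical coverage.  Each PSM
    covering a planted site carries a phospho at that site with probability
    equal to the site's occupancy in the PSM's condition; confidences come
    from the true-site Beta.  Decoy phosphos land on random S/T/Y residues
    at ``decoy_rate`` with low-confidence draws.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if any(s.residue_index is None for s in plan):
        raise ValueError("site plan must be resolved (use simulate_protein)")

    spans = digest(protein.sequence, config.max_missed, config.min_len,
                   config.max_len)
    site_pos = {s.residue_index: s for s in plan}
    for s in plan:
        if not any(sp.covers(s.residue_index) for sp in spans):
            raise ValueError(f"planted site {s.residue_index} is not coverable")

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma,
                              size=len(spans))
    for i, sp in enumerate(spans):
        if any(sp.covers(p) for p in site_pos):
            abundance[i] = max(abundance[i], 1.0)
    residue_mass = sum(a * len(sp) for a, sp in zip(abundance, spans))
    scale = config.mean_depth * config.protein_length / residue_mass
    lam = abundance * scale

    # expected per-replicate depth at each planted site
    expected_depth = {
        p: float(sum(l for l, sp in zip(lam, spans) if sp.covers(p)))
        for p in site_pos
    }

    a_t, b_t = config.true_conf_beta
    a_d, b_d = config.decoy_conf_beta
    psms: list[PsmRecord] = []
    for condition in config.design.conditions:
        for replicate in config.design.replicates:
            counts = rng.poisson(lam)
            for sp, n in zip(spans, counts):
                covered_sites = [
                    site_pos[p] for p in site_pos if sp.covers(p)
                ]
                sty = [
                    i + 1 for i, aa in enumerate(sp.sequence) if aa in "STY"
                ]
                for _ in range(int(n)):
                    mods: list[ModObservation] = []
                    taken: set[int] = set()
                    for site in covered_sites:
                        occ = site.occupancy.get(condition, 0.0)
                        if occ > 0.0 and rng.random() < occ:
                            pep_pos = site.residue_index - sp.start + 1
                            conf = round(100.0 * rng.beta(a_t, b_t), 2)
                            mods.append(ModObservation(
                                site.residue_class, pep_pos, "Phospho", conf
                            ))
                            taken.add(pep_pos)
                    if sty and rng.random() < config.decoy_rate:
                        free = [p for p in sty if p not in taken]
                        if free:
                            pep_pos = int(free[rng.integers(len(free))])
                            conf = round(100.0 * rng.beta(a_d, b_d), 2)
                            mods.append(ModObservation(
                                sp.sequence[pep_pos - 1], pep_pos,
                                "Phospho", conf,
                            ))
                    if "M" in sp.sequence and rng.random() < config.oxidation_rate:
                        pep_pos = sp.sequence.index("M") + 1
                        mods.append(ModObservation("M", pep_pos, "Oxidation"))
                    mods.sort(key=lambda m: m.peptide_position)
                    psms.append(PsmRecord(
                        sample_id=f"{condition}_r{replicate}",
                        condition=condition,
                        replicate=replicate,
                        peptide_sequence=sp.sequence,
                        protein_accession=protein.accession,
                        mods=tuple(mods),
                    ))

    rows = []
    for site in plan:
        membership, label, starred = _expected_truth(
            site, expected_depth[site.residue_index], config
        )
        row = {
            "residue_index": site.residue_index,
            "residue_class": site.residue_class,
            "expected_classification": label,
            "expected_starred": starred,
        }
        for c in config.design.conditions:
            row[f"occupancy_{c}"] = site.occupancy.get(c, 0.0)
            row[f"expected_in_set_{c}"] = membership[c]
        rows.append(row)
    truth = pd.DataFrame(rows).sort_values("residue_index").reset_index(drop=True)
    return psms, truth


def simulate_interactor_counts(
    baselines: dict[str, float],
    multipliers: dict[str, dict[str, float]],
    design: ExperimentDesign,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson replicate counts around baseline x condition multiplier.

    ``multipliers[acc][condition]`` defaults to 1.0 when missing; the
    reference condition's multiplier is forced to 1 so simulated fold
    changes are interpretable against it.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    rows = []
    for acc, base in baselines.items():
        mult = dict(multipliers.get(acc, {}))
        mult[design.reference_condition] = 1.0
        for condition in design.conditions:
            m = mult.get(condition, 1.0)
            for r in design.replicates:
                rows.append({
                    "protein_accession": acc,
                    "condition": condition,
                    "replicate": r,
                    "psm_count": int(rng.poisson(base * m)),
                })
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ProteinRecord, tuple[PlannedSite, ...], list[PsmRecord], pd.DataFrame]:
    """Convenience: protein + resolved plan + PSMs + truth from one config."""
    rng = np.random.default_rng(config.seed)
    protein, plan = simulate_protein(config, rng)
    psms, truth = simulate_psm_dataset(config, protein, plan, rng)
    return protein, plan, psms, truth
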
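from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from phosphostate import (
    FilterThresholds,
    SiteObservation,
    classify_membership,
    classify_sites,
    condition_site_set,
    default_design,
    extract_site_observations,
    map_psms,
    qualifies,
    site_averages,
    venn_counts,
)
from phosphostate.io import ProteinRecord

from conftest import make_psm
from oracles import brute_force_condition_sets

DESIGN = default_design()
T = FilterThresholds()


def obs(residue=10, condition="DMSO", replicate=1, count=0, conf=None,
        letter="S", total=0):
    return SiteObservation(residue, letter, condition, replicate, count, conf,
                          total)


def obs_table(counts_by_rep, condition="DMSO", conf=99.0, residue=10):
    """Observations for one residue/condition; conf applies where count > 0."""
    return [
        obs(residue, condition, r, c, conf if c > 0 else None)
        for r, c in zip(DESIGN.replicates, counts_by_rep)
    ]


class TestQualifies:
    @pytest.mark.parametrize(
        "count,conf,expected",
        [
            (2, 80.0, True),
            (2, 75.0, False),   # strict > at the boundary
            (2, 75.01, True),
            (1, 99.0, False),   # too few phospho-PSMs
            (0, None, False),
            (3, None, False),   # evidence without confidence never qualifies
        ],
    )
    def test_filter_boundaries(self, count, conf, expected):
        assert qualifies(obs(count=count, conf=conf), T) is expected


class TestConditionSiteSet:
    def test_union_over_replicates(self):
        sets = condition_site_set(obs_table([2, 0, 0], conf=80.0), T, DESIGN)
        assert sets["DMSO"] == {10}

    def test_no_single_replicate_reaches_two(self):
        sets = condition_site_set(obs_table([1, 1, 1]), T, DESIGN)
        assert sets["DMSO"] == set()

    def test_all_zero_not_in_set(self):
        sets = condition_site_set(obs_table([0, 0, 0]), T, DESIGN)
        assert sets["DMSO"] == set()

    def test_pooled_mode_sums_replicates(self):
        table = obs_table([1, 1, 1])
        assert condition_site_set(table, T, DESIGN, "pooled")["DMSO"] == {10}

    def test_tightening_thresholds_never_grows_sets(self):
        rng = np.random.default_rng(11)
        table = [
            obs(int(rng.integers(1, 20)), c, r,
                int(rng.integers(0, 5)), float(rng.uniform(0, 100)))
            for c in DESIGN.conditions
            for r in DESIGN.replicates
            for _ in range(10)
        ]
        loose = condition_site_set(table, FilterThresholds(50.0, 1), DESIGN)
        tight = condition_site_set(table, FilterThresholds(90.0, 3), DESIGN)
        for condition in DESIGN.conditions:
            assert tight[condition] <= loose[condition]

    @given(
        rows=hst.lists(
            hst.tuples(
                hst.integers(1, 8),                       # residue
                hst.sampled_from(DESIGN.conditions),
                hst.integers(1, 3),                       # replicate
                hst.integers(0, 4),                       # count
                hst.one_of(hst.none(),
                           hst.sampled_from([10.0, 74.9, 75.0, 75.1, 99.0])),
            ),
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_per_triple_oracle(self, rows):
        table = [obs(res, c, r, n, cf) for res, c, r, n, cf in rows]
        got = condition_site_set(table, T, DESIGN)
        expected = brute_force_condition_sets(
            [(o.residue_index, o.condition, o.replicate, o.phospho_psm_count,
              o.best_confidence) for o in table],
            list(DESIGN.conditions), T.min_confidence_percent,
            T.min_phospho_psms,
        )
        assert got == expected


class TestExtractAndAverages:
    PROTEIN = ProteinRecord("P1", "MELTSKAQSTYRSPELTTPKSSYMELTAGRMELTSQWEYK")

    def test_counts_and_best_confidence(self):
        # two phospho-PSMs at T17 in (STLC, rep 1) with different confidences
        psms = [
            make_psm("ELTTPK", "STLC", 1, [(3, 99.1)]),
            make_psm("ELTTPK", "STLC", 1, [(3, 80.0)]),
        ]
        mapped, _ = map_psms(psms, self.PROTEIN)
        observations = extract_site_observations(mapped, DESIGN)
        hit = [o for o in observations
               if o.residue_index == 17 and o.condition == "STLC"
               and o.replicate == 1]
        assert hit[0].phospho_psm_count == 2
        assert hit[0].best_confidence == 99.1

    def test_zero_observations_synthesized_for_other_cells(self):
        psms = [make_psm("ELTTPK", "STLC", 1, [(3, 99.1)])]
        mapped, _ = map_psms(psms, self.PROTEIN)
        observations = extract_site_observations(mapped, DESIGN)
        # every (condition, replicate) cell of the design is present
        assert len(observations) == len(DESIGN.conditions) * DESIGN.n_replicates
        zeros = [o for o in observations if o.phospho_psm_count == 0]
        assert len(zeros) == len(observations) - 1

    def test_one_psm_with_two_sites_counts_once_per_site(self):
        psms = [make_psm("AQSTYR", "DMSO", 1, [(3, 95.0), (5, 91.0)])]
        mapped, _ = map_psms(psms, self.PROTEIN)
        observations = extract_site_observations(mapped, DESIGN)
        by_site = {
            o.residue_index: o.phospho_psm_count
            for o in observations
            if o.condition == "DMSO" and o.replicate == 1
        }
        assert by_site == {9: 1, 11: 1}

    def test_total_psms_at_position_from_depth(self):
        psms = [
            make_psm("ELTTPK", "STLC", 1, [(3, 99.1)]),
            make_psm("ELTTPK", "STLC", 1),
            make_psm("ELTTPK", "STLC", 1),
        ]
        mapped, _ = map_psms(psms, self.PROTEIN)
        from phosphostate import per_position_depth

        depth = {("STLC", 1): per_position_depth(mapped, len(self.PROTEIN))}
        observations = extract_site_observations(mapped, DESIGN, depth)
        hit = [o for o in observations
               if o.residue_index == 17 and o.condition == "STLC"
               and o.replicate == 1][0]
        assert hit.phospho_psm_count == 1
        assert hit.total_psm_count_at_position == 3

    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 0, 0), 2 / 3), ((24, 24, 24), 24.0), ((17, 17, 17), 17.0)],
    )
    def test_average_includes_zeros_ignores_filter(self, counts, expected):
        averages = site_averages(obs_table(list(counts), conf=10.0), DESIGN)
        assert averages[(10, "DMSO")] == pytest.approx(expected)
        # matches the report's 2-decimal convention, e.g. 0.67
        assert round(averages[(10, "DMSO")], 2) == round(expected, 2)

    def test_average_times_replicates_is_integer(self):
        rng = np.random.default_rng(5)
        counts = [int(rng.integers(0, 9)) for _ in range(3)]
        averages = site_averages(obs_table(counts), DESIGN)
        value = averages[(10, "DMSO")] * DESIGN.n_replicates
        assert value == pytest.approx(round(value))


class TestClassification:
    def sets(self, **kwargs):
        base = {c: set() for c in DESIGN.conditions}
        base.update(kwargs)
        return base

    def observations_for(self, residue, per_condition_counts, conf=99.0):
        out = []
        for condition, counts in per_condition_counts.items():
            out.extend(obs_table(counts, condition, conf, residue))
        return out

    def test_shared_all(self):
        sets = self.sets(**{c: {5} for c in DESIGN.conditions})
        observations = self.observations_for(5, {c: [2, 2, 2] for c in DESIGN.conditions})
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.classification == "shared_all"
        assert not summary.starred

    def test_arrested_shared(self):
        sets = self.sets(nocodazole={5}, paclitaxel={5}, STLC={5})
        observations = self.observations_for(
            5, {c: [2, 2, 2] for c in DESIGN.arrested_conditions}
        )
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.classification == "arrested_shared"

    def test_condition_unique_with_full_replication_is_starred(self):
        sets = self.sets(STLC={5})
        observations = self.observations_for(5, {"STLC": [2, 3, 2]})
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.classification == "condition_unique"
        assert summary.unique_condition == "STLC"
        assert summary.starred

    def test_unique_in_two_of_three_replicates_is_starred(self):
        sets = self.sets(nocodazole={5})
        observations = self.observations_for(5, {"nocodazole": [2, 2, 0]})
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.starred

    def test_unique_in_one_replicate_is_not_starred(self):
        sets = self.sets(STLC={5})
        observations = self.observations_for(5, {"STLC": [3, 0, 0]})
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.classification == "condition_unique"
        assert not summary.starred

    def test_partial_overlap_is_other(self):
        sets = self.sets(DMSO={5}, STLC={5})
        observations = self.observations_for(5, {"DMSO": [2, 0, 0],
                                                 "STLC": [2, 0, 0]})
        (summary,) = classify_sites(sets, DESIGN, observations)
        assert summary.classification == "other"

    def test_labels_partition_the_union(self):
        rng = np.random.default_rng(7)
        sets = {
            c: set(rng.choice(30, size=10, replace=False).tolist())
            for c in DESIGN.conditions
        }
        observations = []
        for condition, members in sets.items():
            for residue in members:
                observations.extend(
                    obs_table([2, 2, 2], condition, 99.0, residue)
                )
        summaries = classify_sites(sets, DESIGN, observations)
        union = set().union(*sets.values())
        assert {s.residue_index for s in summaries} == union
        for s in summaries:
            assert s.classification in {
                "shared_all", "arrested_shared", "condition_unique", "other",
            }

    def test_membership_rule_is_exhaustive_and_exclusive(self):
        for k in range(len(DESIGN.conditions) + 1):
            for combo in itertools.combinations(DESIGN.conditions, k):
                label, unique = classify_membership(set(combo), DESIGN)
                if set(combo) == set(DESIGN.conditions):
                    assert label == "shared_all"
                elif set(combo) == set(DESIGN.arrested_conditions):
                    assert label == "arrested_shared"
                elif len(combo) == 1:
                    assert label == "condition_unique" and unique == combo[0]
                else:
                    assert label == "other"


class TestVenn:
    def test_two_set_partition(self):
        sets = {"A": {1, 2}, "B": {2, 3}}
        cells, total = venn_counts(sets)
        assert cells == {("A",): 1, ("B",): 1, ("A", "B"): 1}
        assert total == 3

    def test_identical_sets_all_in_full_intersection(self):
        sets = {c: {1, 2, 3} for c in DESIGN.conditions}
        cells, total = venn_counts(sets)
        assert cells == {tuple(DESIGN.conditions): 3}
        assert total == 3

    def test_disjoint_sets_have_no_intersection_cells(self):
        sets = {"A": {1}, "B": {2}, "C": {3}}
        cells, _ = venn_counts(sets)
        assert all(len(pattern) == 1 for pattern in cells)

    @given(
        memberships=hst.lists(
            hst.sets(hst.sampled_from(DESIGN.conditions), min_size=1),
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_cells_sum_to_union(self, memberships):
        sets: dict[str, set[int]] = {c: set() for c in DESIGN.conditions}
        for residue, member_conditions in enumerate(memberships, start=1):
            for c in member_conditions:
                sets[c].add(residue)
        cells, total = venn_counts(sets)
        assert sum(cells.values()) == total == len(memberships)
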
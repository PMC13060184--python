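from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phosphostate import (
    default_design,
    fold_change_matrix,
    psm_count_table,
    simulate_interactor_counts,
)

from conftest import make_psm

DESIGN = default_design()


def counts_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein_accession", "condition", "replicate",
                       "psm_count"],
    )


def constant_counts(acc, per_condition):
    rows = []
    for condition, value in per_condition.items():
        for r in DESIGN.replicates:
            rows.append((acc, condition, r, value))
    return counts_frame(rows)


class TestFoldChange:
    def test_pseudocount_formula(self):
        counts = constant_counts("NDC80", {"DMSO": 4, "nocodazole": 24})
        matrix = fold_change_matrix(counts, DESIGN)
        assert matrix.fold_change("NDC80", "nocodazole") == pytest.approx(5.0)

    def test_reference_fold_change_is_exactly_one(self):
        counts = constant_counts("BUB1", {c: 7 for c in DESIGN.conditions})
        matrix = fold_change_matrix(counts, DESIGN)
        assert matrix.fold_change("BUB1", "DMSO") == 1.0

    def test_zero_reference_gives_avg_plus_one(self):
        counts = constant_counts("TTK", {"DMSO": 0, "STLC": 4})
        matrix = fold_change_matrix(counts, DESIGN)
        assert matrix.fold_change("TTK", "STLC") == pytest.approx(5.0)

    def test_missing_replicates_count_as_zero(self):
        # one replicate at 6 PSMs, two absent -> average 2
        counts = counts_frame([("BUB3", "STLC", 1, 6), ("BUB3", "DMSO", 1, 0)])
        matrix = fold_change_matrix(counts, DESIGN)
        assert matrix.fold_change("BUB3", "STLC") == pytest.approx(3.0)

    def test_equal_counts_everywhere_give_unit_fold_changes(self):
        counts = constant_counts("ZW10", {c: 11 for c in DESIGN.conditions})
        matrix = fold_change_matrix(counts, DESIGN)
        assert (matrix.table.fold_change == 1.0).all()

    def test_monotone_in_condition_and_reference_average(self):
        low = fold_change_matrix(
            constant_counts("X", {"DMSO": 4, "STLC": 10}), DESIGN
        ).fold_change("X", "STLC")
        higher_condition = fold_change_matrix(
            constant_counts("X", {"DMSO": 4, "STLC": 14}), DESIGN
        ).fold_change("X", "STLC")
        higher_reference = fold_change_matrix(
            constant_counts("X", {"DMSO": 8, "STLC": 10}), DESIGN
        ).fold_change("X", "STLC")
        assert higher_condition > low > higher_reference

    def test_invariant_to_replicate_order(self):
        rows = [("X", "DMSO", r, c) for r, c in zip((1, 2, 3), (2, 5, 8))]
        rows += [("X", "STLC", r, c) for r, c in zip((1, 2, 3), (9, 0, 3))]
        shuffled = rows[::-1]
        a = fold_change_matrix(counts_frame(rows), DESIGN)
        b = fold_change_matrix(counts_frame(shuffled), DESIGN)
        assert a.fold_change("X", "STLC") == b.fold_change("X", "STLC")

    def test_per_replicate_stage_averages_ratios(self):
        rows = [("X", "DMSO", r, c) for r, c in zip((1, 2, 3), (1, 3, 4))]
        rows += [("X", "STLC", r, c) for r, c in zip((1, 2, 3), (9, 3, 4))]
        matrix = fold_change_matrix(
            counts_frame(rows), DESIGN, pseudocount_stage="per_replicate"
        )
        expected = np.mean([10 / 2, 4 / 4, 5 / 5])
        assert matrix.fold_change("X", "STLC") == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fold_change_matrix(counts_frame([("X", "DMSO", 1, -1)]), DESIGN)


class TestPsmCountTable:
    def test_counts_by_protein_condition_replicate(self):
        psms = [
            make_psm("PEPTIDEK", "DMSO", 1, accession="A"),
            make_psm("PEPTIDEK", "DMSO", 1, accession="A"),
            make_psm("PEPTIDEK", "STLC", 2, accession="B"),
        ]
        table = psm_count_table(psms, DESIGN)
        lookup = {
            (r.protein_accession, r.condition, r.replicate): r.psm_count
            for r in table.itertuples(index=False)
        }
        assert lookup[("A", "DMSO", 1)] == 2
        assert lookup[("B", "STLC", 2)] == 1
        assert lookup[("A", "STLC", 2)] == 0  # absent cells filled with zero

    def test_panel_restricts_and_orders(self):
        psms = [make_psm("PEPTIDEK", accession=a) for a in ("A", "B", "C")]
        table = psm_count_table(psms, DESIGN, panel=["C", "A"])
        assert list(dict.fromkeys(table.protein_accession)) == ["C", "A"]


class TestSimulatedInteractors:
    def test_unit_multipliers_give_unit_fold_changes(self):
        rng = np.random.default_rng(1)
        counts = simulate_interactor_counts(
            {f"P{i}": 60.0 for i in range(8)}, {}, DESIGN, rng
        )
        matrix = fold_change_matrix(counts, DESIGN)
        non_reference = matrix.table[matrix.table.condition != "DMSO"]
        assert non_reference.fold_change.mean() == pytest.approx(1.0, abs=0.1)

    def test_five_fold_multiplier_recovered(self):
        rng = np.random.default_rng(2)
        counts = simulate_interactor_counts(
            {f"P{i}": 40.0 for i in range(10)},
            {f"P{i}": {"STLC": 5.0} for i in range(10)},
            DESIGN, rng,
        )
        matrix = fold_change_matrix(counts, DESIGN)
        stlc = matrix.table[matrix.table.condition == "STLC"]
        # (5b+1)/(b+1) = 4.90 at baseline 40; sampling band around it
        assert stlc.fold_change.mean() == pytest.approx(4.90, abs=0.45)

    def test_zero_baseline_pseudocount_dominates(self):
        rng = np.random.default_rng(3)
        counts = simulate_interactor_counts(
            {"GHOST": 0.0}, {"GHOST": {"STLC": 7.0}}, DESIGN, rng
        )
        matrix = fold_change_matrix(counts, DESIGN)
        assert matrix.fold_change("GHOST", "STLC") == pytest.approx(1.0)
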
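"""MELT-motif phosphorylation counts and interactor fold changes.

Scans a toy bait for degenerate MELT-class motifs ([M/I/L/V][E/D][M/I/L/V]T,
acceptor = the T), counts how many are phosphorylated per condition, then
computes pseudocount fold changes for two simulated interactors.
"""

import numpy as np

import phosphostate as ph

design = ph.default_design()

protein = ph.ProteinRecord(
    "TOY", "AAMELTAAAIDLTAAAVEVTAAAMDLTAAASSSKAAMELTAA"
)
motifs = ph.scan_motifs(protein)
print(f"{len(motifs)} MELT-class motifs found:")
for m in motifs:
    window = protein.sequence[m.start - 1 : m.end]
    print(f"  {m.motif_id}: {window} at {m.start}-{m.end}, "
          f"acceptor T{m.acceptor_position}")

# suppose site sets from the phospho analysis hit some acceptors
sets = {
    "DMSO": {motifs[0].acceptor_position},
    "nocodazole": {m.acceptor_position for m in motifs[:3]},
    "paclitaxel": {m.acceptor_position for m in motifs[:3]},
    "STLC": {m.acceptor_position for m in motifs},
}
per_condition, overall = ph.phosphorylated_motif_counts(sets, motifs)
print("\nphosphorylated motifs per condition:", per_condition)
print(f"distinct motifs phosphorylated anywhere: {overall}/{len(motifs)}")

# interactors: Poisson counts around baseline x condition multiplier
counts = ph.simulate_interactor_counts(
    {"NDC80": 40.0, "BUB1": 25.0},
    {"NDC80": {"nocodazole": 5.0, "paclitaxel": 4.0, "STLC": 5.0},
     "BUB1": {"nocodazole": 2.0, "paclitaxel": 2.0, "STLC": 2.5}},
    design, np.random.default_rng(1),
)
matrix = ph.fold_change_matrix(counts, design)
print("\nfold change vs DMSO, (avg PSMs + 1)/(avg reference PSMs + 1):")
for row in matrix.table.itertuples(index=False):
    print(f"  {row.protein_accession:>6} {row.condition:>11}: "
          f"avg {row.avg_psms:6.2f}  FC {row.fold_change:5.2f}")
# the reference condition's fold change is exactly 1 by construction; the
# pseudocount keeps ratios finite for proteins absent from the reference.
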
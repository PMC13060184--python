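"""Site qualification, averaging, and cross-condition classification.

Builds a handful of per-replicate site observations by hand and shows how
the filter (>75% confidence, >=2 phospho-PSMs, union over replicates), the
zero-inclusive averages, and the shared/arrested/unique labels behave.
"""

import phosphostate as ph

design = ph.default_design()
thresholds = ph.FilterThresholds()  # >75% confidence, >=2 phospho-PSMs


def observations(residue, letter, counts_by_condition, conf=95.0):
    out = []
    for condition, counts in counts_by_condition.items():
        for replicate, count in zip(design.replicates, counts):
            out.append(ph.SiteObservation(
                residue, letter, condition, replicate, count,
                conf if count else None,
            ))
    return out


obs = []
# qualifies everywhere: high counts in every condition
obs += observations(32, "S", {c: (17, 18, 16) for c in design.conditions})
# arrest-specific: nothing in the vehicle, solid counts in the three arrests
obs += observations(765, "S", {
    "DMSO": (0, 0, 0), "nocodazole": (5, 4, 6),
    "paclitaxel": (4, 4, 5), "STLC": (6, 5, 4),
})
# unique to one treatment, replicated -> starred
obs += observations(1115, "T", {
    "DMSO": (0, 0, 0), "nocodazole": (0, 0, 0),
    "paclitaxel": (0, 0, 0), "STLC": (3, 2, 2),
})
# two phospho-PSMs in a single replicate only: in the set, but not starred
obs += observations(207, "S", {
    "DMSO": (0, 0, 0), "nocodazole": (2, 0, 0),
    "paclitaxel": (0, 0, 0), "STLC": (0, 0, 0),
})
# never reaches 2 phospho-PSMs in any single replicate: filtered out
obs += observations(999, "T", {c: (1, 1, 1) for c in design.conditions})

sets = ph.condition_site_set(obs, thresholds, design)
print("qualifying sites per condition:")
for condition, members in sets.items():
    print(f"  {condition:>11}: {sorted(members)}")

summaries = ph.classify_sites(sets, design, obs)
averages = ph.site_averages(obs, design)
print("\nclassification and zero-inclusive averages:")
for s in summaries:
    avg = {c: round(averages[(s.residue_index, c)], 2)
           for c in design.conditions}
    star = " *" if s.starred else ""
    print(f"  {s.residue_letter}{s.residue_index}: {s.classification}{star}  "
          f"avg phospho-PSMs {avg}")
# S32 averages ~17 per condition (shared by all); T1115 is STLC-unique and
# starred because its evidence repeats in >=2 replicates; S207's single
# qualifying replicate keeps it in the set but unstarred; site 999 never
# appears because no single replicate reached 2 phospho-PSMs.
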
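"""Tryptic digestion and per-residue coverage on a small protein.

Digests a toy sequence under the Keil rule (no cleavage before proline),
maps a few observed peptides back onto it, and prints the depth vector and
coverage summary — the same statistics the pipeline reports per replicate.
"""

import phosphostate as ph

protein = ph.ProteinRecord("TOY", "MELTSKAQSTYRSPELTTPKSSYMELTAGRMELTSQWEYK")

spans = ph.digest(protein.sequence, max_missed=1, min_len=4, max_len=30)
print("tryptic peptides (start-end, missed cleavages):")
for s in spans:
    print(f"  {s.start:>2}-{s.end:<2} mc={s.missed_cleavages}  {s.sequence}")

psms = []
for peptide, n in [("AQSTYR", 3), ("ELTTPK", 2), ("MELTSQWEYK", 1)]:
    for i in range(n):
        psms.append(ph.PsmRecord(
            sample_id="demo", condition="DMSO", replicate=1,
            peptide_sequence=peptide, protein_accession="TOY",
        ))
mapped, report = ph.map_psms(psms, protein)
depth = ph.per_position_depth(mapped, len(protein))
stats = ph.coverage_stats(depth)

print("\ndepth per residue:", depth.tolist())
print(f"coverage: {stats.percent_coverage:.2f}% of residues seen; "
      f"mean depth where covered: {stats.mean_depth_covered:.2f}")
# 6 PSMs over three peptides: coverage counts residues hit at least once,
# depth averages only over those residues.
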
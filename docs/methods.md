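# Methods

## Scope and model

`phosphostate` is a downstream analysis for single-bait AP-MS
phospho-profiling.  Its input contract begins *after* the database search:
one row per peptide-spectrum match (PSM), carrying the peptide sequence,
the declared protein accession, the condition and replicate it came from,
and zero or more modification observations, each with an opaque
localization confidence in percent.  Spectra, mass accuracy, retention
time and search scoring are out of scope; the table is assumed
FDR-controlled upstream (rows with an explicit `peptide_fdr` above the
configured threshold, default 1%, are dropped and counted; rows without
one are assumed pre-filtered).

Spectral counts are treated as a semi-quantitative abundance proxy
throughout.  No statistical test is attached to any comparison — the
outputs are counts, averages, set memberships and pseudocount ratios, in
line with how this class of experiment is reported.

## Digestion and mapping

The theoretical digest cleaves C-terminal to K/R except before proline
(Keil rule, the default of mainstream search engines), with up to
`max_missed` retained internal sites (default 2) and a length filter
(default 6–50 for listings).  The digest is used for coverage expectations
and simulation only: observed peptides are placed by exact substring
search, so semi-tryptic evidence is never discarded by theory.  I/L are
distinct.  Peptides matching the bait more than once are handled by
policy — `first` (default, logged), `all` (flagged multi-mapped), or
`drop` — keeping the mapping deterministic and auditable.  An absolute
phospho position is `span_start + peptide_position − 1`, and the protein
letter at that position must equal the modification's residue letter
(validated at parse time).

## Coverage

Depth at residue *i* is the number of mapped PSM spans containing *i*.
Percent coverage is over all residues; **mean depth is averaged over
covered residues only**.  The alternative (dividing by full length) would
scale values by roughly the coverage fraction; the covered-only reading is
the one under which a paired "coverage %, depth" summary is coherent, and
it is the package's fixed choice.  Statistics are computed per replicate
and then averaged per condition (not pooled), matching how replicate
experiments are reported; report tables round to 2 decimals, internal
values keep full precision.

## Site qualification and classification

Per (residue, condition, replicate), the phospho-PSM count is the number
of PSMs carrying a phospho at that residue, and the replicate's confidence
is the **maximum** across those PSMs (a single well-localized PSM
establishes the site; a per-PSM pre-filter is available as a config
alternative).  A replicate qualifies iff confidence `> 75%` (strict
inequality — a site at exactly 75.0 fails) and count `≥ 2`.  A condition's
site set is the union of qualifying replicates; this per-replicate-then-
union semantics is the default, with a `pooled` switch (sum counts, max
confidence, filter once) for the alternative reading.

Averages are raw means over all declared replicates, zeros included,
independent of qualification — the only convention under which 2
phospho-PSMs in one of three replicates prints as 0.67.  Observations are
therefore zero-synthesized across the whole design for every residue with
any evidence.

Classification of each detected site: `shared_all` (every condition's
set), `arrested_shared` (all arrested conditions' sets and absent from the
reference set), `condition_unique` (exactly one set), else `other`.  The
labels are mutually exclusive and partition the union.  A unique site is
*starred* when it has evidence in ≥2 replicates of its condition;
"evidence" defaults to the count criterion alone (`any_evidence`: count ≥
the configured minimum, confidence not required), with `qualifying` (full
per-replicate filter) as the stricter switch — the star is a
reproducibility mark, not a second confidence filter.

## Motifs

MELT-class motifs are degenerate; the built-in scan uses
`[MILV][ED][MILV]T` with the T as acceptor, non-overlapping left-to-right.
Because no canonical coordinate list is bundled, a user-supplied
`motifs.tsv` is authoritative when present and the scan is a convenience.
A motif counts as phosphorylated in a condition when its acceptor position
is in that condition's site set (`acceptor_only`, default; `any_in_window`
counts any residue in the motif span).  SHT or other motif classes run
through the same engine with a different pattern/offset.

## Interactor fold changes

Per protein: average PSM count over the design's replicates (absent
replicates contribute zero), then `FC = (avg + 1)/(avg_ref + 1)`.  The
pseudocount is applied **after** averaging (the arithmetic-explicit
reading); `pseudocount_stage="per_replicate"` instead averages the
per-replicate ratios `(n_r + 1)/(n_ref,r + 1)`.  The reference condition's
FC is exactly 1 by construction, FC is strictly increasing in the
condition average and decreasing in the reference average, and a protein
absent from the reference gets `FC = avg + 1`.  No control subtraction or
enrichment scoring is performed.

## Synthetic data

The generator emulates the structure of a deep single-bait experiment:

- **Bait**: default 2342 residues with ~10% K/R (so tryptic peptides have
  realistic lengths) and an S/T-rich background.  Planted sites are placed
  at digest-coverable positions whose letter is not K/R/P, so overwriting
  with S/T/Y cannot change the cleavage pattern.
- **Counts**: each tryptic peptide (≤2 missed cleavages, length 6–30)
  gets a log-normal abundance (σ = 0.6) fixed across the experiment;
  per (condition, replicate) spectral counts are Poisson with that rate,
  globally scaled to a target mean per-residue depth (default 20,
  comparable to deep bait coverage).  Peptides containing a planted site
  have their abundance floored at the log-normal median: reported sites
  come from regions the instrument actually sampled, and this guarantees
  planted sites are detectable in their active conditions rather than
  coin-flips at the filter boundary.
- **Phosphorylation**: each PSM covering a planted site carries the
  phospho with probability equal to the site's occupancy in that
  condition.  True-site confidences are 100·Beta(9,1) (≈7.5% of draws fall
  below 75%), decoy placements land on random S/T/Y residues at rate 0.01
  per PSM with 100·Beta(2,4) confidences (≈1.6% above 75%) — the 75%
  threshold separates the two imperfectly, so the filter is genuinely
  exercised.  A 5% methionine-oxidation rate exercises non-phospho
  parsing.
- **Default plan**: 40 sites — 14 shared-all (occupancy 0.6 everywhere),
  14 arrested-shared (0.6 in the three arrest conditions, 0 in vehicle),
  12 condition-unique (0.55 in one condition each, spread over all four).
- **Truth**: expected membership is computed analytically — per replicate
  the site's phospho count is ≈Poisson(expected depth × occupancy), a
  replicate qualifies with probability
  `P(N≥2)·(1 − P(conf≤75%)^2)`, and the condition is expected-in-set when
  the union over replicates exceeds ½.  Expected classification and the
  expected star then use the same membership rules as the pipeline, so
  recovery tests are a round trip, not a re-derivation.

What the simulation does **not** model: spectrum-level identification
error, peptide-level FDR structure, missing-value mechanisms tied to
instrument scheduling, chimeric spectra, isoforms/shared peptides, or
biological covariation between sites.  Passing recovery tests therefore
demonstrates the correctness of the aggregation, filtering and
classification logic under realistic count statistics — not robustness to
every failure mode of real acquisitions.

## Numerical and reporting conventions

All coordinates are 1-based inclusive; modification positions are 1-based
within the peptide.  Confidences are percents (75.0 means 75%), stored as
given.  Report tables: averages and coverage at 2 decimals, fold changes
at 4; rows sort by residue index then design condition order, making
reruns byte-identical.  Schematic binning of per-site averages uses a
closed middle bin: `<5 → low`, `[5, 10] → mid`, `>10 → high` (closing both
ends of the middle bin resolves the boundary ambiguity of a "<5 / 5–10 /
>10" legend).  Empty inputs are defined: an all-zero depth vector reports
0% coverage with the mean-depth flag unset; empty site lists yield
header-only tables.

## Problem sizes

The test suite and acceptance script run the full-scale default
simulation (2342 residues, ~35k PSMs per dataset) over 20 seeds for
recovery statistics, and smaller baits (400–600 residues) for smoke,
determinism and monotonicity checks — sizes chosen so the whole suite
completes in well under a minute per property on one CPU.
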
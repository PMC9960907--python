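# Methods

## Pipeline model

`xlmap` treats a cross-link identification as a Cα–Cα distance restraint and
evaluates, for every PPI-structure pair, how many restraints a static
structure satisfies. The pipeline is: parse cross-link tables and the FASTA
database → read mmCIF structures → align proteins onto chains → resolve sites
to residues → measure distances and classify → score → export. Every stage is
deterministic; two runs on identical inputs and config produce byte-identical
outputs.

Assumptions baked into the model:

- Identifications are taken as given; there is no PSM re-scoring or FDR
  estimation.
- The asymmetric unit as deposited is the evaluation target; no
  biological-assembly expansion.
- Distances are Euclidean Cα–Cα, not solvent-accessible surface distances.
  Cα is the anchor (rather than Cβ or the reactive side-chain atom) because
  it exists for glycine and is the dominant convention for cross-link
  restraint checks; the linker thresholds are calibrated to Cα accordingly.
- Only the first model of multi-model (NMR) entries is used, so each link has
  a single deterministic distance.

## Input normalization

Cross-links are keyed by `(protein_a, pos_a, protein_b, pos_b, linker)` after
canonical lexicographic ordering of the two sites, so duplicates and
orientation-swapped rows collapse deterministically; spectral counts
accumulate over collapsed rows. Sites referencing accessions absent from the
FASTA, or positions beyond the sequence length, are dropped into a rejection
log (TSV: row, reason) rather than silently ignored. pLink2 rows with
multiple slash-separated site assignments are treated as ambiguous
localizations and rejected — guessing among them would fabricate restraints.
No residue-type filter is applied anywhere: site-nonspecific linkers are
first-class, and any position is a legal site.

Positions are 1-based in every user-facing format and converted exactly once
at parse time.

## Structure parsing

mmCIF files are read with gemmi. Author numbering (`auth_asym_id`,
`auth_seq_id` + insertion code) is the user-facing coordinate system because
the exported PyMOL selections must name residues PyMOL can find. Amino-acid
residues only; nonstandard amino acids map to `X`; waters and ligands are
excluded. When a residue carries alternate Cα locations the highest-occupancy
altloc wins, ties resolved to the alphabetically first altloc. A residue
without a Cα stays in the chain sequence (it still participates in alignment)
but can never anchor a distance — mixing anchor atoms would make the
thresholds incoherent.

## Alignment and residue mapping

Each database protein is aligned to each chain with exact Smith–Waterman
under BLOSUM62 and affine gaps (open 11, extend 1, i.e. a gap of length L
costs 11 + L). An exact aligner was chosen over a heuristic external BLAST
call: it removes a binary dependency, is optimal rather than approximate, and
chain-scale sequences are small enough that O(nm) is cheap. Tie-breaking is
pinned so results are reproducible across platforms: among equal-scoring end
cells the smallest target index then smallest query index wins, and the
traceback prefers diagonal over up (gap in target) over left (gap in query).

A chain is accepted when alignment identity ≥ `min_identity` (default 0.9)
and query coverage (aligned span / query length) ≥ `min_coverage` (default
0.3). The high identity default guards against mapping paralogs; the low
coverage default tolerates partial constructs in crystal structures. All
accepted chains are kept — a protein may match several copies in a
homo-oligomer.

## Distance classification

For each link, every combination of (chain copy for site A) × (chain copy for
site B) with present Cα is enumerated and the minimum distance taken: a
restraint needs only one geometrically feasible copy pair. Identical
(chain, residue) self-pairs are excluded so an intra-protein link can never
satisfy itself at distance zero; intra-protein links on multi-copy structures
may be satisfied within one copy or across copies, and the winning chain ids
are recorded so outputs distinguish the two. A link with no valid combination
is `unmapped`; otherwise it is `satisfied` when `d ≤ d_max` and `over_length`
when `d > d_max`.

The default linker table ships DSS, BS3 and DSBU at 30 Å maximum Cα–Cα — the
conventional bound for ~11 Å-spacer lysine-reactive reagents once side-chain
reach and coordinate uncertainty are included. Thresholds are data, not
constants: any TSV of (name, max_ca_distance) replaces the table, and an
unknown linker name is a fatal error rather than a silent default.

## Scoring

Features per pair: `f_sat = n_sat/n_mapped` (0 when nothing maps),
`coverage = n_mapped/n_total`, `violation` = mean relative excess of
over-length links, `evidence = n_mapped/(n_mapped + k)`. The score is

```
score = 100 · evidence · max(0, w_s·f_sat + w_c·coverage − w_v·min(violation, 1))
```

with defaults `w_s=0.7, w_c=0.3, w_v=0.2, k=3` and the constraint
`w_s + w_c = 1` so a perfect pair tends to 100. The functional form was
designed to be transparent, bounded in [0, 100], monotone in each feature in
the scientifically expected direction, and conservative at low evidence: with
`k = 3`, three mapped links reach half the asymptotic confidence, so a pair
supported by one satisfied link scores at most 25. Satisfaction is weighted
above coverage (`w_s > w_c`) because an over-length link is stronger evidence
against a static structure than an unmapped link is evidence of anything.
The violation term is capped at 1 so one grossly over-length link cannot
dominate; beyond 100% relative excess the restraint is simply incompatible
and more excess adds no information. All weights are config keys and are
echoed into the score-file header and run manifest.

## Export and determinism

Outputs are TSV (no quoting ambiguity: no field may contain a tab), written
atomically (temp file + rename) with the tool version and config echo in
leading `#` comment lines. Distances are printed to 3 decimals with
round-half-even: sub-milli-Å digits are numerically meaningless and would
break byte-level reproducibility across platforms. PyMOL scripts select
residues by author chain/residue number (insertion codes included) and `name
CA`, draw one distance object per mapped link, and color by status with
configurable colors.

The run manifest (JSON) records the config echo and the pipeline counts
(proteins, links, PPIs, structures, candidate and scored pairs, rejections,
per-entry structure failures, score histogram in bins of width 5).

## Synthetic scenes

The fixture generator places residues on idealized helical traces (rise
1.5 Å per residue, radius 2.3 Å, 100° twist) with chain axes 12 Å apart, so
site-pair distances sweep smoothly from a few Å past typical linker maxima
and both satisfied and over-length links can be planted with known ground
truth. Chain sequences are independent random 20-letter strings, so each
synthetic protein maps to exactly one chain at the default thresholds and
the minimum-over-copies rule reduces to the planted pair. Planned distances
are computed from coordinates rounded to the 3 decimals the mmCIF text
carries, which is why the pipeline reproduces them to < 1e-6 Å rather than
approximately. Scenes are fully determined by the seed.

What the scenes do **not** emulate: realistic protein geometry, missing
density, paralogous chains, heteroatom noise, or identification error. A
green test suite therefore demonstrates correct bookkeeping, alignment and
geometry — not that real cross-link data will be noise-free.

Default test problem sizes (2–3 chains of 30–40 residues, 8–15 links, ~20
seeds) keep the whole suite around ten seconds while exercising every code
path; the pipeline itself scales linearly in candidate pairs and has no
per-size constants tuned to these fixtures.

## Numerical and degenerate-input choices

- Alignment scores are integers; no floating-point ties exist in the DP.
- An empty FASTA, an empty linker table, a structure set with no survivors,
  or invalid score weights are fatal; malformed rows, unparseable structure
  files and unmappable links degrade gracefully into logs and rejection
  counts.
- `n_mapped = 0` yields features `(0, 0, 0)` and score 0 by construction, not
  by special-casing the formula (evidence is 0).
- Gzipped mmCIF is accepted; entries are identified by file stem, lowercased.

## Known limitations

- No SIFTS-based UniProt→PDB numbering: residue correspondence comes from
  alignment only, which can mis-map in low-complexity or repeat regions.
- No profile/HMM remote-homology mapping; a structure of a distant homolog
  will simply fail the identity threshold.
- Euclidean Cα–Cα distance can satisfy a link through the protein interior
  that a surface-path (SASD) criterion would reject.
- The score is a designed summary statistic, not a calibrated probability;
  comparisons are meaningful within a run under one weight setting.
- Parallel evaluation (`--jobs N`) re-aligns proteins per pair instead of
  sharing the serial mode's alignment cache; outputs are identical, wall
  time per pair is not.
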
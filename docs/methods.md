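# Methods

This note documents the model behind `abinterface`, the parameters that
matter, the synthetic-data design, and the numerical choices made where the
design was genuinely open.

## Interface definition

A contact is an unordered pair of one antibody atom and one antigen atom with
Euclidean distance ≤ the cutoff, default **5 Å, boundary inclusive**.  Only
non-hydrogen atoms of standard amino-acid residues are eligible: hydrogens
and deuteriums (detected by element, falling back to an atom-name heuristic
when the element column is blank), waters, ions, and heteroresidues without a
standard parent are excluded before any distance is measured.  Distance
cutoffs are a standard, reproducible interface definition; the package also
supports a cutoff sweep (2/3/4/5/6 Å) so the sensitivity of any downstream
statistic to the cutoff can be checked.  Neighbour search uses a k-d tree
(`scipy.spatial.cKDTree`, inclusive at exactly the radius); the test suite
carries a brute-force all-pairs oracle and asserts exact set equality on
random complexes, plus invariance of contact sets under rigid rotation +
translation to 1e-6 Å.

Counting distinguishes **total contacts** from **unique** paratope/epitope
residues (uPR/uER) and atoms (uPA/uEA): a residue or atom mediating many
contacts is counted once in the unique tallies.  All frequency statistics are
computed on unique residues so multi-contact residues do not bias
compositions; the single exception is the paratope×epitope co-occurrence
matrix, which deliberately pools total atom–atom contacts and is then
row-normalized to 100%.

## Structure input

PDB files are parsed with Biopython's `Bio.PDB.PDBParser` and reduced to
lightweight residue/atom records keyed by `(chain_id, seq_id, icode)`.
Choices the input format forces:

- **Alternate locations**: keep the highest-occupancy copy per atom name,
  ties broken by altloc character order (the common convention).
- **Modified residues**: mapped to their standard parent via Biopython's
  extended 3-to-1 table (MSE→MET, PTR→TYR, …); unmappable residues go to the
  solvent store and are never contact-eligible.
- **Antigen chains of exactly 50 residues are proteins** — the peptide
  definition is strictly "< 50 amino acids", and an annotated antigen type
  always wins over the derived one.
- IMGT insertion codes are preserved verbatim and never renumbered; region
  membership is decided by the numeric part alone.

PDB output (round-trip tested) uses a small fixed-column ATOM-record
formatter shared with the synthetic generator, which needs exact control of
occupancy/B-factor columns.

## Packing duplicates and redundancy

Crystal asymmetric units with several co-crystallized copies of the complex
would otherwise count the same interface multiple times; only the copy with
the **lowest mean B-factor** over amino-acid atoms is kept (a lower atomic
displacement indicates the better-ordered copy).  Hydrogens are excluded from
the mean by default, consistent with contact eligibility; a flag
(`--bfactor-include-hydrogens`) flips this.  Ties keep the unit from the
first annotation row — determinism requires a rule.

Redundancy removal clusters VH and VL sequences separately over IMGT
positions ≤ 128 (variable domain only, so crystallized constant domains
cannot inflate similarity).  Clustering is greedy longest-first at an
inclusive 95% identity threshold, with identity defined as identical aligned
positions of a global alignment (match +1, mismatch 0, linear gap −1 via
`Bio.Align.PairwiseAligner`) divided by the shorter sequence's length — the
CD-HIT convention.  CD-HIT's word-filter heuristics may differ marginally on
edge cases; FASTA export and a `.clstr` reader are provided for exact parity
with an external CD-HIT run.  A redundancy family is a set of complexes whose
chains all share clusters (VH and VL both, for Fv); the survivor is chosen by
best resolution, then lowest mean B-factor, then lexicographic structure ID —
a rule chosen for data quality first and determinism always.
Fv and sdAb complexes never share a family, and Fv pairs sharing only one
chain's cluster are both kept.

## Regions, hotspots, secondary structure

IMGT boundaries: CDR1 27–38, CDR2 56–65, CDR3 105–117, variable domain ends
at 128; FR1–FR4 are the complement.  Boundaries are configurable, e.g. an
expanded CDR2 of 55–66, and the CDR-capture fraction (share of pooled uPRs
inside CDR boundaries) is evaluable under any scheme so boundary variants can
be compared on equal terms.

Hotspot tables report, per (domain, IMGT position incl. insertion code), the
background occurrence (complexes where the position exists / group size) and
the conditional uPR frequency (complexes where it is a uPR / complexes where
it exists — never the group size).  Positions present in fewer than 10%
(inclusive) of complexes are omitted, which naturally drops rare CDR
insertions.  Fv denominators count complexes per (domain, position)
independently.

Secondary structure is consumed, not computed: a classic `.dssp` file (read
with `Bio.PDB.DSSP.make_dssp_dict`) or a 2-column `chain:resid → code`
table.  The 8-state codes collapse to three classes: H/G/I → helix, E/B →
strand, T/S/blank → loop; the newer 'P' (polyproline II) also maps to loop,
as it postdates the 3-class scheme.  Residues without codes default to loop
with a dataset-level warning, affecting only the epitope
secondary-structure table.

## Statistics

- **Group averaging** is two-step everywhere: per-complex percentage first,
  then an unweighted mean over complexes — never pooled counts — except the
  co-occurrence matrix (pooled total contacts by design).
- **Bootstrap CIs**: percentile method on the mean, resampling complexes with
  replacement; defaults n_boot = 5000, level = 0.95, seed = 20230131.
  Percentile (not BCa) matches the default of the plotting stacks this kind
  of analysis is usually reported with.  Coverage is verified by simulation
  in the test suite (92–98% acceptance band on normal data).
- **Wu–Kabat variability** of an alignment column is N·k/n_mode (N sequences
  with a residue there, k distinct amino acids, n_mode the modal count);
  absent positions are excluded from N.  Minimum 1, attained exactly on
  conserved columns.
- **Epitope segments**: within each antigen chain, maximal runs of
  consecutive residue numbers among uERs (insertion codes order after their
  base number); multi-chain antigens sum their per-chain runs.
- **Germline mutation rates** consume externally supplied germline
  assignments and report both per-position percentages and a pooled
  aggregate, labelled separately, since either convention is defensible.
- Zero-contact rows of the co-occurrence matrix are emitted as zeros with a
  flag (stable 20×20 shape) rather than dropped.

## Synthetic data

The generator emulates the statistical structure of the real inputs — IMGT
numbering with insertion codes, controllable antigen length, planted
inter-molecular atom pairs at exact distances, co-crystallized unit copies
with shifted B-factors, and families of near-identical variable-domain
sequences — without any chemical realism.  Residues sit on widely separated
planes (hundreds of Å apart); each planted contact is realized at an isolated
site between the planes.  Contact graphs are restricted to components that
are stars (all contacts share an atom; partners fan out along rotating unit
directions) or paths (collinear layout, so non-adjacent cross-side atoms are
≥ 3 edge lengths apart); denser graphs are rejected, because edge lengths
≤ cutoff with all non-adjacent cross pairs beyond the decoy margin are not
realizable in general.  Every emitted geometry is re-verified with an
all-pairs distance check: the contact set at the cutoff must equal the
planted list exactly, and every other cross pair must exceed the decoy margin
(default 8 Å, above the 6 Å sweep maximum).  Planted distances default to
3.5–4.5 Å.  Non-planted compositions are uniform over the 20 amino acids;
planted positions honor an explicit composition so frequency statistics have
known expectations.  Everything is deterministic per seed (byte-identical
files).

What passing on synthetic data does **not** show: real interfaces have
correlated geometry (shape complementarity, secondary-structure context,
multi-contact residues dominating), real B-factor fields are spatially
smooth, and real antibody families have phylogenetic rather than i.i.d.
mutation structure.  The synthetic suite validates the bookkeeping and the
algorithms exactly; scientific conclusions still require real structures.

## Problem sizes

The test suite and the acceptance script run on deliberately small problems:
datasets of 6–30 synthetic structures, 100 random complexes for the
oracle-equivalence check, 300–500 bootstrap-coverage replications at
n_boot = 1000, and clustering over ~13 sequences of length 110.  These sizes
give exact (not asymptotic) checks for the combinatorial stages and tight
binomial bands for the stochastic ones while keeping the whole suite in the
tens of seconds.

## Known limitations

- The internal clusterer reproduces CD-HIT's *definition* of identity, not
  its heuristics; at thresholds far below 0.9 on large datasets the greedy
  order can differ from CD-HIT's.
- Water-mediated-contact counting is an interpretation (oxygen within the
  cutoff of both sides; mediated contacts counted per protein atom); it is
  opt-in and excluded from every headline statistic.
- Biological-assembly records (REMARK 350) and crystallographic symmetry are
  not expanded; units are defined by annotation rows.
- mmCIF input is not supported.
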
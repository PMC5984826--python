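# Methods

This note documents the models, numerical choices and limitations of the
`fidpd` implementation, in the order the pipeline runs them.

## Structure input

PDB files are parsed with a purpose-built fixed-column reader because the
pipeline needs `SITE` records — the curated functional-site lists — which
general-purpose structure libraries do not expose. Conventions: author
numbering + insertion code identifies residues; only the first `MODEL` is
read; for alternate locations the highest-occupancy conformer wins (ties
prefer altloc `A`); water is never a ligand; every other HETATM group is a
ligand, with single atoms whose element is in the configurable metal list
(default Zn, Mg, Mn, Fe, Ca, Na, K, Cu, Ni, Co) flagged metallic;
covalently incorporated modified residues (MSE, SEP, …) are polymer and
map to `X` by default (optionally to the parent letter). `SITE` residues
that do not resolve against a parsed polymer residue are kept but flagged
unresolved, never silently dropped. The writer round-trips coordinates at
the format's 3-decimal precision and emits standard 4-residues-per-line
`SITE` records.

## Interaction classification

Each functional-site residue is scored against every ligand of its
complex; all criteria act on heavy atoms (explicit hydrogens ignored), and
the detectors run in the precedence order covalent/coordinate → H-bond →
electrostatic → π-stack → vdW so that an atom pair contributes to at most
one interaction type.

* **Covalent / coordinate** — d < R_cov(a) + R_cov(b) + 0.5 Å; counted as
  a coordinate bond when the ligand is a metal ion. Covalent radii are a
  classic single-bond table (C 0.77, N 0.75, O 0.73, S 1.05 Å, …) shipped
  as JSON package data so it can be swapped.
* **H-bond** — heavy-atom criterion d(D,A) ≤ 3.9 Å with at least one
  acceptor antecedent AA making the D–A–AA angle ≥ 90°. When the donor has
  ≥ 2 bonded heavy neighbours an idealized 1.0 Å hydrogen is placed along
  the inverted bisector and the classic d(H,A) ≤ 2.5 Å, D–H–A ≥ 90°
  conditions are additionally enforced. The original pipeline delegated
  this to a program that builds theoretical hydrogens; a deterministic
  dictionary-based typing (per-residue donors/acceptors; ligand N donor
  when < 3 heavy neighbours; ligand O always acceptor, donor-capable when
  hydroxyl-like) is reproducible and dependency-free. A pair may count
  once per role (donor and acceptor), matching the "once per role" rule.
* **Electrostatic** — positively charged side-chain N of Arg/His/Lys
  within 4.5 Å of a ligand O that is not a member of any perceived ring,
  plus negatively charged side-chain O of Asp/Glu within 4.5 Å of a ligand
  N. The ring exclusion is applied exactly and only to the ligand-oxygen
  case.
* **π-stacking** — residue aromatic rings are the canonical atom-name
  cycles of Trp (both), Phe, Tyr, His; ligand rings are all simple cycles
  of 3–8 atoms of the distance-based bond graph (edge iff
  d < R_cov + R_cov + 0.5 Å), flagged carbon-dominant when more than half
  the atoms are carbon. A (residue ring, carbon-dominant ligand ring) pair
  is one stack when the centroids are 4.5–7 Å apart and ≥ 3 distinct
  heavy-atom pairs between the rings fall in the same window; no
  orientation test is applied (the ring normal is computed and exposed but
  deliberately unused, following the pair-counting simplification).
* **van der Waals** — d < vdW(a) + vdW(b) + 0.5 Å for pairs not claimed by
  any type above; a counted stack claims all of its ring–ring atom pairs.
  vdW radii are a CHARMM22-derived per-element JSON table (C 1.70, N 1.55,
  O 1.52, S 1.80 Å, …) with an element fallback.

## Subgroup partitioning

Domains of one parent entry are split so that every member pair of a
subgroup satisfies Cα-RMSD < 7 Å **and** sequence similarity > 10.
"Similarity" is interpreted as percent identity over the columns of a
global BLOSUM62 alignment (gap open 10, extend 0.5); the threshold is a
parameter. The RMSD correspondence is the aligned, non-gap, Cα-bearing
positions of that same alignment; pairs with < 20 usable correspondences
are treated as dissimilar. Since the clustering algorithm behind the
published subgroup counts is not specified, a deterministic greedy leader
scheme is used: domains sorted by descending length then id join the first
subgroup whose every member they are compatible with, else found a new
one. This enforces the mutual constraints by construction (verified
pairwise in the tests) at the cost of not being globally optimal.

## Profile modules

Match states are MSA columns with gap fraction ≤ 0.5. Emissions are
observed frequencies with a Laplace pseudocount α = 1 over the 20-letter
alphabet; insert states emit the background. Transitions are counted from
the observed per-row M/I/D state paths with a pseudocount of 0.1 — lighter
than the emission prior because with a full count of 1 a single-sequence
module would pay more for M→M (−1 bit) than a perfectly matching residue
earns (~0.93 bits) and a query identical to the consensus would no longer
align end to end.

Column conservation C reinterprets the four-symbol alignment display
convention (gap / `+` / lowercase / capital) as deterministic column
statistics: C = 4 when all rows are identical and ungapped, 3 when the
modal residue fraction ≥ 0.8, 1 when the fraction of rows in the
BLOSUM62-positive class of the modal residue ≥ 0.5, else 0 (gap-majority
columns are 0). The thresholds are exposed as the natural boundaries of
that scheme; they are a stated reinterpretation, not a published recipe.

S and V annotation maps each member's site positions through the MSA to
match columns, counting hits (S) and summing interaction vectors (V);
sites landing on insert columns are dropped with a warning rather than
reassigned (the alternative was considered and rejected as silently
moving ground truth). Accumulation commutes with member order and
conserves total counts, both property-tested.

Subgroup MSAs are normally an input (aligned FASTA); a built-in
center-star aligner (BLOSUM62 pairwise alignments merged on the center's
coordinates) keeps the pipeline self-contained for fixtures and small
inputs. It is a heuristic and is not intended to replace a real MSA
program on divergent families.

## Scanning and E-values

Queries are aligned to each module by local Viterbi over match/insert/
delete states: entry and exit are free at any match state, match emissions
score log₂(e/q) bits against a uniform background q = 1/20 (`X` scores 0),
insert emissions score 0. Significance is calibrated per module by fitting
a right-tailed Gumbel by maximum likelihood to the Viterbi scores of
decoy sequences (default 200, uniform background, decoy length = query
length, cached per length, seeded reproducibly from the database seed and
module id), giving evalue(s) = n_profiles · exp(−λ(s − μ)), clamped at
10⁻³⁰⁰ so the E-score E = −log₁₀(evalue) is bounded by 300. Base 10 is a
choice (the weighting equations only need "negative logarithm"); rankings
within a hit set are unaffected by the base. Hits with evalue ≤ 10⁻⁵ are
kept, best hit per module; an empty result is the defined no-hit outcome,
which is a success, not an error.

## Prediction

F and I are the hit-weighted annotation sums given in the README. The
scale rule retains residues with F ≥ (M/100)·F_max and selects the
⌈T/100 · retained⌉ highest-F positions (ceiling and ascending-position
tie-breaks are our choices; the selection is invariant to rescaling all
E-scores, which is property-tested). Renormalization of selected F values
to 1–100 is linear (min → 1, max → 100, all-equal → 100); a rank-based
map was the alternative and is not used. Labels are binarized after the
chemical post-filter so that a suppressed component cannot resurface.

## Evaluation

Precision, recall and MCC are computed per target from the per-residue
confusion counts; MCC returns 0 only when a denominator factor vanishes —
the convention is not used to clamp small negative values (one published
table prints 0 where the exact formula gives −0.02; the exact value is
reported here and the macro average is unaffected at printed precision).
Macro averages exclude no-hit targets. PLI recall compares predicted and
structure-derived labels on a (site × interaction-type) cell grid; the
default grid is the predicted true-positive sites × 6 displayed types
(COV, COO, ELE, HBD, HBA, π — vdW excluded, mirroring how the benchmark
tables display it), pooled across targets as Σcorrect/Σtotal. The exact
cell-counting rule behind some published per-target totals is ambiguous,
so the grid construction is configurable.

## Synthetic benchmark

The generator emulates the two inputs the method learns from — families of
homologous domain sequences with designated conserved site columns, and
protein–ligand complexes with interactions planted at specified
geometries — and nothing else. Members are i.i.d. mutants of a random
seed sequence at substitution rate 0.15 per non-conserved position
(defaults: 3 families × 8 members × 60 residues, the sizes used throughout
the tests and the acceptance script; chosen to exercise every code path in
seconds on one CPU). Complexes place the chain on an idealized extended
backbone (Cα every 3.8 Å along x, side chains grown in +y) and plant one
ligand per site whose geometry satisfies exactly one detector's criterion
with ≥ 0.2 Å margin and violates all others; each generated complex is
re-validated against the detectors before it is emitted, and planted
positions must be ≥ 3 residues apart so one plant's ligand cannot graze a
neighbour's side chain. The covalent plant uses a single-sulfur ligand
bonded to Cys SG because for lighter elements the ligand atom cannot clear
the vdW envelope of the side chain's own neighbour.

End-to-end recovery is evaluated with n-top selection at n = planted site
count (the planted columns are equally annotated, so their F values tie;
the fixed-count selection mode is the appropriate protocol for a truth set
of known size, exactly as fixed-count selection is used for catalytic-site
prediction). What passing shows: the pipeline transfers site positions
and interaction types through the profile layer essentially losslessly
when family structure is clean. What it does not show: robustness to
indels and alignment error (the default families are indel-free; an indel
mode exists and exercises insert-column dropping), to folded-backbone
geometry, to noisy or sparse SITE annotation, or to real database scale.

## Known limitations

* The Viterbi/Gumbel scanner is a clean-room profile-HMM implementation;
  scores and E-values are internally calibrated and are not comparable to
  HMMER3 numbers.
* Donor/acceptor typing is dictionary-based and ignores protonation-state
  inference; His is treated as both chargeable and aromatic everywhere.
* Ligand ring perception enumerates simple cycles up to length 8 from a
  distance-based bond graph; macrocycles and exotic bonding are out of
  scope.
* Cross-chain SITE records are handled per chain (positions are mapped on
  the chain being extracted; residues on other chains are logged and
  skipped), since the merging rule for multi-chain sites is unspecified.
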
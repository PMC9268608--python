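# Methods

## Scope

`stereoscreen` implements the analysis layer of a stereoisomer virtual
screen: everything downstream of the docking engine and the MD engine.
Docking itself (grid construction, genetic-algorithm search), MD
simulation (solvation, thermostats, constraint algorithms) and end-point
free-energy methods (MM/GBSA, MM/PBSA) are out of scope; their outputs —
score tables and coordinate trajectories — are this package's inputs.

## Data model

A score table has one row per candidate protein: four stereoisomer
docking scores and one known-inhibitor score (kcal/mol; more negative is
better), a functional group (anti-apoptosis/survival, cell growth and
proliferation, metastasis, signaling), and a subcellular localization
(membrane, cytoplasm, nucleus). The packaged fixture transcribes the
published 60-protein panel. Its group sizes are 7 / 22 / 10 / 21
following the table layout of the source (whose prose counts 21 growth
and 11 metastasis proteins; the table layout is taken as authoritative,
and the discrepancy is recorded here rather than silently resolved).
Localizations are recovered from the published weight column
(3/2/1 ↔ membrane/cytoplasm/nucleus). One PDB code printed as
"5 × 02" is normalized to `5X02`; two protein names with variant
spellings between tables use the score-table spelling.

Interaction profiles map each (protein, ligand) pose to residue sets per
interaction type (π-π stacking, hydrogen bond, π-sulfur, hydrophobic).
Residue identity is the pair (three-letter code, sequence number),
compared case-insensitively on the code. The published inhibitor row
lists Arg459 where other evidence suggests Arg549; the fixture keeps the
printed value — no typo correction at runtime — which makes the
*trans*-(−)/pexidartinib CSF1R overlap exactly 1/6.

## Selection gate

Energy criterion: strict inequality (`isomer < inhibitor`); ties fail,
matching the ordinary reading of "lower than". Site criterion: the
original screen judged binding-site similarity visually; we substitute
the Jaccard index of interacting-residue unions because it is
reproducible, symmetric, bounded in [0,1], and monotone in shared
residues. Default threshold 0.1: with printed residue sets of 2–5
residues, any shared pocket residue passes. Two empty residue sets give
a vacuous similarity of 1.0, flagged in the output. Proteins lacking
interaction data degrade to the energy criterion alone, flagged.

## Rank-and-weight scoring

Competition rank of isomer *i* within a protein: `4 − #{j : s_j < s_i}`.
Tied scores share the max-style rank (e.g. scores −9.90, −9.90 both rank
4 when best); without ties the ranks are exactly {4,3,2,1}. The tie rule
is not stated in the source; max-style sharing is the unique rule
consistent with the published rank rows for proteins with tied scores.
Ranks are invariant under any strictly increasing transformation of the
scores, so the scoring depends only on the within-protein ordering.

Weighted rank = rank × localization weight. Group summaries sum ranks
and weighted ranks per isomer; the preferred isomer is the argmax of the
weighted sums. Ties for the maximum are reported (`tie=True`, all
members listed), never silently broken.

Where the published per-protein rank entries conflict with ranks
recomputed from the published scores (a handful of rows, e.g. the CSF1R
cis ranks), recomputation from scores is authoritative; the published
group sums that do not reconcile with their own per-protein entries are
likewise not reproduced. The headline values this package does
reproduce exactly from the score fixture: growth-group weighted sums 151
(trans-(−)) and 55 (trans-(+)); weighted cells 8 (COX2) and 12 (CSF1R);
preferred isomer trans-(−) in three groups and cis-(+) for metastasis.

## Variability

Per protein we report the n−1 sample variance and its square root for
the four isomer scores. The published per-protein spread values are
labeled "SD" but match the sample *variance* of the tabulated scores
(1.089 for CSF1R, 0.52 for Hsp90b, 0.036 for AKR1B1); both quantities
are therefore exposed under unambiguous names. Two published values do
not reconcile with the tabulated scores at all: cdc25A (printed 0.48,
scores give ≈0.90) and the claim that EGFR has the smallest spread
(scores give ≈2.89, the largest of the shared targets). These are
treated as data inconsistencies, not reproduction targets.

One-way ANOVA across isomers is computed from the textbook between/within
sums of squares with the p-value from the F distribution, significance at
p < 0.01. It requires ≥2 replicates per isomer (per-run docking scores);
with a single score per isomer the within-group variance is undefined and
only the descriptive variance applies. What replicate structure fed the
published ANOVA is unstated, so those p-values are not reproduced.

## Trajectory metrics

Superposition is the least-squares rigid-body (Kabsch) solution via SVD,
with the proper-rotation determinant correction. RMSD uses frame 0 as
default reference; RMSF superposes frames onto the window-mean structure
(two passes: align to the first window frame, build the mean, realign to
it). The protein center of mass is mass-weighted over protein atoms
only, ligand excluded. d(n, state) is the time-mean Cα-to-COM distance
over an analysis window; the source does not say whether Δd used
snapshots or averages, so averaging over the final third of frames (the
equilibrated tail) is this package's documented choice, configurable.
Classification is strict: further iff Δd > 2 Å, closer iff Δd < −2 Å.
An optional residue-number offset maps internal 1-based indices to
author numbering; default 0.

Multi-model PDB and XYZ files are read through MDAnalysis after a cheap
per-MODEL atom-count validation pass that reports the offending frame.
XYZ carries no residue metadata; the convention adopted is one residue
per atom, with the ligand flagged by atom-name match. Atom masses come
from a standard element table (element column if present, else the
leading letter of the atom name, so `CA` in a protein is carbon); unknown
atoms fall back to 12.011 Da with a warning.

## Synthetic generators

Score tables: score(protein, isomer) = base + effect(group, isomer) +
N(0, noise_sd²), rounded to the 0.01 kcal/mol print precision of docking
output; the inhibitor score is base + offset, noiseless. Defaults mirror
the study conditions: base −9 kcal/mol (the panel median), planted
effects of 0.4–1.0 kcal/mol giving trans-(−) the best offset in three
groups and cis-(+) in metastasis (the published conclusion), docking
noise 0.1 kcal/mol, 20 proteins per group, and a localization mix
dominated by cytoplasmic proteins (0.10/0.75/0.15) as in the panel.

Trajectories: a fixed helix-like Cα scaffold (radius 8 Å, rise 1.5 Å,
twist 100° per residue — chosen so residue-to-COM distances are
non-degenerate), isotropic Gaussian jitter per residue (default 0.2 Å),
planted radial displacements for designated residues in the bound state,
and a single-atom ligand drifting away from the protein at a configured
rate. For isotropic jitter of width σ the expected RMSF is σ√3, the
closed form used in recovery tests. Trajectory defaults (50 residues,
300 frames) keep the full suite fast; recovery tests state their own
sizes (up to 5,000 frames).

One integer seed governs each generator; independent streams are derived
per stage tag, so adding a stage never perturbs another's draws.
Identical configs and seeds produce byte-identical output files.

What the generators do **not** emulate: force-field physics, solvent,
correlated residue motions, anisotropic fluctuations, realistic ligand
poses, or score correlations between isomers beyond the planted group
effects. Passing recovery tests therefore demonstrates the correctness
of the statistics pipeline, not the behavior of the method on real
docking or MD output.

## Numerical choices and degenerate inputs

- Variance uses the n−1 denominator throughout; two-pass computation via
  numpy.
- ANOVA with all groups internally constant: F = 0 (p = 1) when means
  agree, F = ∞ (p = 0) otherwise.
- Jaccard of two empty sets: 1.0, flagged vacuous.
- All-equal docking scores rank (4,4,4,4): zero isomers strictly better.
- Report JSON is written with sorted keys and atomic rename, so repeated
  runs on identical inputs are byte-identical and failed runs leave no
  partial output.

## Known limitations

- The site-similarity criterion depends on published residue lists, which
  cover only two proteins in the fixture; all other proteins are gated by
  energy alone.
- The 2 Å Δd threshold and the 0.1 Jaccard threshold are screening
  conventions, not statistical tests; no multiplicity control is applied.
- Group-level preferred-isomer calls inherit whatever bias the group
  composition carries; the weighting scheme is a heuristic for drug
  accessibility, not a physical quantity.
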
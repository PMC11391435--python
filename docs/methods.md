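# Methods

This note records the conventions, defaults and design choices behind
`mdcompare`, and what the synthetic-data tests do and do not establish
about real trajectories.

## Data model and sampling conventions

Coordinates are Cartesian ångströms; times nanoseconds. Residues are
indexed 0-based and contiguously in file order; PDB author numbering is
kept as metadata and used in every report label so that residues can be
cross-referenced with structure-based numbering (e.g. G323, T324).
Multi-model PDB files carry no time information, so frame times are
synthesised at a configurable spacing (default 0.1 ns/frame).

Analyses operate on the final portion of each replicate (default the
last 5/6 of simulated time, i.e. the last 250 ns of a 300 ns run) and on
evenly spaced frame samples: 500 frames for energetics, 5000 for ML
features, 250 for water-bridge scans and 1250 for secondary-structure
fractions, all configurable. Even sampling always includes the first
and last in-window frames and never duplicates frames. Concatenation of
replicates records per-frame provenance so per-replicate statistics
remain recoverable.

## Flexibility

RMSD is computed after Kabsch (SVD) least-squares superposition on a fit
selection that may differ from the measured selection — ligand RMSD is
measured after a protein-backbone fit. RMSF is the root-mean-square
deviation of each Cα from its position in a *fixed reference structure*
(the equilibrated starting structure of the first reference-state
replicate), not from the trajectory mean; a mean-structure mode exists
for comparison but the reference convention is the default because the
downstream ΔRMSF thresholds were calibrated against it. Comparisons
flag residues at |ΔRMSF| ≥ 1 Å (ordered) or ≥ 3 Å (disordered); all
threshold comparisons in the package are inclusive (≥, or strict > only
for the 0.8 importance score, which is quoted as ">0.8").

## Secondary structure

A simplified Kabsch–Sander assignment over four codes {H, E, T, C}:
backbone NH→CO hydrogen bonds from the electrostatic energy model
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond iff
E < −0.5 kcal/mol; two consecutive i→i+4 turns make a helix, reciprocal
or offset bridge patterns make strands, isolated 3/4/5-turns make T,
everything else C. 3₁₀/π helices collapse to H and isolated bridges to
E; π-helix and bend geometry are deliberately out of scope since only
helix/strand/turn fractions are interpreted. Missing amide hydrogens
are reconstructed on the N–H bisector of (N→CA, N→C_prev) at 1.01 Å;
residues missing backbone atoms are assigned C with a warning.

## Hydrogen bonds

A (donor, hydrogen, acceptor) triple passes when the donor–acceptor
distance is ≤ 3.5 Å and the angle between the D→H bond vector and the
D→A vector is ≤ 30° — the out-of-linearity convention of the common
trajectory-analysis tools; only polar atoms (N, O, S, P and hydrogens
bonded to them) participate, and intra-residue pairs are excluded by
default. Occupancy is the percentage of analysed (windowed) frames in
which the specific triple passes. Cross-state comparison tables keep a
triple when it reaches 10 % occupancy in at least one replicate of
either compared state; retained sub-1 % cells are reported but marked.
Histidine tautomers need no special casing: donor/acceptor roles follow
from which ring nitrogen carries the hydrogen in the input topology.
Water bridges require one water H-bonded to a ligand atom and to a
protein atom in the same frame, in either donor/acceptor role on each
leg.

## Energetics

The molecular-mechanics interaction energy between two groups is the
explicit pairwise sum of Coulomb (f = 1389.35458 kJ·mol⁻¹·Å·e⁻²,
relative dielectric ε_r configurable, default 1) and Lennard-Jones
(Lorentz–Berthelot combining) terms, with no cutoff by default. These
defaults favour exact agreement with closed-form and brute-force
oracles; they are not a solvated force-field protocol.

Nonpolar solvation uses the linear SASA model g = γ·SASA + b with
γ = 0.0226778 kJ·mol⁻¹·Å⁻² and b = 3.84928 kJ/mol applied per species
(complex, partner A, partner B), so the binding difference is
γ·ΔSASA − b; a difference-only convention (γ·ΔSASA) is also available.
SASA is an in-package Shrake–Rupley implementation (default probe
1.4 Å, 960 sphere points via the golden-spiral construction, element
radii C 1.7 / N 1.55 / O 1.52 / S 1.8 / H 1.2 / P 1.8 Å, overridable);
exactly coincident duplicate atoms are resolved deterministically in
favour of the lower atom index. The energetics stage uses 240 points
per atom by default as a speed/accuracy compromise; the single-atom
closed form 4π(r+probe)² is met to <0.5 % at 960 points.

The polar (Poisson–Boltzmann) term is **never solved internally**: it
is ingested from external per-residue or per-frame tables (a g_mmpbsa
contribution-file reader is provided) or set to zero with a prominent
log message. Re-implementing a PB solver is out of proportion to the
analysis layer, and grid/radii parameters of external tools are rarely
published, so ingestion keeps provenance honest.

Binding energies follow the single-trajectory convention: complex and
unbound partners are evaluated on the same frames, so intramolecular
terms cancel and only cross-group interactions contribute.
Per-residue decomposition splits every cross-group pairwise term
half-and-half between the two residues involved, which makes residue
contributions sum exactly to the group–group MM total; the nonpolar
share of a residue is γ times its buried-area change, with the
per-species constant kept as a whole-system term. Replicate summaries
report mean ± sample sd (n−1) at the replicate level. State Δ values
are computed two ways: from means rounded to one decimal (the
convention that reproduces printed tables, where Δ equals the
difference of the printed means) and from raw means; both are logged.

## Statistics

The one-tailed Mann–Whitney U statistic counts pairs in which the
comparison sample beats the reference in the direction of the stated
alternative; the p-value is the exact null tail probability obtained
from the count-of-partitions recursion over all C(n1+n2, n1) labelings
(used whenever n1+n2 ≤ 40 and the data are tie-free — at five replicates
per state the minimum attainable p is 1/252 ≈ 0.004). Ties fall back to
a tie-corrected, continuity-corrected normal approximation on midranks
and are flagged. The direction of each comparison is supplied by the
caller per hypothesis and recorded in run outputs; no multiple-testing
correction is applied.

## Ensemble-ML residue importance

Contact features are the inverse of the minimum heavy-atom distance
between an interfacial residue pair in one frame, standardized per
column over all pooled frames of both states; a pair is eligible if it
comes within 10 Å in at least one sampled frame of any replicate of
either state. Each of 20 iterations (seeds seed+0 … seed+19) greedily
prunes features whose absolute Pearson correlation with an already-kept
feature exceeds 0.9, visiting columns in a seeded random order, then
trains logistic regression, a 100-tree random forest and an MLP (one
hidden layer of 32 units) on the full frame set. Training accuracy is
recorded and a warning raised below 1.0; there is no held-out split —
the models are per-run diagnostics of separability, not predictive
deliverables. Feature importance is |coefficient| for LR, impurity
importance for RF, and mean absolute first-layer weight per input for
the MLP (permutation importance available as an option; outputs record
which was used). Residue importance sums a residue's surviving pair
importances, is averaged over iterations, and is normalized to a
maximum of 1 per model per interface so the 0.8 threshold acts on a
bounded scale. An optional separability gate zeroes an iteration's
importances unless all three models reach training accuracy 1.0 (tree
ensembles memorise training noise, so the gate keys on the weakest
model).

Categories: ml flag = importance > 0.8 (strict) in ≥ 1 model; energy
flag = |ΔΔG_Total| ≥ 2 kJ/mol between states; rmsf flag = |ΔRMSF| over
the order-class threshold. Category 3 = all three flags, category 2 =
ml plus one other, category 1 = ml only.

## Synthetic data

The generator builds two ideal α-helical backbone chains (N, CA, C, O,
H per residue, built from standard internal coordinates φ = −57°,
ψ = −47°) facing across a configurable interface (default 9 Å between
axes), with a simple backbone charge scheme and per-element LJ
parameters. Ensembles default to the replicate structure of the study
design it emulates: 2 states × 5 replicates, per-axis Gaussian jitter
(default 0.15 Å) applied as rigid per-residue displacements so that
H-bond and secondary-structure geometry survive noise. Planted
quantities: per-residue fluctuation sds per state (expected
ΔRMSF ≈ √3·|σ_B − σ_A|, an approximation that ignores the jitter of
other residues), contact pairs whose CA–CA distance is drawn from
Normal(state mean, jitter), and H-bond pairs placed inside the
geometric criteria in a Bernoulli(q) fraction of frames (2.9 Å, aligned)
and at 6 Å otherwise. Waters are isolated 3-atom HOH residues placed
near the interface only on request. Identical seeds give bit-identical
ensembles; replicates differ only by RNG stream.

A geometric limitation, by construction: moving a whole residue to set
a planted contact distance also perturbs that residue's distances to
*every* residue of the partner chain, so neighbouring pairs acquire a
correlated share of the separation signal. Planted-pair *recovery* by
the ML stage is therefore validated on a pair-level feature generator
in which each pair's distance series is drawn independently — noise
pairs identically distributed across states, planted pairs with
disjoint bounded (uniform) state distributions chosen so that classes
are exactly separable while planted-feature correlations stay below the
0.9 pruning threshold. The geometric generator remains the bed for the
flexibility, H-bond, distance-series and energetics stages.

What passing synthetic tests establish: the estimators recover planted
fluctuation amplitudes, occupancies, contact separations and pairwise
energies at the stated sampling sizes, and the ML pipeline ranks truly
separating pairs above noise. What they do not establish: behaviour
under force-field realism, solvent, conformational transitions,
autocorrelated frames, or ambiguous protonation — real trajectories
violate the generator's independence assumptions, and the thresholds
(1/3 Å, 10 %, 0.8, 2 kJ/mol) are conventions, not statistically
calibrated decision boundaries.

## Numerical choices and degenerate inputs

Kabsch superposition rejects selections of rank < 2 (collinear or
coincident) rather than returning an arbitrary rotation. Pairwise
energies raise a singularity error below 1e-6 Å separation and name the
offending atom when parameters are missing. Occupancy denominators are
the windowed frame count. Standardization guards zero-variance columns
(sd 1 substituted). Importance normalization is skipped for all-zero
vectors (no 0/0). Exact Mann–Whitney U uses integer count recursion
with no floating cancellation; p-values are reported at full precision
and rounded to 3 decimals for table layouts. Deltas of replicate means
reproduce printed tables only under the rounded-mean convention; the
raw difference can differ in the last decimal (e.g. −203.5 vs −203.6),
which is why both are always reported.

## Problem sizes used in the shipped checks

The packaged acceptance checks run the table statistics at the original
5-replicates-per-state size, the RMSF Monte-Carlo check at 5,000–10,000
frames, occupancy recovery at 1,000–2,000 frames, and the ML recovery
at 2 states × 5 replicates × 1,000 frames with 3 planted pairs among 55
eligible pairs over 20 iterations and 3 generator seeds. The pipeline
defaults (500/5000/250/1250 frames) apply to real-data runs; synthetic
end-to-end tests scale counts down, a choice recorded in each run log.
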
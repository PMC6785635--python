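# Methods

This note records the models, defaults and design choices behind each stage
of the pipeline, what the synthetic generators do and do not emulate, and the
known limitations.

## Coordinates and alphabets

Alignment columns and residue numbers are 1-based throughout, matching PDB
and structural-biology convention.  Sequences use the 20-letter amino-acid
alphabet plus `-` (gap) and `X` (unknown).  `X` is treated as a gap by the
descriptor encoding because no physicochemical descriptor is defined for it.

Position labels ("Pos16") are free strings tied to reference residue numbers
through a `PositionMap`.  The package ships the 14 cavity-position anchors
that are recoverable from the published NPF6.3 numbering (Pos1↔41, Pos2↔44,
Pos3↔45, Pos12↔82, Pos16↔164, Pos18↔168, Pos28↔353, Pos31↔359, Pos37↔469,
Pos40↔477, Pos43↔483, Pos46↔503, Pos47↔504, Pos50↔511); the remaining
positions of the published 51-position cavity set were never printed and are
deliberately not guessed — users supply them when reproducing the real-data
analysis.

## Cavity residue selection

Structures are superposed by least-squares rigid-body fitting (Kabsch, via
SVD) over a user-supplied Cα pairing; the package does not compute
structure-based sequence alignments.  Selection has two rules: residues
whose minimum heavy-atom distance to any ligand heavy atom is ≤ 8 Å
(ligand-bound, inward-facing structures), or ≤ 12 Å to named cavity probe
atoms (outward-facing models without a ligand).  Distances ignore hydrogens
(crystal structures generally lack them); ties at exactly the cutoff are
included (`<=`), a deterministic boundary convention.

"Surface-exposed" is operationalized as relative per-residue solvent
accessibility ≥ 0.05: Shrake–Rupley accessible surface with probe radius
1.4 Å and 960 sphere points per atom (element-based radii, computed with
biotite), summed per residue and divided by the Tien et al. (2013)
theoretical per-residue-type maxima, clamped to [0, 1].  The threshold is a
package choice — no published criterion exists for this step — and is
configurable; because of this, exact reproduction of the published
51-position set from the source structures is not a test target.  Residue
names outside the 20 standard types fall back to a 200 Å² maximum.

Per-structure selections are merged as a union in alignment coordinates;
residues lacking an alignment mapping are reported, never silently dropped.

## z-scale encoding and PCA

Residues are encoded by the three-component z-scales of Hellberg et al.
(1987) — principal-component summaries of 29 physicochemical properties:
z₁ hydrophilicity, z₂ steric bulk, z₃ polarity.  The table is versioned
(`hellberg-1987`) and pluggable.  A set of N fingerprints over P positions
becomes an N × 3P matrix.

Gap cells are imputed with the column mean over non-gap rows by default
(zero-imputation available): mean imputation avoids dragging scores toward
an arbitrary origin at positions where only a few sequences have gaps.

PCA mean-centers columns but does not scale to unit variance: the z-scales
are already standardized descriptors on a common footing, so variance
differences between positions are signal, not nuisance.  Components come
from the SVD of the centered matrix; a deterministic sign convention (the
largest-magnitude loading element is made positive) makes scores and plots
reproducible.  Eigenvalues use the n−1 denominator.

Cluster structure in score space is made reproducible with seeded k-means
(default k=4, best of 20 restarts) on the first two components, replacing
by-eye ellipse grouping; labels are renumbered by cluster size, largest
first.  Exact published cluster memberships were drawn by eye on external
sequences and are not a test target.  Dropping the proton-coupling motif
positions (Pos1–Pos3) and re-running the encoding and PCA is a first-class
operation (`drop_positions`), mirroring the published 48-residue control.

## Logo statistics

Frequencies exclude gaps from the denominator (logo convention) rather than
treating the gap as a 21st symbol.  Information content is
IC = log₂20 − H(f) bits, in [0, 4.32]; the optional small-sample correction
subtracts (20−1)/(2·ln2·n) and floors at 0.  Group contrasts use the
Jensen–Shannon divergence with base-2 logarithms, symmetric and bounded by
1 bit.  Pseudocount defaults: 0 for plain logos, 0.5 for divergence ranking
(stabilizes small groups).  Cluster-consensus uniqueness uses a 0.7
within-group frequency threshold (configurable); group rosters (e.g. which
transporters count as substrate-positive) are explicit inputs, not
hard-coded.

## Ion-trap model

All compounds are treated as monoprotic weak acids (default pKa 4.0 —
gibberellins and jasmonates are carboxylic acids; the precise values are
rarely tabulated and results are reported as ratios, which are insensitive
to small pKa shifts applied to both compartments).  Only the neutral species
crosses the membrane passively; anion permeability is 0.  The kinetic model

    dS_in/dt = (P·A/V)·(f_n(pH_out)·S_out − f_n(pH_in(t))·S_in) + k_t·S_out

uses a constant external bath, oocyte-scale placeholder geometry (V = 1 µl,
A = 0.2 cm², configurable) and a first-order carrier term k_t·S_out with no
saturation: screen concentrations relative to carrier affinities are not
established, so the carrier term is phenomenological.  Integration is
stiff-safe adaptive LSODA at rtol 1e-8, piecewise across internal-pH
breakpoints so step changes are resolved exactly.  At k_t = 0 the steady
state equals the closed-form equilibrium ratio, which the tests verify to
1%.

The oxygen-count permeability rule (≥6 oxygens non-permeating, 5 moderate,
≤4 high) is an empirical observation about gibberellins in oocytes, encoded
as stated; oxygen counts in the packaged registry are derived from molecular
formulas at load time.  Assay-pH recommendations (5.0 / 5.5 / 6.0 by class)
echo the optimized assay conditions.  Measured accumulations of highly
permeating compounds at 60 min sit far below the closed-form equilibrium —
consistent with non-equilibrium sampling — and no kinetic constants are
fitted to published figures; the package exposes the gap rather than hiding
it.

## Screen statistics

Normalization subtracts the mock (water-injected) mean before dividing by
the mock-subtracted reference mean, per batch; mock subtraction is on by
default because background diffusion otherwise inflates moderately
permeating compounds, and it makes normalized activities scale-invariant
within a batch.  Negative mock-subtracted means are clamped to 0 for
proportions but reported raw.

Significance per compound: one-way ANOVA across all groups is reported, and
transporter-vs-mock pairwise t-tests (classical pooled-variance by default,
Welch optional) are adjusted by Holm–Šidák step-down over the per-compound
family of transporter-vs-mock contrasts — not the all-pairs family, matching
the per-compound asterisk convention of screen figures.  The adjustment is
adj_(i) = max_{j≤i} [1 − (1 − p_(j))^(m−j+1)] over ascending raw p-values,
capped at 1; it is verified in tests against statsmodels' independent
implementation and controls the family-wise error rate under the null
screen generator (calibration test over 500 seeded simulations).

A transporter is a *bona fide* carrier of a substrate class when it is
significant for at least one compound of that class; applied to the
non-permeating gibberellins this excludes any hit explainable by diffusion.

## Synthetic generators and what they show

All generators are pure functions of (spec, seed).

The **fingerprint generator** plants group-specific conserved residues at
chosen positions over a background distribution (uniform by default,
Dirichlet optional).  The standard recovery benchmark uses four groups of
12–15 sequences over 51 positions, with 12 planted positions — three
contributed per group — each fully conserved within every group and with
four physicochemically spread marker residues (R/G/F/D) rotated across
groups per position.  This mirrors how real discriminating cavity positions
behave: shared alignment columns at which groups carry different conserved
residues.  Under these conditions the encode→PCA→k-means chain recovers the
planted groups with mean adjusted Rand index ≈ 0.98 over 20 seeds.  Designs
in which each group's planted positions are background in the other groups
carry much less co-varying signal and are not recoverable from two principal
components at these sample sizes; the benchmark therefore fixes the
shared-column design.  The generator draws residues independently across
sequences and positions — no phylogenetic correlation — so passing the
benchmark shows the pipeline recovers planted physicochemical structure, not
that real subfamily structure is this easy.

The **contrast benchmark** plants one discriminating position (R vs K at
conservation 0.9, groups of 15) among 50 background positions; the planted
position ranks first by Jensen–Shannon divergence in ≥19 of 20 seeds.

The **toy-structure generator** places residues on a 10 Å cubic lattice (or
an ideal α-helix) with a single-atom ligand at an exactly known offset, so
selections are checkable against an all-pairs distance scan and against
analytic distances; it does not emulate realistic protein packing.

The **screen generator** draws replicate amounts lognormally (positive,
CV-parameterized, matching LC-MS-style quantities) around mock_mean × effect
with mock and reference in every batch.  Calibration defaults: mock mean
10 pmol/oocyte, CV 0.2, n = 5 replicates — replicate scatter chosen as
realistic for quantified oocyte extracts, with n in the published 5–6 range.
It draws replicates independently and does not model batch effects beyond a
batch label, ion suppression, or oocyte-to-oocyte expression variability.

## Numerical conventions

- PCA oracle agreement (scores/eigenvalues vs dense eigendecomposition):
  1e-8 absolute.
- Superposition RMSD agreement with the closed-form quaternion (Horn)
  solution: 1e-6 Å.
- ODE: LSODA, rtol 1e-8, atol 1e-12.
- Proportions sum to 1 within 1e-12; JSD bounded within 1e-12 slack.
- k-means ties and label order: best of 20 seeded restarts, labels by
  descending cluster size with first-occurrence tie-break.

## Known limitations

- The real-data path (the 53-protein alignment, bacterial transporter
  structures, homology models) is user-supplied input; the package neither
  downloads nor rebuilds it, and does not compute alignments or homology
  models.
- The exposure criterion and the exact published 51-position set are not
  exactly reproducible (criterion unpublished); the selection machinery is
  validated against oracles on constructed structures instead.
- The ion-trap model is monoprotic, non-electrogenic and unsaturated; it is
  a design and interpretation aid for transport assays, not a fitted
  biophysical model of the oocyte.
- The packaged screen table is a transcription of published summary results
  (replicate-level data were not published); per-compound significance
  flags for the ten hits are aggregate.
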
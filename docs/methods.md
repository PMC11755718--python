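# Methods

cardkit re-implements, as a tested library, the analysis layer used to
characterise CARD–CARD (caspase activation and recruitment domain)
interfaces such as the Apaf-1 CARD / caspase-9 CARD contact in the
apoptosome: typed inter-domain interaction detection with persistence
statistics over trajectories, native-contact fractions against a reference
complex, buried-interface surface area and Coulombic surface potential,
consensus clustering of multi-engine docked poses with Kelley-penalty model
selection, and a consensus normality / routed two-sample comparison
protocol. This note records the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Structure model

Structures are read from (multi-model) PDB files via biotite; one frame per
MODEL block. Alternate locations are resolved by keeping the variant with
the highest occupancy — the convention used when preparing crystal
structures for simulation — with ties broken by the lowest altloc letter so
resolution is deterministic. Residue numbering follows the author numbering
in the file (crystal-paper residue names such as Asp27 remain meaningful);
no renumbering is ever performed. Hydrogens are kept when present (hydrogen
bond geometry needs them) but are excluded from `heavy` selections.
Trajectories whose MODEL blocks differ in atom identity are flagged
`topology_constant = False` and the persistence/RMSD stages refuse them
(fail fast) rather than attempting a per-key alignment.

## Interaction detection

Four inter-chain interaction types are detected per frame between two
disjoint chain groups. The source material for this kind of analysis names
the types but not the geometric cutoffs (they are internals of commercial
interaction-diagram tools), so literature-standard defaults are used and
everything is configurable through `InteractionCriteria`:

| type | test | default |
|---|---|---|
| hydrogen bond | d(H···A) ≤ 2.8 Å, ∠D–H–A ≥ 120°, ∠H–A–antecedent ≥ 90° | heavy-atom fallback d(D···A) ≤ 3.5 Å when no hydrogens |
| salt bridge | anionic O (Asp/Glu carboxylate, C-terminal) to cationic N (Lys NZ, Arg NE/NH1/NH2, N-terminal amine) ≤ 4.0 Å | |
| hydrophobic | closest C–C between apolar side-chain carbons ≤ 4.5 Å | Arg CB/CG/CD included (aliphatic stem) |
| π-cation | cation center (Arg CZ, Lys NZ) to aromatic ring centroid ≤ 6.0 Å and ≤ 45° off the ring normal | rings must be planar within 0.5 Å |

One record is emitted per (residue pair, type, frame); a pair engaging
through several simultaneous types yields several records, which is why
summed persistence can exceed 100%. Histidine is treated as neutral
(Nδ acceptor / Nε donor) since protonation assignment is out of scope; a
cationic-His switch exists. When a structure carries hydrogens, donors
missing their template hydrogen fall back to the heavy-atom distance test
if the fallback cutoff is set, and are skipped otherwise; a structure with
no hydrogens at all and no fallback cutoff is a configuration error.

The detector is validated two ways: exact set-equivalence against an
independent all-pairs brute-force enumeration on randomized toy complexes,
and closure against the synthetic generator (every planted contact must be
detected, with a 10% cutoff margin).

## Persistence, native fraction, key residues

Persistence of a (pair, type) row is the fraction of frames containing at
least one such record. The display filter keeps rows strictly above 10% of
frames; per-residue accumulated counts are taken over the *reported* rows
(each retained row increments both partner residues once per replicate) and
"key residues" are those with strictly more than five accumulated
interactions across replicates. The native reference set is the pair-level
(type-agnostic) set of residue pairs detected in a reference complex; a
typed matching mode exists but is off by default. The native-interaction
percentage per frame is the fraction of reference pairs present
(`pairwise` mode), or — for cross-docked complexes where only one side's
residues are meaningful — the fraction of reference-side residues with any
partner (`one_sided_groupA` mode, any partner counts since no partner
constraint is published). The heatmap bins records on a 3-ns grid by
default, mirroring the sampling grain of the analysis this reproduces.

## Geometry

Superposition is the Kabsch solution (via scipy's `align_vectors`);
trajectory RMSD is plain unweighted coordinate RMSD against the first
frame, computed on backbone heavy atoms of the whole complex by default
(Cα/heavy/all selectable). Backbone RMSD is the common stability readout
and matches the ~1.4 Å magnitudes typical of stable CARD–CARD complexes;
mass-weighting is off because the simpler choice is reproducible. Series
sampling keeps values at ticks 0, Δ, 2Δ, … choosing the nearest frame at or
after each tick (deterministic, keeps t = 0). Fewer than 3 pairs or a
collinear pairing is a degenerate-geometry error.

## Surface area and potential

SASA is Shrake–Rupley with a deterministic golden-spiral (Fibonacci)
lattice — no RNG, so results are exactly reproducible at a given point
count (default 960, probe 1.4 Å, Bondi-style element radii, hydrogens
excluded). Buried interface area is sasa(A) + sasa(B) − sasa(A∪B). The
published interface sizes this feeds into do not state whether that sum is
halved, so both conventions are first-class outputs with `half_sum` (one
face's worth) the default. Quadrature error grows for shallow overlap caps:
at 960 points the two-sphere analytic check holds to 1.5% when the cap
subtends at least ~25 lattice points, which the stated test separations
(2.0–5.0 Å for 3.1 Å expanded radii) respect.

The Coulombic potential at a point is φ = k·Σ qᵢ/(ε·dᵢ) with
k = 332.0636 kcal·Å/(mol·e²), reported in kcal/(mol·e). The charge model is
a pluggable formal-charge residue template (±1 split over the charged-group
oxygens/nitrogens, zero elsewhere) because no force-field charge set is
prescribed by the source analysis; potential values are therefore
qualitative (sign and pattern), not force-field-accurate. The dielectric is
a constant ε = 4 by default (typical protein-surface choice); a
distance-dependent ε = c·d mode is available.

## Consensus docking stage

Top poses (≤ 10 per engine by default) are pooled, reduced to the shared
heavy-atom identity set (mismatched residues are dropped ensemble-wide and
logged), and compared by pairwise heavy-atom RMSD after Kabsch
superposition — docked poses from different engines sit in different frames
of reference; a receptor-fixed no-superpose switch exists. The published
clustering metric ("RMSD of all heavy atoms, hydrogen bonds, and sulfate
bonds") is not a well-defined metric, so heavy-atom RMSD alone is used — the
only reproducible reading. Agglomerative clustering uses average linkage by
default (complete/single available) through scipy; scipy's deterministic
tie ordering stands in for an explicit lowest-pair-index rule. The cluster
count is chosen by the Kelley–Gardner–Sutcliffe penalty: average
within-cluster spread (mean pairwise distance over clusters with ≥ 2
members), min–max normalised to [1, n−1] across the candidate K range, plus
K; the minimum wins, ties to the smaller K. The representative complex is
the medoid (minimal mean distance to its cluster) of the largest cluster —
the distance-space stand-in for "closest to the centroid"; a
coordinate-mean centroid mode exists for harmonised ensembles.

Measured behaviour at the synthetic study conditions (3 planted
rigid-transform clusters, 10 poses each, effective between/within RMSD
separation ≈ 12): the KGS criterion selects K = 3 in 95 of 100 seeded runs
and the per-cluster medoids then always lie in distinct planted clusters;
the misses select K = 4 by splitting off 2–3 poses of one cluster, a known
mild overclustering tendency of the penalty at moderate separation.

## Statistical protocol

A sample is declared normal only when Kolmogorov–Smirnov, Shapiro–Wilk and
Anderson–Darling all fail to reject at α = 0.05. Because the KS test
against a normal with estimated parameters is anticonservative, the
Lilliefors-corrected form is used (statsmodels), with a switch for the
plain form; Anderson–Darling uses the estimated-parameter (case 3)
p-value. Comparisons route to Welch's unequal-variance t test when both
samples pass the consensus and to the two-sided Mann–Whitney U test
otherwise; significance at p < 0.05, unpaired (the safest default for
replicate MD series). Series are subsampled on a 3-ns grid before testing;
autocorrelation beyond that grid is not modelled. The routed procedure's
empirical type-I error on normal nulls is ≈ 0.05 (measured 0.048 over 1000
replicates by the acceptance script).

## Synthetic data: what it emulates, what it does not

The generator builds two-chain complexes whose backbone is an ideal
α-helix (1.5 Å rise, 100°/residue, 2.3 Å Cα radius) with schematic template
side chains placed so each planted contact satisfies its type's criteria
with ≥ 10% margin — emulating, at criteria level, a two-helix-bundle
interface. Non-contact residues are glycine; donor hydrogens are placed
explicitly and oriented so unplanned hydrogen bonds cannot arise. Every
structure is verified against the detector before being returned
(generator/analyzer closure by construction), and inter-chain clashes
below 2 Å between atoms of different contacts are build errors.

Trajectories realise per-contact presence schedules (always-on, Bernoulli
p per frame, or break-at-frame-f) by displacing the mobile side chain well
beyond 1.5× the largest cutoff; whole-complex rigid jitter (σ = 0.1 Å, 1°)
adds realism without touching contact geometry, and each frame is verified
against its schedule. Pose ensembles transform the ligand chain by K
well-separated rigid transforms (full-magnitude translations along
golden-spiral directions, distinct rotations) plus within-cluster jitter
(σ = 0.5 Å, 2°), returning true labels for oracle tests.

What the generator does *not* emulate: force-field energetics, rotamer
libraries, solvent, conformational breathing, or correlated contact
dynamics. Passing tests therefore demonstrate correctness of the analysis
arithmetic and geometry on inputs with known truth — not that the criteria
defaults reproduce any particular commercial tool's calls on real
trajectories.

## Numerical choices and degenerate inputs

Seeds are passed explicitly everywhere (`numpy.random.default_rng`); no
global RNG state. Kabsch on collinear or < 3-point pairings raises;
identical frames superpose to RMSD ~1e-7 Å (float SVD), so exact-zero
assertions use 1e-6 tolerances. The Kelley stage raises on all-singleton
candidate ranges; equal spreads normalise to 1 so the smallest K wins.
Empty native reference sets, zero-variance samples (flagged, treated
non-normal), unknown residues in role assignment (skipped with a warning)
and unknown elements in SASA (hard error naming the atom) are all handled
explicitly. Problem sizes in the test and acceptance runs (24-residue
chains, 60–300-frame trajectories, 30-pose ensembles, 100–1000 statistical
replicates) were chosen to exercise every code path with tight planted
truth at interactive runtimes.

## Known limitations

- Interaction cutoffs approximate common interaction-diagram conventions;
  no attempt is made to reproduce any proprietary classifier exactly (the
  known Asp–Arg "hydrophobic" artifact of one such tool is neither
  reproduced nor suppressed — arginine's aliphatic stem simply participates
  in the hydrophobic set, which is documented chemistry).
- The charge model supports sign/pattern-level electrostatics only.
- π–π stacking, halogen bonds and water-mediated bridges are not detected.
- mmCIF input, protonation assignment and per-residue RMSF are out of
  scope; MD itself, MMGBSA energies, alanine-scanning energetics and the
  external docking engines are consumed as inputs, never run.
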
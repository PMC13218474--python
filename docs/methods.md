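# Methods

## The system and the quantities computed

`rhpdimer` post-processes molecular-dynamics trajectories of two
single-chain nanoparticles (SCNPs) built from a four-monomer random
heteropolymer (RHP) — MMA (`M`), OEGMA (`O`), EHMA (`E`), SPMA (`S`) at
target ratios 50:25:20:5, 100 monomers per chain — solvated in explicit
water in a periodic orthorhombic box. Association between the two chains
is quantified through five families of metrics:

1. **Shared solvation shell.** For each frame, the set of water molecules
   within 5.0 Å (the second solvation shell) of each chain is computed;
   the *shared* count is the size of the intersection and the *union*
   count is `shell1 + shell2 − shared`. A frame is *adsorbed* when at
   least 40 waters are shared; the percent of time adsorbed is the
   adsorbed-frame fraction. The per-simulation scalars (mean shared, mean
   union, max shared, sum shared) are the coordinates of the scatter
   diagnostic in which strongly associated and independently solvated
   systems form two clusters: association converts solo-shell water into
   shared water and buries interface area, so mean shared rises while the
   union count falls.
2. **Contacts by monomer chemistry.** A residue–residue contact exists at
   a time point when a heavy (non-hydrogen) atom of a residue in chain 1
   is within 10 Å of a heavy atom of a residue in chain 2. Contact counts
   are accumulated per ordered monomer-type pair (A, B) and normalized by
   a·b, where a and b are the atom counts of types A and B in a single
   chain, counted from the actual topology.
3. **Interacting residues and interface composition.** A residue
   *interacts* if, in any analyzed frame, any of its atoms (hydrogens
   included) comes within 10 Å of any atom of the other chain; percentages
   use the chain's residue count as denominator, with a backbone variant
   restricting the residue's own atoms to backbone atoms. The *interface
   composition* is time-weighted: every polymer atom within 10 Å of the
   partner chain contributes one appearance per qualifying frame (an atom
   interfacial for 5000 frames counts 5000 times); appearances are
   normalized to 1 across the four types whenever any exist, both pooled
   and per chain. Enrichment relates a type's interfacial share to its
   share of the chain's atoms; contacts-per-atom profiles are rescaled to
   [0, 1] by dividing by the maximum (min–max scaling is available as an
   alternative reading, and the raw appearance table is always emitted).

   Note the deliberate coexistence of two 10 Å determinations: contacts
   are heavy-atom-only, interaction/composition are any-atom. Each has its
   own switch.
4. **Backbone RMSF.** Over a trailing window (40 ns by default, measured
   back from the final frame; shorter trajectories are analyzed whole with
   a warning), every frame's backbone is superposed onto the chain's
   window-average backbone structure by least-squares rigid-body fitting
   (Kabsch; one mean → fit → re-mean refinement pass). Per-atom RMSF is
   the RMS deviation from the window-mean position; the per-residue value
   averages the residue's backbone atoms, and group means split residues
   by interaction status.
5. **Sequence sensitivity.** Per-simulation metrics grouped by sequence
   are compared with the Kruskal-Wallis H test (mid-rank ties, tie
   correction, chi-square p-value with k−1 degrees of freedom — standard
   at ~10 observations per group; an exhaustive-permutation p-value is
   available for small pooled n). The test is rank-based because the
   association metrics are strongly non-normal (bimodal across the
   associated/dissociated dichotomy). The same path serves max shared,
   percent adsorbed and sum shared. Per-sequence aggregation reports mean
   ± sample standard deviation (n−1; undefined at n = 1). The
   adsorption–composition regression fits, per monomer type, adsorbed-time
   fraction against interfacial percentage by OLS and reports Pearson r.

## Geometry conventions

* All distances use the orthorhombic minimum-image convention by default
  (`use_pbc`); the cutoff must not exceed half the smallest box edge.
* "Within X Å" is closed (≤ X) by default; `boundary="open"` is exposed
  because the convention is not universal.
* Coordinates are Å; residues are numbered 1-based per chain; frames are
  0-based internally and reported as times in ns.
* Waters count as whole molecules. `water_site_mode` controls shell
  membership: `any_atom` (default — a water is in a shell if any of its
  atoms is within the cutoff) or `oxygen_only`.
* The fast pair search delegates to a grid method that computes in
  float32; candidates are gathered with a small cutoff margin and
  refiltered with exact float64 minimum-image distances, so results are
  set-identical to the exhaustive O(N²) definition.

## File formats

Topology is standard PDB (chain id, residue name/number, atom name,
element column, CRYST1 box); a residue map assigns polymer residue names
to monomer codes and flags water/ion names. Trajectories are DCD (binary;
float32 coordinates, frame times reconstructed from the float32 header
time step) or a text XYZ dialect with a per-frame header
`t= <time_ns> box= <lx> <ly> <lz>` and `%.8e` coordinates, which
round-trips float32 values and times exactly. Configuration files are
YAML mirroring `AnalysisConfig` fields.

## The synthetic generator

No trajectories are distributed with the methodology this package
implements, so the generator manufactures reduced-scale scenarios whose
every analyzable property is planted and machine-readable
(`ScenarioTruth`):

* Two identical 100-monomer bead chains (serpentine compact lattice,
  3 Å spacing; two backbone beads per monomer, side-chain beads ordered
  OEGMA > EHMA > MMA > SPMA) face each other along x in an 80 Å cube with
  ~600 single-site waters (a 3-site option exercises `any_atom` mode),
  plus K⁺ counterions for the sulfonate monomers.
* A scripted schedule of adsorbed intervals drives rigid-body placement:
  facing backbone surfaces 4 Å apart when adsorbed, 25 Å when dissociated.
  Gaussian jitter is applied to chain centers (σ = 0.2 Å), to every atom
  (σ = 0.15 Å), and additionally to ideal-geometry interface atoms
  (σ = 0.45 Å) so interfacial residues genuinely fluctuate more.
* **Bridging waters** (50) occupy the mid-plane slab, inside both 5 Å
  shells on adsorbed frames and outside every shell when dissociated.
  Ambient waters are rejection-sampled out of the interfacial slab, so the
  shared count on adsorbed frames equals the planted roster exactly and is
  zero when dissociated.
* **Tracked shell waters with burial** (120 per chain, 60 of them anchored
  on the facing surface) follow each chain rigidly; the facing-surface
  ones are displaced to a far park position while adsorbed. Because burial
  (120 waters) exceeds bridging (50), the union water count strictly falls
  on association — the mechanism behind the two-cluster solvation
  diagnostic. Without burial a toy system would show the *opposite* union
  response.
* Truth bookkeeping: the adsorbed mask/fraction and bridging roster are
  exact schedule plants; interface residues, per-atom appearance counts
  and composition fractions are recorded by an independent brute-force
  all-pairs scan of the generated frames (jitter makes 10 Å-boundary
  membership frame-dependent, so a noise-free-geometry plant cannot match
  a cumulative measurement exactly — the brute-force route shares no code
  with the grid-search analysis path).
* All randomness flows from one seed through named `SeedSequence`
  children (sequence shuffle, chain jitter, water placement, water jitter,
  ions); no global state.

What the generator does **not** emulate: polymer internal dynamics,
thermodynamically meaningful association kinetics, force fields, water
structure, counterion condensation. Passing tests therefore demonstrate
correctness of the *measurement* layer (counting, weighting, windows,
statistics) under known ground truth, not fidelity of any physical model.
Defaults (200 frames at 0.25 ns spacing, ~1 400 atoms) keep a full
scenario analysis in the seconds range on one CPU; the full experimental
scale (160 Å cube, 5 000 waters, 120 ns) is reachable through the spec
fields but is not a test requirement.

## Numerical choices and degenerate inputs

* Closed cutoffs at exact float64 distances; duplicate (co-located) atoms
  are legal and each counts.
* Interface composition with zero appearances is *undefined* (`None`),
  never a vector of zeros; enrichment then raises.
* Kruskal-Wallis rejects all-identical pooled values (tie correction
  denominator zero); the chi-square p is clamped to (0, 1].
* Regression per type is undefined with fewer than two distinct x values.
* Superposition requires ≥ 3 non-collinear atoms; rotations are proper.
* RMSF needs ≥ 2 frames in the window; window selection uses a 1e-9
  relative time tolerance so reconstructed file times cannot drop a
  boundary frame.
* Batches isolate failures per entry and fail only if every entry fails;
  master tables are canonically sorted by (sequence, conformation,
  replicate) so manifest order never changes results.

## Known limitations

* Orthorhombic boxes only; no triclinic support, no trajectory unwrapping
  (chains are assumed whole within the analysis window).
* "Total water" in the solvation diagnostic is reported as the union
  count; the sum-of-shells reading can be derived from the emitted
  per-frame table (`shell1 + shell2`).
* Whether headline interacting-residue percentages should average the two
  chains or report one chain is unspecified in the field; the report emits
  per-chain values and their mean, and the pipeline's master table uses
  the mean.
* DCD times are float32-quantized; use the XYZ dialect when exact time
  round-trips matter.
* RMSF is reported in Å per residue over backbone atoms; no side-chain or
  time-resolved fluctuation analysis.
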
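# rhpdimer

Trajectory analysis of random-heteropolymer (RHP) single-chain
nanoparticle dimerization in explicit water.

Random heteropolymers built from four methacrylate monomers — MMA (`M`),
OEGMA (`O`), EHMA (`E`) and SPMA (`S`), typically at 50:25:20:5 ratios and
100 monomers per chain — collapse into protein-like single-chain
nanoparticles whose association ("multimerization") is stochastic:
some chain pairs adsorb durably through hydrophobic surface patches,
others only touch transiently. `rhpdimer` implements the measurement
layer for simulations of two such chains in water, for computational
polymer scientists who have trajectories (or want synthetic ones) and
need the association statistics:

* **Shared-solvation-shell association.** Per frame, the waters within
  5.0 Å of each chain; the shared count `|S₁ ∩ S₂|`; the union count
  `|S₁| + |S₂| − shared`. A frame is *adsorbed* when ≥ 40 waters are
  shared, and the percent of time adsorbed, max/sum/mean shared waters
  summarize each run. Associated systems show high shared / low union
  water; independently solvated systems the opposite.
* **Contacts by monomer chemistry.** Heavy-atom residue–residue contacts
  within 10 Å, accumulated per type pair (A, B) and normalized by a·b
  (atom counts of the two types in a single chain).
* **Interacting residues & interface composition.** Any-atom 10 Å
  determinations: the fraction of residues that ever interact (with a
  backbone-restricted variant), and the time-weighted monomer composition
  of the interface (an atom interfacial for 5000 frames counts 5000
  times), normalized to 1, with enrichment relative to sequence
  composition and a per-type adsorption–composition regression.
* **Backbone RMSF.** Per-residue backbone fluctuation over the trailing
  40 ns after rigid-body superposition onto the window-average structure,
  partitioned into interacting vs non-interacting residues.
* **Sequence sensitivity.** Kruskal-Wallis H tests (tie-corrected,
  chi-square or exact-permutation p) across sequences on max shared
  waters, percent adsorbed and sum of shared waters, plus per-sequence
  mean ± SD aggregation.
* **Synthetic scenarios with planted truth.** A generator manufactures
  two-chain + water trajectories with scripted adsorption schedules,
  guaranteed bridging waters, interface burial and known interface
  composition, so every analysis stage can be validated against exact
  ground truth without external data.

See `docs/methods.md` for the model conventions, the synthetic-data
design and its limitations.

## Worked example

Generate a scenario that is adsorbed for 60 % of its 200 frames, then
analyze it:

```bash
rhpdimer synth --fraction 0.6 --seed 5 --out demo/scn
rhpdimer analyze --topology demo/scn.pdb --trajectory demo/scn.xyz \
    --out demo/analysis --rmsf-window 10
```

which prints

```json
{
 "iface_E": 0.20917458994658888,
 "iface_M": 0.40865184287283607,
 "iface_O": 0.35364975946058563,
 "iface_S": 0.028523807719989393,
 "max_shared": 50,
 "mean_shared": 30.0,
 "mean_union_total": 213.5,
 "pct_residues_any_atom": 75.0,
 "pct_residues_backbone": 75.0,
 "percent_time_adsorbed": 60.0,
 "rmsf_interacting": 0.6219349898089607,
 "rmsf_noninteracting": 0.2576969354299302,
 "sum_shared": 6000
}
```

Reading the numbers: the run spends 60.0 % of its frames with ≥ 40 shared
waters (exactly the scripted fraction — the generator plants 50 bridging
waters on adsorbed frames, hence `max_shared = 50`); 75 % of residues come
within 10 Å of the partner chain at some point; the interface is
MMA-enriched relative to the 50:25:20:5 sequence at the atom level; and
interfacial residues fluctuate ~2.4× more than non-interfacial ones
(RMSF in Å over the trailing 10 ns). Per-frame tables (solvation, type-pair
contacts, interacting residues, per-residue RMSF) and JSON summaries are
written to `demo/analysis/`.

Batch mode runs a YAML manifest of (sequence, conformation, replicate)
entries, aggregates per sequence, and emits the Kruskal-Wallis and
regression reports:

```bash
rhpdimer batch --manifest manifest.yaml
rhpdimer stats --master out/aggregate/master_table.tsv --out restats
```

The same operations are importable as a library
(`rhpdimer.shared_water_series`, `rhpdimer.interface_composition`,
`rhpdimer.backbone_rmsf`, `rhpdimer.kruskal_wallis`, ...).

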
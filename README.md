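# crysdyn

Conformational analysis of the **early unfolding of two-domain β-sandwich
proteins** from molecular-dynamics trajectories, written for structural
biologists studying lens γ-crystallins (and similar Greek-key folds) who want
the standard battery of trajectory observables — native-contact fraction,
contact maps, DSSP-style secondary-structure event sequencing, aromatic
cluster persistence, essential dynamics, interdomain hinge motion — as one
reproducible, scriptable pipeline rather than a collection of one-off tool
invocations.

The motivating system is human γD-crystallin (HGDC), a 173-residue eye-lens
protein of two domains with two Greek-key motifs each, whose early unfolding
(strand detachment in motif 2, loss of the conserved Tyr-pair and Tyr-corner
aromatic interactions, interdomain closure/twist motion) precedes the
aggregation that underlies cataract. The default region vocabulary
(`motif2_beta3` = G61–A64, `motif1_beta3` = C33–V38, `motif2_beta2` =
Q55–L58, …) addresses that chain, but every analysis is generic.

## What it computes

- **Native-contact fraction** Q(t) = N(t) / N(t₀), where a contact between
  residues *i*, *j* exists when any heavy atom of *i* is within 6.5 Å of any
  heavy atom of *j* (closed boundary). Whole-protein, per-domain and
  per-region variants; the numerator counts all contacts at *t*, so Q may
  exceed 1 when non-native contacts form (a strict-native mode caps it at 1).
- **Ensemble contact maps** (per-pair frequency over sampled frames) and
  **subtractive maps** A − B between two ensembles, in raw-frequency or
  per-trajectory change ("loss") form.
- **Secondary structure** by Kabsch–Sander hydrogen bonds,
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
  E < −0.5, with n-turn (G/H/I), bridge/ladder (B/E) and turn (T) patterns;
  per-region β-content and an ordered list of **unfolding events** (rolling
  β-content dropping below a threshold and staying there).
- **Aromatic interactions**: ring-centroid distances, presence in the
  4.5–7.0 Å aromatic–aromatic band, per-pair persistence percentages and
  connected-component **cluster formation events**.
- **Kinematics**: Kabsch superposition, RMSD(t), per-residue RMSF about the
  time-averaged structure, essential-dynamics PCA (eigenvalues/eigenvectors
  of the aligned coordinate covariance, projections onto the top modes), and
  a two-domain rotation decomposition: with rotation axis **n** and
  interdomain unit vector **d**, %twist = 100·(n·d)², %closure = 100 − %twist.
- **Potential-energy bookkeeping** E_pot = E_valence + E_nonbond with the
  full term split and ΔE = E(t_end) − E(t₀), against any pluggable scorer
  (a toy bond/LJ/Coulomb scorer is built in).
- **Synthetic trajectories with scripted ground truth**: an idealized
  two-domain antiparallel β-sandwich builder plus an event script (strand
  detachments, rigid rotations with a chosen twist/closure mix, aromatic
  cluster formation, Gaussian noise) whose true onsets and parameters are
  emitted alongside — this is how every stage of the pipeline is validated.

## Worked example

Simulate the bundled "GdnHCl-like" preset — three sequential strand
detachments plus a closure-dominated interdomain rotation on a 72-residue
toy β-sandwich — and analyse it:

```
$ crysdyn simulate --preset gdnhcl_like --seed 1 --out sim
wrote 100-frame trajectory (dt=0.25 ns) to sim
$ crysdyn analyze --traj sim/traj.pdb --regions sim/regions.cfg --out run \
      --fixed-domain domain1_core --moving-domain domain2
```

`run/events.tsv` then contains (header trimmed):

```
region           onset_ns  kind       beta_before_pct  beta_after_pct
motif2_beta3     3.5       melt       65.7             0.9
motif1_beta3     11        melt       66.4             1.4
motif2_beta2     18.5      melt       68.2             3.2
```

i.e. the three scripted strands lose their β-structure in the scripted order
(true onsets 3.75, 11.25 and 18.75 ns; the detector localises each to within
one sampled frame), dropping from ~66% to ~1–3% β-content — the same
motif-2-β3-first sequencing read off real denaturant trajectories. The run
metadata reports the interdomain motion split,

```
fraction_closure = 96.7   fraction_twist = 3.3   (9 frames below the 1° floor)
```

matching the scripted closure-dominated rotation, while the urea-like preset
(`--preset urea_like`) yields `fraction_twist = 100` and one aromatic-cluster
formation event, `onset 13.75 ns, members 9+21+23+27`, at the scripted frame.
`crysdyn compare --run-a … --run-b …` then produces the signed subtractive
contact map between two such runs, and `crysdyn report --run …` re-verifies
every emitted table against its manifest checksum.

## Layout

| module | contents |
|---|---|
| `crysdyn.io_model` | PDB read/write, Structure/Trajectory types, atom selections, named regions |
| `crysdyn.contacts` | contact sets, Q series, ensemble & subtractive maps |
| `crysdyn.secondary_structure` | Kabsch–Sander energies, DSSP-style labels, unfolding events |
| `crysdyn.aromatics` | ring centroids, band persistence, cluster events |
| `crysdyn.kinematics` | superposition, RMSD/RMSF, essential-dynamics PCA, closure/twist |
| `crysdyn.energetics` | energy breakdown bookkeeping, ΔE, toy scorer |
| `crysdyn.synthetic_data` | β-sandwich builder, unfolding scripts, ground truth, ion arithmetic |
| `crysdyn.pipeline` / `crysdyn.cli` | orchestration, TSV reports, manifest, `crysdyn` command |
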
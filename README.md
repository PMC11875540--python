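# ionphase

Sequence-specific, ion-aware modeling of liquid-liquid phase separation
(LLPS) of charged intrinsically disordered proteins, with four engines that
share one charge-sequence representation:

* **`seqcharge`** — sequences, per-residue charges (R/K +1, D/E −1,
  phosphotyrosine −2, neutral otherwise at pH 7.4), charge metrics
  (Q, NCPR, FCR), and solution electroneutrality bookkeeping.
* **`rgrpa`** — analytical free energy of a charged heteropolymer solution
  with counterions and salt: ideal lattice mixing, a Flory–Huggins term
  `χ(T) = ε_h/T* + ε_s` with reduced temperature `T* = l/l_B(T)`, and a
  charge-fluctuation (RPA) integral evaluated for a Gaussian chain whose
  Kuhn length is renormalized by a variational factor `x`.
* **`coexist`** — phase equilibria on top of `rgrpa`: restricted
  (uniform-salt) temperature–concentration binodals and critical points,
  plus unrestricted two-dimensional salt–polymer diagrams with
  Donnan-consistent tielines formulated in neutral components.
* **`fhfit`** — fits `(ε_r, ε_h, ε_s)` to dilute/dense coexistence data by
  repeated restricted-binodal solves (log-concentration least squares).
* **`fts`** — lattice field-theoretic simulation via complex-Langevin
  dynamics for mixtures of a charge-sequenced protein, a 6-bead ATP-Mg
  species (four −1 beads and two +1 beads, net −2), and monovalent ions;
  density–density correlation functions and per-residue integrated ion
  contacts.
* **`cgmd`** — explicit-ion coarse-grained MD energy model
  (`U = U_el + U_sr + U_bond`; truncated-shifted Coulomb, Ashbaugh–Hatch
  short range, harmonic bonds), a BAOAB Langevin integrator, and
  slab-geometry analysis (z-density profiles, plateau extraction, critical
  temperature from an order-parameter + rectilinear-diameter fit).
* **`bridging`** — counterion-bridging analysis of snapshots: RDFs,
  enumeration of interchain Arg⁺–Cl⁻–Arg⁺ configurations, geometric
  true/neutralizing/intermediate classification (equivalent to the
  explicit Coulomb criterion for unit charges), projected P(x, d) heat
  maps, and the isolated three-bead Boltzmann reference system.
* **`fixtures`** — built-in model sequences (a 103-residue Caprin1-IDR
  model with 15 R / 1 K / 3 D / 7 Y, its 7-site phospho variant, and the
  RtoK variants) plus deterministic synthetic-data generators
  (counter-based RNG) for every analysis stage.

Internal units: energies in kT, lengths in the peptide virtual bond length
b = 3.8 Å; converters to molar / mg/ml live in `ionphase.constants`.

## CLI

```sh
ionphase seq --name caprin1_wt --metrics
ionphase free-energy --config cfg.json --rho-p 1e-4 --rho-s 3e-3
ionphase binodal --config cfg.json --salt 3.3e-3 --t-min 300 --t-max 360
ionphase saltmap --config cfg.json --zs 1 --zc 2 -T 560
ionphase fit --data coex.tsv --sequence py_caprin1
ionphase fts --config fts.json --correlations pp,p-atp --contact-profile atp
ionphase md --system sys.json -T 300 --steps 20000 --seed 1 --out traj.xyz
ionphase slab --traj traj.xyz
ionphase bridge --traj traj.xyz --cutoff 11 --bin 2
ionphase synth ideal-gas --n 500 --out gas.xyz
```

`cfg.json` holds `{"sequence": "caprin1_wt", "epsilon_r": 80.5, "eps_h":
1.0, "eps_s": 0.0, "zs": 1, "zc": 1}`; FTS configs list species with bead
charges and densities (one ion species may be left free and is set by
electroneutrality).

Coexistence TSVs have the header
`T  T_unit  salt  salt_unit  phase  conc  conc_unit  sequence` with
temperatures in C or K and concentrations in `uM | mM | M | mg/ml | b-3`
(mass units need the sequence for the molar mass).

Trajectories use a plain extended-XYZ dialect:
`species x y z chain_id` per atom with the orthorhombic box in the comment
line (`Lattice="lx 0 0 0 ly 0 0 0 lz"`); chain id −1 marks free ions.

## Scale notes

The analytical engine reproduces the qualitative salt/valency phase
behavior (polyelectrolyte reentrance with an interior UCST maximum,
monotone polyampholyte dissolution, zero-salt LLPS only for multivalent
counterions, tieline-slope signs, dense-phase valency ordering) but — like
other simplified field theories — overestimates absolute transition
temperatures; trend tests therefore pick state points on the model's own
critical-temperature scale.  FTS and MD tests run at reduced lattice sizes
and schedules sized for a CI budget; production-scale settings are plain
configuration changes.
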
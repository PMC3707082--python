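# ptenkin

Quantitative analysis of phospho-regulated, membrane-interfacial phosphatase
activity — built around the biochemistry of PTEN, the PIP3 3-phosphatase whose
C-terminal tail phosphorylation switches the enzyme into a closed,
autoinhibited conformation.  The package implements the five measurement
chains such a study needs, plus seeded synthetic-data generators so every
stage can be exercised and validated without raw experimental data:

1. **Interfacial (surface-dilution) kinetics.**  For an enzyme acting on a
   vesicle-embedded substrate, the initial velocity follows

   `V0 = Vmax·Xs·S0 / (iKm·Ks + iKm·S0 + Xs·S0)`, `Vmax = kcat·[E]T`,

   where `S0` is the bulk substrate concentration (µM), `Xs` the surface
   concentration (mol%), `iKm` the interfacial Michaelis constant (mol%) and
   `Ks` the membrane dissociation constant (µM).  Paired bulk-dilution and
   surface-dilution titrations give apparent hyperbolas whose parameters
   combine algebraically: `iKm = (Vmax_SD/Vmax_BD − 1)·Xs`,
   `Ks = Km_BD·(Xs/iKm + 1)`, `kcat = Vmax_SD/[E]T`.  Apparent substrate
   inhibition at high mol% is handled by fitting only the lowest surface
   concentrations (default four).
2. **Soluble-substrate kinetics**: Michaelis–Menten fits, efficiency-only
   (`kcat/Km`) estimation in the sub-saturating regime, and single-site IC50
   fits for trans inhibition by the phosphorylated tail peptide.
3. **Protection kinetics**: pseudo-first-order dephosphorylation of the
   phospho-tail by a probe phosphatase, concentration-normalized rate
   differentials, and the inferred closed:open conformational equilibrium.
4. **Vesicle co-sedimentation**: fraction bound from pellet/supernatant
   densitometry, saturable binding curves, matched-binding compositions.
5. **SAXS shape descriptors**: Guinier Rg, regularized pair-distance
   distribution P(r), Dmax estimation and an elongation (shoulder) metric.

The audience is enzymologists and biophysicists analyzing these assay types;
the interface is the Python API (`import ptenkin`) plus a thin `ptenkin` CLI
for CSV-based workflows.

## Worked example

`examples/protection_equilibrium.py` simulates the protection assay at a
60 min native half-life (1 µM probe) and a 4.8 min denatured half-life
(0.5 µM probe), fits both decays, normalizes for probe concentration and
infers the equilibrium:

```
native:    t1/2 = 59.0 min at 1.0 uM probe
denatured: t1/2 = 4.74 min at 0.5 uM probe
normalized rate differential: 24.9-fold
closed:open = 25:1 (rate-ratio convention), 24:1 (occupancy model), open fraction = 0.040
```

A ~25-fold protection factor means the phospho-tail is sequestered ~96% of
the time.  The other scripts in `examples/` (one per capability) run the
interfacial round trip, the soluble/inhibition analyses, the binding
comparison and the SAXS descriptors the same way, each printing the numbers
it computes and what they mean.

## Command line

```sh
ptenkin simulate --outdir demo --seed 0      # synthetic CSV bundle + config.yaml
ptenkin run-all --config demo/config.yaml    # every stage; CSV + JSON report
ptenkin fit-interfacial --input demo/velocities.csv
```

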
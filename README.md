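# nkaproton

Protonation-state analysis of the Na⁺-bound Na⁺,K⁺-ATPase ion-binding
pocket: state enumeration, ion-stability metrics, water-pathway flux,
quantum-cluster carving and binding-energy bookkeeping, exercised
end-to-end on synthetic trajectories and energy ledgers with planted
ground truth.

## The scientific problem

The sodium pump (Na⁺,K⁺-ATPase, NKA) exports 3 Na⁺ and imports 2 K⁺ per
ATP. In the phosphorylated, Na⁺-bound E1P state its transmembrane pocket
holds three ions in sites I, II and III, each coordinated by one
glutamate and one aspartate: Glu779/Asp808 (I), Glu327/Asp804 (II),
Glu954/Asp926 (III). Which of these six acidic side chains carry a
proton is invisible to crystallography but controls ion stability, water
access and ion release. This package implements the analysis pipeline
for answering that question from simulation data:

1. **Enumeration.** All 2⁶ = 64 proton assignments, written `n[ijk]`
   where `n` is the proton count and `i, j, k` code sites I–III as
   `0` (none), `E` (Glu), `D` (Asp) or `2` (both). `3[E20]` = Glu779 +
   both site-II residues protonated.
2. **Stability metrics.** Per trajectory replica, the mean ion RMSF
   (root of the time-averaged squared deviation of each ion from its own
   window-average position, averaged over the three ions) and the
   hydration number N_water (mean count of unique water molecules whose
   oxygen lies within 5 Å of any ion). A state is *stable* when every
   replica satisfies N_water < 8 and RMSF < 0.5 Å; replicas whose ion
   drifts > 5 Å from its starting site exclude the state.
3. **Water gates.** Transit counting through three pathway corridors
   (extracellular ↔ site I, N-terminal ↔ site II, C-terminal ↔ site
   III): a water completes an inward transit when it passes mouth-zone →
   site-zone while staying inside the corridor. The gate hypothesis —
   each site's glutamate, when protonated, closes its pathway — is
   tested by contrasting states that move one proton Glu → Asp.
4. **Cluster model.** The pocket is carved for DFT energetics: residues
   with an oxygen within 2.5 Å of an ion plus sequence neighbours, whole
   residues with peptide bonds cut and hydrogen-capped at 1.09 Å, alpha
   carbons frozen, net charge = ion count − deprotonated acids.
5. **Energetics.** From externally computed (counterpoise-corrected)
   fragment energies: ΔE_bind(i) = E_full − E_without(i) − E_ion per
   site, against the hydration reference ΔE_hyd = E_shell − E_water −
   E_ion of a single ion in a 9 Å water shell. Strengths (−ΔE) above
   the hydration reference mean the pocket outcompetes water (the state
   binds Na⁺ from solution); a site at or below it is releasable.

Because real MD/QM inputs need microseconds of sampling, the package
ships a first-class synthetic-data generator that plants known RMSF
(σ√3), hydration (Poisson λ), transit counts, unbinding events and
binding strengths, so every estimator is verifiable against closed-form
truth.

## Worked example

```bash
python analysis/01_enumerate_states.py
python analysis/02_stability_screen.py --seed 1
python analysis/03_water_pathways.py --seed 1
python analysis/04_qm_cluster.py --seed 1
python analysis/05_binding_energies.py --seed 1
python analysis/06_report.py
```

Step 02 simulates the 64-state ensemble (3 replicas × 2000 frames at
50 ps) and prints

```
stable states (6): 3[02E], 3[DEE], 3[EDE], 3[EEE], 4[022], 4[E2E]
planted stable: 3[02E], 3[DEE], 3[EDE], 3[EEE], 4[022], 4[E2E]
excluded by unbinding: 10 states
```

— the classifier recovers exactly the six planted-stable states and
excludes the ten states whose site-II ion was scripted to escape. Step
03 prints the gate associations

```
GLU779 deprotonation opens the extracellular pathway (3[EEE] -> 3[DEE])
GLU327 deprotonation opens the N-terminal pathway (3[EEE] -> 3[EDE])
GLU954 deprotonation opens the C-terminal pathway (3[EEE] -> 3[EED])
```

and step 05 the energy verdicts, e.g.

```
hydration reference: 169.27 ± 1.22 kcal/mol (10 shells)
  3[EEE]: I 182.3±0.8, II 182.4±0.9, III 179.1±1.1 kcal/mol -> bindable
  4[E2E]: I 153.3±1.3, II 152.0±2.1, III 149.4±2.4 kcal/mol -> NOT bindable
releasable sites: 3[EED]/III, ...
```

Three-proton states bind Na⁺ from water (~180 vs ~170 kcal/mol);
adding a fourth proton shifts strengths by ~−30 kcal/mol and loses
bindability; protonating Asp926 (state 3[EED]) makes site III — and
only site III — releasable.

The same stages are available as a CLI (`nkaproton enumerate|simulate|
metrics|classify|pathways|carve|energies|report|run-all`) operating on
multi-model PDB files, an energy-ledger TSV and a YAML config.

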
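# Methods

## Protonation-state grammar

The six titratable pocket residues are grouped by binding site, fixed in
the order I (Glu779, Asp808), II (Glu327, Asp804), III (Glu954, Asp926);
numbering follows the shark-pump crystal structure convention. A state
symbol `n[ijk]` carries the proton count and one code per site
(`0`/`E`/`D`/`2`). The codec validates the leading digit against the
codes on decode — `2[EEE]` is rejected rather than repaired, since a
count/code mismatch in an input table indicates a corrupted record.
Enumeration orders states by proton count, then lexicographically with
`0 < E < D < 2`; the ordering is our choice, made once for reproducible
reports. The codec is total over registries with any number of sites
(an empty registry yields the single state `0[]`), though the pipeline
only uses the canonical three-site registry.

## Ion RMSF and hydration number

For ion *i* over window frames *t*:

RMSF_i = sqrt( ⟨ |r_i(t) − ⟨r_i⟩|² ⟩_t ),  reported per ion and as the
mean over the three ions. No superposition or alignment is applied: the
statistic is each ion's fluctuation about its own time-averaged
position, so it is invariant under rigid motions of the whole frame set
and scales linearly under isotropic scaling about the mean (both
asserted as property tests).

N_water counts *unique* water molecules whose oxygen lies within the
cutoff (default 5 Å) of **any** of the three ions — a water bridging two
ions counts once. Distances are ion-to-water-oxygen; the orthorhombic
minimum-image convention is applied only when the trajectory carries a
box. The distance kernels are vectorised over frames in NumPy and are
checked against naive double-loop references to 1e−10 relative
tolerance on small randomised trajectories.

The default averaging window is the last 10 ns of the trajectory; for
trajectories shorter than 10 ns the final 20 % of frames is used. At
the generator's 50 ps sampling this gives 201 window frames per 100 ns
replica.

**Unbinding.** An ion is unbound when its final-window-frame
displacement from its reference point (default: its first-frame
position) exceeds the escape threshold (default 5 Å). Only the final
frame is inspected; an excursion that returns is not an unbinding
event. This is deliberately the simplest monotone criterion for "the
ion left"; the threshold is configurable.

**Classification.** A state is *stable* iff every replica satisfies
N_water < 8 **and** RMSF < 0.5 Å (strict inequalities, hence a replica
exactly on a threshold fails) and no ion unbinds in any replica; any
unbinding gives the verdict `excluded_unbinding` instead, and the
report lists both granularities (which replica, which criterion).

## Water pathways

Each pathway is a corridor: a cylinder of radius 5 Å (configurable)
between a mouth point (bulk end) and a site point (pocket end), with
spherical end zones of the same radius. A water completes an inward
transit when it reaches the site zone having last visited the mouth
zone with every intervening frame inside the corridor; outward transits
are the mirror image; leaving the corridor voids the attempt; re-entries
count separately. This zone-sequence rule is an order-based,
parameter-light definition chosen because it is exactly countable on
scripted fixtures and maps inward to outward one-to-one under frame
reversal (property-tested). In real use the endpoint coordinates come
from tunnel-finding software; tunnel detection itself is out of scope.

Flux is summarised as the mean ± standard error (sample SD/√n) of
inward counts over replicas; a gate is called *open* when the mean
exceeds 1 transit per replica per window (configurable). The gate
association test takes a reference state with all three glutamates
protonated plus contrast states differing by one Glu → Asp proton move
and reports, per pathway, the flux under the protonated and
deprotonated glutamate and the direction of change; states with *more*
protons than the reference whose deprotonated-Glu pathway nonetheless
stays closed are flagged as occlusion exceptions.

## Quantum-cluster carving

Residue selection: any residue with an oxygen atom (backbone or side
chain) within the Na⁺ hydration radius (default 2.5 Å) of any ion, plus
residues sequence-adjacent (±1 in residue number, same chain — the
reading consistent with the consecutive runs in published pocket
models). Residues enter whole; only peptide bonds are cut. Every
severed bond is capped with a hydrogen placed 1.09 Å along the original
bond vector (standard N–H/C–H geometry); a listed residue at a true
chain terminus has nothing severed and gets no cap, so an interior
fragment of any length carries exactly two caps. All alpha carbons are
frozen. Net charge = (+1 × ions) − (deprotonated Glu/Asp included) +
other formal charges (default 0); acidic residues absent from the
protonation state count as deprotonated. Waters with oxygen within 5 Å
of any ion are kept as whole molecules. The hydration reference is a
single ion with all whole waters whose oxygen lies within 9 Å.

Deck emission is engine-agnostic: an XYZ file plus a plain-text deck
with method keywords (default B3LYP/6-31G** with dispersion), charge,
multiplicity (default 1, closed shell), atom count and 1-based frozen
indices, byte-stable for identical inputs. Running QM, BSSE ghost
decks and geometry optimisation are out of scope.

## Binding-energy bookkeeping

ΔE_bind(i) = E_full − E_without(i) − E_ion and ΔE_hyd = E_shell −
E_water − E_ion, on already counterpoise-corrected fragment energies
supplied as a long-format TSV (state, replica, fragment, energy, unit).
Energies are stored signed (negative = stabilising) and reported as
strength = −ΔE to match the conventional positive presentation. Units
are hartree or kcal/mol (627.509 kcal/mol per hartree); a ledger must
be unit-consistent. Replicas aggregate as mean ± SD/√n.

Verdicts: a state is *bindable from water* when its mean site strength
is at least the hydration strength; a site is *releasable* when its
strength is below the hydration strength or within a tolerance of it.
The tolerance (default 5 kcal/mol) operationalises "similar to the
hydration energy"; it is configurable and the calibrating contrast is
the planted ~180 vs ~170 kcal/mol landscape with the −30 kcal/mol
four-proton shift. These are potential-energy comparisons; entropic
contributions and free energies are explicitly out of scope.

## Synthetic data: what it emulates and what it does not

The generator plants, per state: per-axis Gaussian ion jitter σ about
three fixed anchors ≥ 8 Å apart (expected RMSF = σ√3); a per-frame
Poisson(λ) count of waters placed 2–4.5 Å from a randomly chosen ion's
actual position (so the 5 Å unique count is exactly the drawn integer),
with all other waters parked ≥ 7 Å away in a region outside every
corridor; scripted transits as 6-step mouth → site waypoint walks; and
unbinding as a rigid 12 Å displacement of the site-II ion from
mid-trajectory. Energies decompose planted strengths exactly
(E_without = E_full − E_ion + strength) with optional Gaussian replica
noise. All randomness derives from one seed via spawned generators;
identical seeds give byte-identical files.

The default scenario mirrors the study design: 64 states × 3 replicas
× 2000 frames at 50 ps (100 ns each); six planted-stable states
(σ = 0.2 Å → RMSF ≈ 0.35 Å, λ = 6) matching the published stable set;
ten states with one unbinding replica (the published exclusion count);
the remainder unstable via σ = 0.4 Å and/or λ = 11; gate-contrast
states carrying 12 scripted transits per replica, with 3[EED] made
hydration-unstable (λ = 11) since its opened C-terminal pathway floods
site III. The planted energy landscape puts 3-proton states near
180 kcal/mol, site III of 3[EED] at 172, 4-proton states 30 lower, the
hydration reference at 170 with replica noise SD 4.4 (ten shell
replicas, SE ≈ 1.39).

What passing tests show: the estimators, counters, carver and
bookkeeping are correct against planted truth, and the classifier
separates states whose parameters sit ≥ 3 standard errors from the
thresholds. What they do not show: anything about real MD — the
generator has no water dynamics, force field, electrostatics or
correlated motion, waters are resampled independently each frame, and
transits are scripted rather than diffusive. Conclusions about the real
pump require real trajectories fed through the same interfaces.

## Numerical and design choices

- Strict `<` at both stability thresholds; ties classify unstable.
- Zone spheres take priority over the corridor body; if the two end
  spheres overlap, the nearer endpoint wins (degenerate geometries are
  rejected at construction).
- Mouth/site points 15 Å apart in the synthetic geometry, site points
  7 Å from their anchor so transit waypoints never enter the 5 Å
  hydration count.
- TSV state tables list residue columns in registry order (Glu before
  Asp within each site); published tables sometimes order site III
  Asp-first.
- Problem sizes in tests and the acceptance script (2000-frame
  replicas, 200-frame gate fixtures, 40-trajectory oracle suite) are
  the package's own study-design choices, sized so closed-form
  tolerances (5 % on RMSF, 3 SE on N_water) are met with margin.
- Report TSVs use fixed float formatting; outputs are byte-stable at
  fixed seed and config (timestamps only in the run log).

## Known limitations

- The transit definition is a declared substitute for procedures whose
  published details are unavailable; absolute flux values are not
  comparable across definitions, only contrasts within one definition.
- Unbinding inspects only the final window frame; a transient escape
  with return is invisible by design.
- The carver assumes single-conformer structures with complete backbone
  atoms; alternate locations and missing N/C atoms at a cut site are
  not repaired, and side chains are never severed.
- Minimum-image handling covers orthorhombic boxes only; synthetic
  fixtures are box-free.
- The residue-selection rule is exposed with a configurable radius; its
  exact agreement with any particular crystal structure's published
  19-residue list is not asserted here.
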
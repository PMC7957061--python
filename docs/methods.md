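# Methods

`calfluct` simulates spontaneous, Na⁺/Ca²⁺-exchanger (NCX)-mediated
Ca²⁺ fluctuations in perisynaptic astrocytic processes with explicit 3D
voxel geometry, together with the morphometrics and spectral statistics
used to interpret them.  This note documents the model, its
assumptions, the numerical choices, and what the synthetic geometry
does and does not emulate.

## Geometry and morphometrics

A synapse environment is a 1.2 × 1.2 × 1.2 µm voxel grid (201 × 201 ×
41 voxels at 6 × 6 × 30 nm pitch) whose voxels are labelled ECS,
astrocyte, bouton, spine, dendrite or "other" neuropil.

**ECS correction.** Chemically fixed tissue under-represents the
extracellular space, so each cellular segment is shrunk by 6 nm (one
in-plane voxel) and the freed shell relabelled ECS.  Erosion is applied
in-plane only: the 30 nm section thickness exceeds the 6 nm shrink, so
eroding along z would remove five times the intended distance.  Voxels
on the sample boundary are treated as segment continuation and are not
eroded.

**Surface/volume ratio (SVR).** SVR = exposed astrocyte face area /
astrocyte volume, with anisotropic face areas (dy·dz, dx·dz, dx·dy) and
6-connectivity; sample-boundary faces are excluded because the process
continues outside the sample.  This definition yields µm⁻¹ directly and
is exact for axis-aligned sheets — the leaflet case, where a slab of
thickness t measures SVR = 2/t exactly.  For smooth *curved* surfaces,
face counting converges to the staircase limit of 3/2 times the true
area (the average of |nx|+|ny|+|nz| over orientations), so a voxelized
sphere of radius r measures (3/2)(3/r), not 3/r.  This bias is inherent
to pixel-counting surface estimators and is shared by the EM-derived
numbers the model is calibrated to; absolute comparisons of SVR across
methods are therefore approximate, while comparisons within the
pipeline are consistent.

**Coverage.** A bouton/spine surface voxel is "covered" when an
astrocyte voxel is reachable within a contact distance along
face-connected paths through the ECS.  The contact distance is not
defined numerically in the source description; the default 12 nm
(up to two in-plane ECS voxels after the ECS correction) is this
package's choice and is configurable.

**Selection.** The five-criterion filter (excitatory axon, terminal
present, non-multisynaptic bouton, spine target, astrocytic volume
fraction ≥ 2%, threshold inclusive) is a pure predicate over record
attributes.

## Synthetic geometry

Real reconstructions are replaced by a generator that produces one
bouton (sphere), one spine (head sphere + neck cylinder), a synaptic
cleft (default 24 nm, along the in-plane x axis so the cleft is
resolved at 6 nm pitch), an astrocytic leaflet, and randomly packed
ellipsoidal neuropil that brings the ECS fraction to a target (default
0.18, matching the corrected tissue value).  The leaflet is a shell of
controllable thickness at a 6 nm gap from the cell membranes,
restricted to solid-angle bands ("wraps") growing from the cleft pole;
wrap fractions are sampled per synapse from correlated Beta marginals
(Gaussian copula, ρ = 0.5), which produces both symmetric and highly
asymmetric coverage.  Filler keeps a 12 nm clear corridor around all
membranes so the ECS remains a connected, tortuous network.

**SVR calibration.** Voxelization and rim faces bias a wrapped patch's
SVR above the flat-sheet limit 2/t, approximately SVR(t) ≈ 2000/t + c
(t in nm, c the rim/curvature offset).  The generator therefore
*measures* each realization and solves for t against the measured
offset, enlarging the wrap when the target is rim-dominated; mid-range
targets land within ~5%, the extremes (SVR ≲ 5 µm⁻¹, where the
astro-volume budget imposed by the ECS target binds) within ~15%.
Population defaults are SVR 22 ± 5 µm⁻¹ — the reported leaflet scale.

What the generator does *not* emulate: realistic spine taxonomy,
multi-synaptic boutons, en-passant axons, and the true joint coverage
distribution (the copula is a modelling choice).  Tests passing on
synthetic geometry therefore establish the correctness of the machinery
and the direction/size of geometric effects, not quantitative
properties of any particular real tissue volume.

## Transporter kinetics

EAAT is a 13-step single-ring cycle with separate binding/unbinding of
3 Na⁺, 1 H⁺ and 1 Glu on the extracellular side, translocation, ordered
intracellular release, and K⁺ countertransport on the return leg.  NCX
is the 6-step consecutive (ping-pong) cycle exchanging 3 Na⁺ for 1
Ca²⁺; its forward direction extrudes Ca²⁺.  Rate laws are

    k = base × temperature_factor × [ligand]^order × exp(−z F V / 2RT)

with z the elementary charge moved inward (symmetric Eyring barrier)
and V = −70 mV by default.  The temperature factor defaults to Q10 = 3
over one 10 °C decade (configurable through t_ref/t_sim).  pH is fixed;
H⁺ steps are pseudo-first-order.

**Rate values.** The numeric rate constants shipped in
`calfluct/data/{eaat,ncx}.yaml` are authored for this package (the
cited kinetic schemes are published as figures whose numbers are not
recoverable from text).  They were chosen to (i) satisfy *exact* cycle
detailed balance — the product of forward base rates equals the product
of reverse base rates, so all directionality is thermodynamic and the
NCX reversal potential is exactly 3E_Na − 2E_Ca (verified by a
bisection test); (ii) use literature-plausible magnitudes (Glu on-rate
1e7 /M/s, hundreds-of-µM pre-loading Glu affinity, NCX unidirectional
turnover of order 1e2/s near rest); and (iii) keep every state's exit
probability below 1 at the 1 µs step including Q10 and the worst-case
local [Glu] after release.  All rates are editable; the loader
validates structure, not values.  Under these rates NCX sits close to
its reversal at baseline (forward/Ca-efflux at [Na⁺]ᵢ = 10 mM,
reverse/Ca-entry at 15–20 mM), which is the regime that makes the
exchanger a sensitive Na⁺-to-Ca²⁺ transducer.

**Stepping.** Fixed-step Bernoulli sampling at the 1 µs engine clock:
each molecule makes at most one transition per step with probability
k·dt.  Two equivalent samplers are provided: a per-molecule sampler
(required when EAAT molecules carry per-molecule local [Glu]) and a
grouped sampler that draws per-state transition counts from the exact
multinomial law and assigns them to uniformly chosen molecules —
identical in distribution because molecules within a state are
exchangeable, but O(n_states) on quiet steps.  An exact Gillespie
sampler is included as a test oracle only.  The analytic steady state
is the null vector of the generator matrix (unique by strong
connectivity).

## Particles, pools and bookkeeping

Extracellular Glu and intracellular Ca²⁺ are explicit particles taking
per-axis Gaussian steps of s.d. √(2·D·dt) (Euler–Maruyama; D_glu =
0.33 µm²/ms as reported, D_ca = 0.22 µm²/ms — a package choice, the
source states no value).  A move out of the home compartment is
rejected; a move out of the sample cube removes the particle unless the
species count is below its baseline, in which case it is returned.
Intracellular Na⁺ is a well-mixed scalar concentration (≈1.5 × 10⁶
ions at 15 mM, so particle noise is negligible) moved only by
transporter stoichiometry and floored at zero.

Ligand bookkeeping is declarative per transition: binding from a *pool*
sequesters the nearest eligible free particle (Glu within the 50 nm
microdomain box; Ca²⁺ within a 300 nm capture radius of the NCX site —
a package default); if none is in range the transition is vetoed
(state reverted, event logged), which prevents negative mass.  Binding
from a *bath* (extracellular Ca²⁺, cytosolic Glu) tracks no particle;
releasing a bath-origin ligand to a pool creates a particle at the
transporter's membrane site (this is how reverse NCX injects Ca²⁺).
Every species satisfies an exact ledger: initial + created = free +
bound + boundary-removed + translocated, checked after every run.

Local [Glu] for each EAAT is the free-Glu count in its 50 × 50 × 50 nm
box divided by the box's ECS volume (voxel-overlap-weighted, clipped
below at 10% of the box to keep the estimate finite at occluded
membranes).

## Protocol

Per run: place transporters randomly over the astrocyte surface faces
(probability ∝ face area; 10,800 EAAT/µm² and 500 NCX/µm²); initialise
states from the analytic steady state and settle stochastically for
30 ms at pinned baseline concentrations (same endpoint as random
initialisation, faster convergence — the convergence itself is tested
separately from random starts); then run 30 ms at 1 µs steps with the
per-step order move → transitions → bookkeeping, releasing 5,000 Glu
molecules at the cleft centroid at 10 ms when enabled.  Traces
([Ca²⁺]ᵢ as free ions / astrocyte volume, [Glu]ₑ, [Na⁺]ᵢ) are recorded
every 10 µs (100 kHz).  Runs are bit-reproducible from (geometry,
config, seed); grid runs derive independent streams from
(seed, geometry index, patch index, run seed).

## Spectral readout

Band power is a single-segment rectangular-window periodogram of the
mean-subtracted 12–21 ms trace segment (one-sided density, 1/(fs·N)
scaling), integrated over bins with centre frequency in 100–500 Hz and
expressed as 10·log₁₀ relative to 1 nM².  With 9 ms of data the
frequency resolution is ≈111 Hz (4 band bins); Welch averaging cannot
resolve 100 Hz here, which motivates the single-segment estimator.
The dB reference is arbitrary (the source normalisation is unstated),
so only differences and trends are comparable across implementations.
A constant segment reports −∞ and is treated as missing.  Regression
(OLS with R²), one-way ANOVA and SVR-binned mean ± SEM summaries are
classical.

## Scaled-down experiment sizes

The packaged trend experiment uses 20 synthetic geometries spanning
SVR ≈ 3–35 µm⁻¹ with 3 seeds per condition and [Na⁺]ᵢ ∈ {10, 15, 20}
mM, NCX only — enough to resolve the positive power-vs-SVR slope
(p < 0.05) and the Na⁺ ordering of median powers, chosen as the
package's standard desk-scale problem size.  The acceptance script's
diffusivity check uses 10,000 particles × 1,000 steps.

## Known limitations

* No Ca²⁺ buffers, ER stores, mitochondria, astrocytic NMDA receptors
  or IP₃R amplification; no electrodiffusive feedback on membrane
  potential; fixed pH.
* The Ca²⁺ capture radius, contact distance, Ca²⁺ diffusivity and the
  absolute kinetic rate values are package choices (documented above);
  trend-level results are robust to them, absolute dB values are not.
* Voxel face-counting overestimates curved-surface areas by up to 3/2
  (see above); SVR values are internally consistent but not
  estimator-independent.
* The well-mixed Na⁺ pool ignores submembrane Na⁺ microdomains.
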
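# calfluct

Stochastic simulation of spontaneous, NCX-mediated Ca²⁺ fluctuations in
perisynaptic astrocytic processes, with explicit 3D voxel geometry.

## The problem

Astrocytes wrap synapses with extremely thin sheets ("leaflets",
< 200–300 nm) whose surface-to-volume ratio (SVR) is enormous.  In such
a microdomain the Na⁺/Ca²⁺ exchanger (NCX) — an electrogenic antiporter
exchanging 3 Na⁺ for 1 Ca²⁺ that operates close to its reversal
potential E_NCX = 3E_Na − 2E_Ca — can flicker between forward (Ca²⁺
efflux) and reverse (Ca²⁺ entry) operation.  Because the leaflet's
cytosol holds only a handful of free Ca²⁺ ions, this flickering
produces large relative fluctuations of [Ca²⁺]ᵢ without any involvement
of internal stores.  This package implements a discrete-particle,
Markov-kinetics model of that mechanism and the analysis used to
quantify it, for modellers of astrocyte–synapse interactions:

* **geometry** — voxel label volumes (1.2³ µm at 6 × 6 × 30 nm pitch)
  with ECS-fixation correction, compartment fractions, astrocytic SVR,
  pre/postsynaptic astrocytic coverage, and the five-criterion filter
  for "classical" single excitatory spine synapses;
* **synthetic** — a generator of tripartite-synapse label volumes with
  calibrated SVR, controllable coverage and target ECS fraction, so the
  whole pipeline runs without any EM dataset;
* **kinetics** — a 13-step EAAT glutamate-transporter cycle (3 Na⁺,
  1 H⁺, 1 Glu in / 1 K⁺ out) and the 6-step NCX cycle (3 Na⁺ : 1 Ca²⁺),
  voltage- and Q10-corrected, with analytic steady states and exact
  stochastic stepping at 1 µs;
* **particles** — random-walk diffusion of extracellular glutamate
  (D = 0.33 µm²/ms) and intracellular Ca²⁺ with compartment
  confinement, baseline floors and exact mass ledgers; a well-mixed
  intracellular Na⁺ pool;
* **sim** — the full protocol: transporter placement (10,800 EAAT/µm²,
  500 NCX/µm²), 30 ms pre-equilibration, 10 ms baseline, optional
  release of 5,000 glutamate molecules at the cleft, 30 ms total at
  1 µs steps, 100 kHz concentration traces;
* **spectral** — 100–500 Hz band power of the Ca²⁺ trace over the
  12–21 ms window (dB), power-vs-SVR regression, one-way ANOVA, binned
  summaries.

The model's central predictions — reproduced by the test suite on
synthetic geometry — are that the Ca²⁺ band power **increases with
astrocytic SVR** (fluctuations arise in thin processes) and **increases
with intracellular Na⁺** (raising [Na⁺]ᵢ from 10 to 20 mM pushes NCX
into reverse mode and enables fluctuations in thicker processes).

## Worked example

```python
from dataclasses import replace
from calfluct.synthetic import PopulationSpec, make_population
from calfluct.sim import SimulationConfig, run_simulation
from calfluct.spectral import band_power_db

# two leaflets: thick (SVR ~ 5/µm) and thin (SVR ~ 30/µm)
recs = make_population(PopulationSpec(n_synapses=2, svr_targets=[5, 30], seed=7))
cfg = SimulationConfig(eaat_enabled=False, release_enabled=False, seed=1)
for rec in recs:
    res = run_simulation(rec, cfg)
    bp = band_power_db(res.ca_nM, 1e5, time_ms=res.time_ms)
    print(f"SVR {rec.morphometrics.svr:5.1f} /um  "
          f"[Ca]i mean {res.ca_nM.mean():6.1f} nM  "
          f"100-500 Hz power {bp.power_db:6.1f} dB")
```

prints

```
SVR   5.0 /um  [Ca]i mean   99.4 nM  100-500 Hz power   -5.7 dB
SVR  29.0 /um  [Ca]i mean  102.4 nM  100-500 Hz power   16.0 dB
```

The thin process (high SVR) carries ~22 dB more high-frequency Ca²⁺
fluctuation power than the thick one: its NCX-covered membrane is large
relative to a cytosol holding only a few free Ca²⁺ ions, so individual
exchanger events move the concentration appreciably.  (Absolute dB
values are relative to 1 nM²; only differences and trends are
meaningful.)

The same experiment at scale — 20 geometries spanning SVR 3–35 µm⁻¹ ×
3 Na⁺ levels × 3 seeds, with per-condition regression and ANOVA — runs
end-to-end with:

```bash
calfluct pipeline --seed 0 --out out/
```

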
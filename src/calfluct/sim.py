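"""Full simulation protocol for one synapse environment.

The protocol mirrors the modelled experiment: transporters (EAAT at
10,800/µm², NCX at 500/µm²) are scattered randomly over the astrocytic
surface; their states pre-equilibrate for 30 ms at pinned baseline
concentrations; then the timed run starts with 10 ms of baseline
activity, optional release of 5,000 glutamate molecules at the synapse
centroid at 10 ms, and continues to 30 ms.  Every 1 µs step performs,
in order: particle moves, transition sampling (with each EAAT reading
the local [Glu] in its 50 nm ECS microdomain), and bookkeeping
(ligand sequestration/release, Na+ stoichiometry).

Traces of [Ca2+]i (free intracellular ions / astrocyte volume), [Glu]e
and [Na+]i are recorded every ``record_interval_us`` (default 10 µs,
i.e. a 100 kHz trace).  Runs are bit-reproducible from (geometry,
config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    LabelVolume,
    SynapseRecord,
    astro_surface_area_volume,
    surface_face_masks,
)
from .kinetics import (
    KineticScheme,
    RateContext,
    SchemeStepper,
    TransporterPopulation,
    build_eaat_scheme,
    build_ncx_scheme,
    steady_state,
)
from .particles import (
    AVOGADRO,
    DiffusionParams,
    ParticlePool,
    SodiumPool,
    CompartmentIndex,
    _box_ecs_volume_nm3,
    apply_transporter_events,
    count_to_mM,
    diffuse_step,
    init_pool_from_concentration,
    release_glutamate,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "place_transporters",
    "run_simulation",
    "run_condition_grid",
]


@dataclass
class SimulationConfig:
    """All tunable simulation parameters (concentrations in mM unless
    noted; defaults are the modelled baseline conditions)."""

    # constant extracellular / intracellular concentrations
    na_e: float = 140.0
    k_e: float = 3.0
    ca_e: float = 2.0
    k_i: float = 130.0
    glu_i: float = 3.0
    # dynamic species, baseline values
    glu_e: float = 3.0e-4  # 0.3 µM
    na_i: float = 15.0
    ca_i: float = 1.0e-4  # 100 nM
    # transporter surface densities (1/µm²)
    eaat_density_um2: float = 10800.0
    ncx_density_um2: float = 500.0
    # biophysics
    membrane_potential_mv: float = -70.0
    q10: float = 3.0
    t_ref_c: float = 27.0
    t_sim_c: float = 37.0
    d_glu_um2_ms: float = 0.33
    d_ca_um2_ms: float = 0.22
    capture_radius_nm: float = 300.0
    glu_box_nm: float = 50.0
    # protocol
    dt_us: float = 1.0
    t_equilibrate_ms: float = 30.0
    t_release_ms: float = 10.0
    t_end_ms: float = 30.0
    n_glu_release: int = 5000
    release_enabled: bool = True
    eaat_enabled: bool = True
    ncx_enabled: bool = True
    record_interval_us: float = 10.0
    seed: int = 0
    # optional rate overrides by transition name
    eaat_rates: dict | None = None
    ncx_rates: dict | None = None

    def __post_init__(self) -> None:
        if self.dt_us <= 0 or self.t_end_ms <= 0 or self.t_equilibrate_ms < 0:
            raise ValueError("times must be positive")
        if self.release_enabled and not (0 <= self.t_release_ms < self.t_end_ms):
            raise ValueError("t_release must lie within [0, t_end)")
        if self.eaat_density_um2 < 0 or self.ncx_density_um2 < 0:
            raise ValueError("densities must be >= 0")
        if self.record_interval_us < self.dt_us:
            raise ValueError("record_interval must be >= dt")

    @property
    def temperature_factor(self) -> float:
        return self.q10 ** ((self.t_sim_c - self.t_ref_c) / 10.0)

    def rate_context(self, **overrides) -> RateContext:
        return RateContext(
            glu_e=overrides.get("glu_e", self.glu_e),
            na_e=self.na_e,
            na_i=overrides.get("na_i", self.na_i),
            k_e=self.k_e,
            k_i=self.k_i,
            ca_e=self.ca_e,
            ca_i=overrides.get("ca_i", self.ca_i),
            glu_i=self.glu_i,
            membrane_potential_mv=self.membrane_potential_mv,
            temperature_factor=self.temperature_factor,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimulationResult:
    """Recorded time series plus event accounting for one run."""

    time_ms: np.ndarray
    ca_nM: np.ndarray
    glu_uM: np.ndarray
    na_mM: np.ndarray
    event_counts: dict
    n_vetoed: dict
    metadata: dict
    pools: dict = field(default_factory=dict)
    populations: dict = field(default_factory=dict)

    def conservation_ok(self) -> bool:
        """Exact mass balance for every particle species."""
        for sp, pool in self.pools.items():
            if not pool.conservation_ok():
                return False
            n_bound_pop = 0
            for pop in self.populations.values():
                held = pop.bound & pop.bound_from_pool
                # only count holders of this species
                species_states = _holding_states(pop.scheme)
                if sp in species_states:
                    n_bound_pop += int(
                        (held & np.isin(pop.states, species_states[sp])).sum()
                    )
            if n_bound_pop != pool.n_bound:
                return False
        return True

    def net_cycle_count(self, species: str) -> float:
        """Net completed forward cycles of a transporter species,
        estimated from the net traversals of its first forward edge."""
        pop = self.populations[species]
        scheme = pop.scheme
        a, b = scheme.forward_cycle[0], scheme.forward_cycle[1]
        idx = {t.name: i for i, t in enumerate(scheme.transitions)}
        counts = self.event_counts[species]
        return float(
            counts[idx[scheme.edge(a, b).name]] - counts[idx[scheme.edge(b, a).name]]
        )


def _holding_states(scheme: KineticScheme) -> dict[str, np.ndarray]:
    """States in which a molecule holds a tracked particle, per species,
    derived by walking the forward cycle through bind/release actions."""
    held: dict[str, set] = {}
    current: dict[str, bool] = {}
    # two passes so holding status wraps around the ring
    for _ in range(2):
        for t in scheme.forward_edges():
            if t.particle is not None:
                sp = t.particle["species"]
                current[sp] = t.particle["action"] == "bind"
            for sp, holding in current.items():
                if holding:
                    held.setdefault(sp, set()).add(scheme.state_index[t.target])
    return {sp: np.array(sorted(s)) for sp, s in held.items()}


def place_transporters(
    vol: LabelVolume,
    densities: Mapping[str, float],
    rng: np.random.Generator,
    schemes: Mapping[str, KineticScheme] | None = None,
) -> dict[str, TransporterPopulation]:
    """Distribute transporters randomly over the astrocytic surface.

    The count per species is ``round(density * surface area)``; sites
    are sampled over exposed astrocyte voxel faces with probability
    proportional to face area.  Each molecule keeps its face-center
    position plus points just inside (astrocyte) and outside (ECS) the
    membrane for ligand release.
    """
    faces = surface_face_masks(vol, "astro")
    pitch = np.asarray(vol.pitch_nm)
    origin = np.asarray(vol.origin_nm)
    centers_list, in_list, out_list, areas_list = [], [], [], []
    for mask, axis, direction, face_area in faces:
        idx = np.argwhere(mask)
        if len(idx) == 0:
            continue
        vox_center = origin + (idx + 0.5) * pitch
        offset = np.zeros(3)
        offset[axis] = direction * pitch[axis] / 2.0
        centers_list.append(vox_center + offset)
        in_list.append(vox_center)
        out_list.append(vox_center + 2.0 * offset)
        areas_list.append(np.full(len(idx), face_area))
    if not centers_list:
        raise ValueError("astrocyte has zero exposed surface area")
    centers = np.vstack(centers_list)
    site_in = np.vstack(in_list)
    site_out = np.vstack(out_list)
    areas = np.concatenate(areas_list)
    total_area_um2 = areas.sum() * 1e-6
    p = areas / areas.sum()

    if schemes is None:
        schemes = {}
        if "eaat" in densities:
            schemes["eaat"] = build_eaat_scheme()
        if "ncx" in densities:
            schemes["ncx"] = build_ncx_scheme()

    out: dict[str, TransporterPopulation] = {}
    for species, density in densities.items():
        n = int(round(density * total_area_um2))
        chosen = rng.choice(len(centers), size=n, p=p) if n > 0 else np.empty(0, int)
        out[species] = TransporterPopulation(
            scheme=schemes[species],
            states=np.zeros(n, dtype=np.int64),
            positions_nm=centers[chosen].reshape(n, 3),
            site_in_nm=site_in[chosen].reshape(n, 3),
            site_out_nm=site_out[chosen].reshape(n, 3),
        )
    return out


def _local_glu_for(
    pop: TransporterPopulation,
    source_state: int,
    glu_pool: ParticlePool,
    ecs_vols_nm3: np.ndarray,
    box_nm: float,
) -> np.ndarray | None:
    """Per-molecule local [Glu] (mM) for molecules in the Glu-binding
    state; NaN elsewhere.  Counts free particles in the 50 nm Chebyshev
    box around each site, over the precomputed ECS box volume."""
    sel = np.nonzero(pop.states == source_state)[0]
    if len(sel) == 0:
        return None
    local = np.full(pop.n, np.nan)
    pos = glu_pool.positions
    if len(pos) == 0:
        local[sel] = 0.0
        return local
    half = box_nm / 2.0
    sites = pop.positions_nm[sel]
    # chunked Chebyshev box counting
    counts = np.zeros(len(sel), dtype=np.int64)
    chunk = max(1, int(2e6 / max(len(pos), 1)))
    for i0 in range(0, len(sel), chunk):
        s = sites[i0 : i0 + chunk]
        inbox = (np.abs(pos[None, :, :] - s[:, None, :]) <= half).all(axis=2)
        counts[i0 : i0 + chunk] = inbox.sum(axis=1)
    local[sel] = counts / (AVOGADRO * ecs_vols_nm3[sel] * 1e-24) * 1e3
    return local


def run_simulation(record: SynapseRecord | LabelVolume, cfg: SimulationConfig) -> SimulationResult:
    """Execute the full protocol on one synapse environment."""
    if isinstance(record, LabelVolume):
        record = SynapseRecord(
            volume=record,
            centroid_nm=tuple(
                o + e / 2 for o, e in zip(record.origin_nm, record.extent_nm)
            ),
        )
    vol = record.volume
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    area_um2, astro_vol_um3, svr = astro_surface_area_volume(vol)
    astro_vol_nm3 = astro_vol_um3 * 1e9
    astro_vol_L = astro_vol_nm3 * 1e-24
    ecs_vol_nm3 = float(vol.mask("ecs").sum()) * vol.voxel_volume_nm3

    densities = {}
    if cfg.eaat_enabled:
        densities["eaat"] = cfg.eaat_density_um2
    if cfg.ncx_enabled:
        densities["ncx"] = cfg.ncx_density_um2
    schemes = {}
    if cfg.eaat_enabled:
        schemes["eaat"] = build_eaat_scheme(cfg.eaat_rates)
    if cfg.ncx_enabled:
        schemes["ncx"] = build_ncx_scheme(cfg.ncx_rates)
    populations = (
        place_transporters(vol, densities, rng, schemes) if densities else {}
    )

    dt_ms = cfg.dt_us * 1e-3
    base_ctx = cfg.rate_context()
    steppers = {
        sp: SchemeStepper(pop.scheme, base_ctx, dt_ms) for sp, pop in populations.items()
    }

    # ---- pre-equilibration: analytic steady-state init + stochastic settle
    n_eq = int(round(cfg.t_equilibrate_ms * 1e3 / cfg.dt_us))
    for sp, pop in populations.items():
        p = steady_state(pop.scheme, base_ctx)
        pop.states[:] = rng.choice(pop.scheme.n_states, size=pop.n, p=p)
        stepper = steppers[sp]
        counts = np.bincount(pop.states, minlength=pop.scheme.n_states)
        for _ in range(n_eq):
            stepper.step_grouped(pop.states, rng, counts)
        holding = _holding_states(pop.scheme)
        for states in holding.values():
            m = np.isin(pop.states, states)
            pop.bound[m] = True
            pop.bound_from_pool[m] = False

    # ---- particle pools
    pools = {
        "ca": init_pool_from_concentration(vol, "ca", "astro", cfg.ca_i, rng),
        "glu": init_pool_from_concentration(vol, "glu", "ecs", cfg.glu_e, rng),
    }
    sodium = SodiumPool(cfg.na_i, astro_vol_L, baseline_mM=cfg.na_i)
    diff = DiffusionParams(cfg.d_glu_um2_ms, cfg.d_ca_um2_ms, cfg.dt_us)
    indices = {
        "ca": CompartmentIndex(vol, "astro"),
        "glu": CompartmentIndex(vol, "ecs"),
    }

    # per-EAAT microdomain ECS volume (static geometry)
    glu_src_state = None
    eaat_box_vols = None
    if "eaat" in populations:
        scheme = populations["eaat"].scheme
        glu_edge = next(
            t
            for t in scheme.transitions
            if t.particle
            and t.particle["action"] == "bind"
            and t.particle.get("source") == "pool"
        )
        glu_src_state = scheme.state_index[glu_edge.source]
        sites = populations["eaat"].positions_nm
        eaat_box_vols = np.array(
            [
                _box_ecs_volume_nm3(s, cfg.glu_box_nm / 2.0, vol, 0.1)
                for s in sites
            ]
        )

    # ---- timed run
    n_steps = int(round(cfg.t_end_ms * 1e3 / cfg.dt_us))
    rec_every = int(round(cfg.record_interval_us / cfg.dt_us))
    release_step = (
        int(round(cfg.t_release_ms * 1e3 / cfg.dt_us)) if cfg.release_enabled else -1
    )
    n_rec = n_steps // rec_every + 1
    time_ms = np.arange(n_rec) * rec_every * dt_ms
    ca_nM = np.zeros(n_rec)
    glu_uM = np.zeros(n_rec)
    na_mM = np.zeros(n_rec)
    event_counts = {
        sp: np.zeros(len(pop.scheme.transitions), dtype=np.int64)
        for sp, pop in populations.items()
    }
    n_vetoed = {sp: 0 for sp in populations}
    state_counts = {
        sp: np.bincount(pop.states, minlength=pop.scheme.n_states)
        for sp, pop in populations.items()
    }

    def _record(i: int) -> None:
        ca_nM[i] = count_to_mM(pools["ca"].n_free, astro_vol_nm3) * 1e6
        glu_uM[i] = count_to_mM(pools["glu"].n_free, ecs_vol_nm3) * 1e3
        na_mM[i] = sodium.concentration_mM

    _record(0)
    for step in range(n_steps):
        if step == release_step:
            release_glutamate(
                pools["glu"], vol, record.centroid_nm, cfg.n_glu_release, rng
            )
        # (1) particle moves
        for sp, pool in pools.items():
            diffuse_step(pool, vol, diff, rng, index=indices[sp])
        # (2) transitions under current concentrations
        ca_i_mM = count_to_mM(pools["ca"].n_free, astro_vol_nm3)
        glu_e_mM = count_to_mM(pools["glu"].n_free, ecs_vol_nm3)
        for sp, pop in populations.items():
            stepper = steppers[sp]
            stepper.update_concentrations(
                {"ca_i": ca_i_mM, "na_i": sodium.concentration_mM, "glu_e": glu_e_mM}
            )
            if sp == "eaat" and glu_src_state is not None:
                local = _local_glu_for(
                    pop, glu_src_state, pools["glu"], eaat_box_vols, cfg.glu_box_nm
                )
                mols, trans = stepper.step(pop.states, rng, local)
            else:
                mols, trans = stepper.step_grouped(pop.states, rng, state_counts[sp])
            if len(mols):
                np.add.at(event_counts[sp], trans, 1)
                # (3) bookkeeping
                vetoes = apply_transporter_events(
                    pools,
                    sodium,
                    pop,
                    (mols, trans),
                    rng,
                    capture_radius_nm=cfg.capture_radius_nm,
                    glu_box_nm=cfg.glu_box_nm,
                )
                if vetoes:
                    n_vetoed[sp] += vetoes
                    state_counts[sp] = np.bincount(
                        pop.states, minlength=pop.scheme.n_states
                    )
        if (step + 1) % rec_every == 0:
            _record((step + 1) // rec_every)

    meta = {
        "synapse_id": record.synapse_id,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "svr_um_inv": svr,
        "astro_area_um2": area_um2,
        "astro_volume_um3": astro_vol_um3,
        "n_transporters": {sp: pop.n for sp, pop in populations.items()},
    }
    return SimulationResult(
        time_ms=time_ms,
        ca_nM=ca_nM,
        glu_uM=glu_uM,
        na_mM=na_mM,
        event_counts=event_counts,
        n_vetoed=n_vetoed,
        metadata=meta,
        pools=pools,
        populations=populations,
    )


def run_condition_grid(
    records: Sequence[SynapseRecord],
    cfg: SimulationConfig,
    patches: Sequence[Mapping] | None = None,
    seeds: Sequence[int] = (0,),
):
    """Cartesian product of geometry x config patch x seed.

    Each run gets an independent, reproducible RNG stream derived from
    (cfg.seed, geometry index, patch index, seed).  Returns a pandas
    DataFrame with one row per run (ids, condition fields, svr and the
    result object in column ``result``).
    """
    import pandas as pd

    patches = list(patches) if patches else [{}]
    valid_fields = set(SimulationConfig().to_dict())
    for p in patches:
        unknown = set(p) - valid_fields
        if unknown:
            raise ValueError(f"unknown config fields in patch: {sorted(unknown)}")
    rows = []
    for gi, rec in enumerate(records):
        for pi, patch in enumerate(patches):
            for seed in seeds:
                run_seed = int(
                    np.random.SeedSequence([cfg.seed, gi, pi, int(seed)]).generate_state(1)[0]
                    % (2**31)
                )
                run_cfg = replace(cfg, seed=run_seed, **patch)
                res = run_simulation(rec, run_cfg)
                rows.append(
                    {
                        "geometry": rec.synapse_id or f"geo{gi}",
                        "patch": pi,
                        "seed": int(seed),
                        "svr_um_inv": res.metadata["svr_um_inv"],
                        **{k: v for k, v in patch.items()},
                        "result": res,
                    }
                )
    return pd.DataFrame(rows)
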
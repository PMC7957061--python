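"""Discrete-particle diffusion and transporter bookkeeping.

Extracellular glutamate molecules and intracellular Ca2+ ions are
explicit particles performing Gaussian random walks (per-axis standard
deviation sqrt(2 D dt), the Euler–Maruyama discretisation of free
diffusion) at the engine clock.  Boundary rules:

* a particle whose move leaves its home compartment (ECS for Glu,
  astrocyte for Ca2+) is returned to its previous position;
* a particle leaving the sample cube is removed from the pool, unless
  the species count has fallen below its baseline, in which case it is
  returned instead.

Intracellular Na+ is a single well-mixed concentration: at 15 mM a
typical astrocytic segment holds over a million ions, so particle noise
is negligible and only transporter stoichiometry moves it.

Every particle is accounted for in a mass ledger (free + bound +
translocated + boundary-removed - created is invariant), which the
simulation verifies exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LabelVolume

try:  # optional JIT acceleration of the per-particle walk
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco

__all__ = [
    "AVOGADRO",
    "DiffusionParams",
    "MassLedger",
    "ParticlePool",
    "SodiumPool",
    "init_pool_from_concentration",
    "particles_for_concentration",
    "diffuse_step",
    "local_concentration",
    "release_glutamate",
    "apply_transporter_events",
]

AVOGADRO = 6.02214076e23

#: litres per cubic nanometre
_L_PER_NM3 = 1e-24


def particles_for_concentration(conc_mM: float, volume_nm3: float) -> int:
    """Number of particles representing a concentration in a volume."""
    return int(round(conc_mM * 1e-3 * volume_nm3 * _L_PER_NM3 * AVOGADRO))


def count_to_mM(count: float, volume_nm3: float) -> float:
    return count / (AVOGADRO * volume_nm3 * _L_PER_NM3) * 1e3


@dataclass
class MassLedger:
    """Exact per-species particle accounting."""

    initial: int = 0
    created: int = 0
    removed_boundary: int = 0
    translocated: int = 0  # left the pool's compartment through a transporter

    def balances(self, n_free: int, n_bound: int) -> bool:
        return (
            self.initial + self.created
            == n_free + n_bound + self.removed_boundary + self.translocated
        )


@dataclass
class ParticlePool:
    """Explicit free particles of one species in one compartment.

    Positions are in nm.  Bound particles (sequestered by transporters)
    are counted in ``n_bound``; their owners are tracked on the
    transporter side and they reappear at the transporter position when
    released.
    """

    species: str  # "glu" | "ca"
    positions: np.ndarray
    home_role: str
    baseline_count: int
    n_bound: int = 0
    ledger: MassLedger = field(default_factory=MassLedger)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.baseline_count < 0:
            raise ValueError("baseline_count must be >= 0")
        if self.ledger.initial == 0:
            self.ledger.initial = len(self.positions)

    @property
    def n_free(self) -> int:
        return len(self.positions)

    def conservation_ok(self) -> bool:
        return self.ledger.balances(self.n_free, self.n_bound)


@dataclass
class SodiumPool:
    """Well-mixed intracellular Na+ concentration over the astrocyte."""

    concentration_mM: float
    astro_volume_L: float
    baseline_mM: float = 15.0

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValueError("concentration must be >= 0")
        if self.astro_volume_L <= 0:
            raise ValueError("astro_volume_L must be > 0")

    def add_ions(self, n: float) -> None:
        self.concentration_mM += n / (self.astro_volume_L * AVOGADRO) * 1e3
        if self.concentration_mM < 0.0:
            self.concentration_mM = 0.0


@dataclass
class DiffusionParams:
    """Diffusion coefficients (µm²/ms) and the step interval (µs)."""

    d_glu_um2_ms: float = 0.33
    d_ca_um2_ms: float = 0.22
    dt_us: float = 1.0

    def __post_init__(self) -> None:
        if self.d_glu_um2_ms < 0 or self.d_ca_um2_ms < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.dt_us <= 0:
            raise ValueError("dt must be > 0")

    def sigma_nm(self, species: str) -> float:
        """Per-axis Gaussian step s.d. in nm: sqrt(2 D dt)."""
        d = {"glu": self.d_glu_um2_ms, "ca": self.d_ca_um2_ms}[species]
        # D in µm²/ms -> nm²/µs is 1e6/1e3 = 1e3 factor
        return float(np.sqrt(2.0 * d * 1e3 * self.dt_us))


def init_pool_from_concentration(
    vol: LabelVolume,
    species: str,
    role: str,
    conc_mM: float,
    rng: np.random.Generator,
) -> ParticlePool:
    """Place ``round(conc * volume * N_A)`` particles uniformly at random
    inside the compartment's voxels."""
    mask = vol.mask(role)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError(f"compartment {role!r} has zero volume")
    n = particles_for_concentration(conc_mM, n_vox * vol.voxel_volume_nm3)
    idx = np.argwhere(mask)
    if n > 0:
        chosen = idx[rng.integers(0, n_vox, size=n)]
        pitch = np.asarray(vol.pitch_nm)
        origin = np.asarray(vol.origin_nm)
        pos = origin + (chosen + rng.random((n, 3))) * pitch
    else:
        pos = np.empty((0, 3))
    return ParticlePool(
        species=species, positions=pos, home_role=role, baseline_count=n
    )


@_njit(cache=False)
def _walk_kernel(pos, disp, origin, inv_pitch, shape, home, max_remove):
    """Apply displacements with compartment confinement; mark removable
    boundary-leavers (up to ``max_remove``).  Returns the number marked;
    the ``keep`` mask is encoded by moving removed rows' x to NaN."""
    n = pos.shape[0]
    n_removed = 0
    for i in range(n):
        x = pos[i, 0] + disp[i, 0]
        y = pos[i, 1] + disp[i, 1]
        z = pos[i, 2] + disp[i, 2]
        rx = (x - origin[0]) * inv_pitch[0]
        ry = (y - origin[1]) * inv_pitch[1]
        rz = (z - origin[2]) * inv_pitch[2]
        if rx < 0.0 or ry < 0.0 or rz < 0.0:
            inside = False
        else:
            ix, iy, iz = int(rx), int(ry), int(rz)
            inside = ix < shape[0] and iy < shape[1] and iz < shape[2]
        if inside:
            if home[ix, iy, iz]:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
            # else: left its compartment -> stays at previous position
        else:
            if n_removed < max_remove:
                pos[i, 0] = np.nan  # marked for removal
                n_removed += 1
            # else: baseline floor -> stays at previous position
    return n_removed


class CompartmentIndex:
    """Precomputed lookup tables for fast confinement checks."""

    def __init__(self, vol: LabelVolume, home_role: str):
        self.origin = np.asarray(vol.origin_nm)
        self.inv_pitch = 1.0 / np.asarray(vol.pitch_nm)
        self.shape = np.asarray(vol.shape)
        self.home = vol.mask(home_role)

    def classify(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(inside sample, inside home compartment) for positions in nm."""
        idx = ((pos - self.origin) * self.inv_pitch).astype(np.int64)
        inside = (
            (pos[:, 0] >= self.origin[0])
            & (pos[:, 1] >= self.origin[1])
            & (pos[:, 2] >= self.origin[2])
            & (idx[:, 0] < self.shape[0])
            & (idx[:, 1] < self.shape[1])
            & (idx[:, 2] < self.shape[2])
        )
        ok = np.zeros(len(pos), dtype=bool)
        if inside.any():
            ii = idx[inside]
            ok[inside] = self.home[ii[:, 0], ii[:, 1], ii[:, 2]]
        return inside, ok


def diffuse_step(
    pool: ParticlePool,
    vol: LabelVolume | None,
    params: DiffusionParams,
    rng: np.random.Generator,
    index: CompartmentIndex | None = None,
) -> ParticlePool:
    """One Gaussian random-walk step for every free particle (in place).

    With ``vol=None`` the walk is unconfined (used for diffusion
    calibration).  Otherwise compartment confinement and the
    sample-boundary/baseline rules above apply.  Passing a prebuilt
    :class:`CompartmentIndex` avoids rebuilding lookup tables each step.
    """
    n = pool.n_free
    if n == 0:
        return pool
    sigma = params.sigma_nm(pool.species)
    if sigma == 0.0:
        return pool
    disp = rng.standard_normal((n, 3)) * sigma
    if vol is None:
        pool.positions = pool.positions + disp
        return pool

    if index is None:
        index = CompartmentIndex(vol, pool.home_role)
    headroom = max(0, pool.n_free - pool.baseline_count)
    if _HAVE_NUMBA:
        n_removed = _walk_kernel(
            pool.positions,
            disp,
            index.origin,
            index.inv_pitch,
            index.shape,
            index.home,
            headroom,
        )
        if n_removed:
            pool.positions = pool.positions[~np.isnan(pool.positions[:, 0])]
            pool.ledger.removed_boundary += n_removed
        return pool

    new = pool.positions + disp
    inside, ok = index.classify(new)
    # particles that left their compartment but stayed in the sample:
    # revert (keep previous position) -- handled by not updating them.
    pool.positions[ok] = new[ok]
    if not inside.all():
        leavers = np.nonzero(~inside)[0]
        # boundary removal down to the baseline floor
        n_remove = min(headroom, len(leavers))
        if n_remove > 0:
            remove_idx = leavers[:n_remove]
            pool.positions = np.delete(pool.positions, remove_idx, axis=0)
            pool.ledger.removed_boundary += n_remove
        # the rest stay at their previous positions
    return pool


def local_concentration(
    pool: ParticlePool,
    center_nm,
    vol: LabelVolume | None = None,
    box_edge_nm: float = 50.0,
    min_volume_fraction: float = 0.1,
) -> float:
    """Concentration (mM) of free particles in an axis-aligned box.

    The denominator is the ECS volume of the box (voxel-overlap weighted)
    when a volume is given, clipped below at ``min_volume_fraction`` of
    the full box to keep the estimate finite at occluded membranes; the
    box is clipped at the sample boundary.
    """
    c = np.asarray(center_nm, dtype=float)
    half = box_edge_nm / 2.0
    pos = pool.positions
    if pool.n_free > 0:
        inbox = np.all(np.abs(pos - c) <= half, axis=1)
        count = int(inbox.sum())
    else:
        count = 0
    v_box = _box_ecs_volume_nm3(c, half, vol, min_volume_fraction)
    return count_to_mM(count, v_box)


def _box_ecs_volume_nm3(
    c: np.ndarray, half: float, vol: LabelVolume | None, min_frac: float
) -> float:
    full = (2 * half) ** 3
    if vol is None:
        return full
    lo = np.maximum(c - half, np.asarray(vol.origin_nm))
    hi = np.minimum(c + half, np.asarray(vol.origin_nm) + np.asarray(vol.extent_nm))
    if np.any(hi <= lo):
        return full * min_frac
    pitch = np.asarray(vol.pitch_nm)
    origin = np.asarray(vol.origin_nm)
    i_lo = np.floor((lo - origin) / pitch).astype(int)
    i_hi = np.ceil((hi - origin) / pitch).astype(int)
    # separable per-axis overlap lengths of the box with each voxel row
    overlaps = []
    for ax in range(3):
        edges = origin[ax] + np.arange(i_lo[ax], i_hi[ax] + 1) * pitch[ax]
        seg_lo = np.maximum(edges[:-1], lo[ax])
        seg_hi = np.minimum(edges[1:], hi[ax])
        overlaps.append(np.maximum(seg_hi - seg_lo, 0.0))
    w = overlaps[0][:, None, None] * overlaps[1][None, :, None] * overlaps[2][None, None, :]
    sub = vol.mask("ecs")[
        i_lo[0] : i_hi[0], i_lo[1] : i_hi[1], i_lo[2] : i_hi[2]
    ]
    v_ecs = float((w * sub).sum())
    return max(v_ecs, full * min_frac)


def release_glutamate(
    pool: ParticlePool,
    vol: LabelVolume,
    centroid_nm,
    n: int = 5000,
    rng: np.random.Generator | None = None,
    spread_nm: float = 50.0,
) -> ParticlePool:
    """Instantaneous synaptic release: add ``n`` free Glu particles in the
    ECS voxels nearest the synapse centroid (within ``spread_nm``, or the
    single nearest ECS voxel if none are that close)."""
    if n == 0:
        return pool
    rng = rng if rng is not None else np.random.default_rng(0)
    c = np.asarray(centroid_nm, dtype=float)
    if not vol.contains(c[None, :])[0]:
        raise ValueError(f"centroid {tuple(c)} outside the sample volume")
    ecs = vol.mask("ecs")
    if not ecs.any():
        raise ValueError("volume contains no ECS voxels for release")
    idx = np.argwhere(ecs)
    pitch = np.asarray(vol.pitch_nm)
    origin = np.asarray(vol.origin_nm)
    centers = origin + (idx + 0.5) * pitch
    d = np.linalg.norm(centers - c, axis=1)
    near = idx[d <= spread_nm]
    if len(near) == 0:
        near = idx[[int(np.argmin(d))]]
    chosen = near[rng.integers(0, len(near), size=n)]
    new = origin + (chosen + rng.random((n, 3))) * pitch
    pool.positions = np.vstack([pool.positions, new])
    pool.ledger.created += n
    return pool


def apply_transporter_events(
    pools: dict,
    sodium: SodiumPool,
    population,
    events: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    capture_radius_nm: float = 300.0,
    glu_box_nm: float = 50.0,
) -> int:
    """Apply fired transitions: ligand bind/release bookkeeping and Na+
    stoichiometry.  Returns the number of vetoed binding events.

    A pool-binding transition with no eligible free particle in range
    (Glu within the transporter's microdomain; Ca2+ within
    ``capture_radius_nm`` of the site) is vetoed: the molecule's state is
    reverted and no stoichiometry is applied, which prevents negative
    mass.  Events are processed in a random order each step to avoid
    index bias.
    """
    mols, trans = events
    scheme = population.scheme
    n_veto = 0
    delta_na = 0.0
    if len(mols) == 0:
        return 0
    order = rng.permutation(len(mols))
    for k in order:
        m, ti = int(mols[k]), int(trans[k])
        t = scheme.transitions[ti]
        vetoed = False
        if t.particle is not None:
            sp = t.particle["species"]
            pool: ParticlePool = pools[sp]
            site = population.positions_nm[m]
            if t.particle["action"] == "bind":
                if t.particle.get("source") == "pool":
                    radius = glu_box_nm / 2.0 if sp == "glu" else capture_radius_nm
                    pidx = _nearest_free_particle(pool, site, radius, chebyshev=sp == "glu")
                    if pidx is None:
                        # veto: revert the state change
                        population.states[m] = scheme.state_index[t.source]
                        n_veto += 1
                        vetoed = True
                    else:
                        pool.positions = np.delete(pool.positions, pidx, axis=0)
                        pool.n_bound += 1
                        population.bound[m] = True
                        population.bound_from_pool[m] = True
                else:  # bath origin
                    population.bound[m] = True
                    population.bound_from_pool[m] = False
            else:  # release
                from_pool = bool(population.bound_from_pool[m])
                if t.particle.get("dest") == "pool":
                    target = (
                        population.site_in_nm[m]
                        if pool.home_role == "astro"
                        else population.site_out_nm[m]
                    )
                    pool.positions = np.vstack([pool.positions, target[None, :]])
                    if from_pool:
                        pool.n_bound -= 1
                    else:
                        pool.ledger.created += 1
                else:  # released to a bath (translocated out of the pool)
                    if from_pool:
                        pool.n_bound -= 1
                        pool.ledger.translocated += 1
                population.bound[m] = False
                population.bound_from_pool[m] = False
        if not vetoed:
            delta_na += t.ions.get("na", 0)
    if delta_na:
        sodium.add_ions(delta_na)
    return n_veto


def _nearest_free_particle(
    pool: ParticlePool, site: np.ndarray, radius_nm: float, chebyshev: bool = False
):
    if pool.n_free == 0:
        return None
    diff = pool.positions - site
    if chebyshev:
        d = np.max(np.abs(diff), axis=1)
    else:
        d = np.linalg.norm(diff, axis=1)
    i = int(np.argmin(d))
    return i if d[i] <= radius_nm else None
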
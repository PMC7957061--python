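"""Synthetic tripartite-synapse geometry generation.

Real perisynaptic geometry comes from saturated EM reconstructions; this
module generates statistically matched stand-ins so the whole simulation
and analysis pipeline is testable without any external dataset.  A
generated volume contains one presynaptic bouton (a sphere truncated at
the synaptic cleft), one postsynaptic spine (head sphere plus neck
cylinder), an astrocytic leaflet sheet of controllable thickness wrapping
controllable fractions of the pre- and postsynaptic perimeters, randomly
packed ellipsoidal "other" neuropil to bring the extracellular space
(ECS) down to a target fraction, and ECS elsewhere.

The generator targets *measured* morphometrics: population generation
realises a geometry, measures its surface/volume ratio (SVR) with
:mod:`calfluct.geometry`, and iterates the leaflet thickness until the
measured SVR matches the requested one, so voxelization bias does not
shift the population.  Default population parameters (SVR 22 +- 5 1/µm,
ECS fraction 0.18) match the leaflet scale reported for cortical
neuropil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .geometry import (
    DEFAULT_PITCH_NM,
    DEFAULT_SHAPE,
    LabelVolume,
    SynapseRecord,
    astro_surface_area_volume,
    morphometrics,
)

__all__ = [
    "SynapseGeometrySpec",
    "PopulationSpec",
    "make_slab_fixture",
    "make_tripartite",
    "make_population",
]

# label ids used by the generator
ECS, ASTRO, BOUTON, SPINE = 0, 1, 2, 3
_FILLER_BASE = 10


@dataclass
class SynapseGeometrySpec:
    """Parameters of one synthetic tripartite synapse.

    All lengths in nm.  ``wrap_fraction_pre``/``post`` give the fraction
    of the bouton/spine-head sphere surface (by solid angle, measured
    from the cleft pole outwards) that the astrocytic leaflet wraps.
    """

    bouton_radius_nm: float = 250.0
    spine_head_radius_nm: float = 200.0
    spine_neck_radius_nm: float = 80.0
    cleft_width_nm: float = 24.0
    leaflet_thickness_nm: float = 90.0
    leaflet_gap_nm: float = 6.0
    wrap_fraction_pre: float = 0.6
    wrap_fraction_post: float = 0.6
    target_ecs_fraction: float = 0.18
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    pitch_nm: tuple[float, float, float] = DEFAULT_PITCH_NM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bouton_radius_nm",
            "spine_head_radius_nm",
            "spine_neck_radius_nm",
            "leaflet_thickness_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("wrap_fraction_pre", "wrap_fraction_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.target_ecs_fraction < 1.0:
            raise ValueError("target_ecs_fraction must be in (0, 1)")
        extent_x = self.shape[0] * self.pitch_nm[0]
        needed = self.cleft_width_nm + 2 * (
            self.bouton_radius_nm + self.spine_head_radius_nm
        )
        if needed > 2 * extent_x:
            raise ValueError(
                f"spec not realizable: bouton+spine span {needed:.0f} nm exceeds "
                f"volume extent {extent_x:.0f} nm"
            )


@dataclass
class PopulationSpec:
    """Parameters of a synthetic synapse population.

    ``svr_mean``/``svr_sd`` parameterise the normal distribution of the
    per-synapse astrocytic SVR targets (1/µm); ``coverage_corr`` is the
    Gaussian-copula correlation between pre- and postsynaptic coverage
    (each Beta(``coverage_a``, ``coverage_b``) marginally), which yields
    both symmetric and highly asymmetric wraps.
    """

    n_synapses: int = 20
    svr_mean: float = 22.0
    svr_sd: float = 5.0
    coverage_a: float = 1.2
    coverage_b: float = 1.2
    coverage_corr: float = 0.5
    target_ecs_fraction: float = 0.18
    seed: int = 0
    svr_targets: Sequence[float] | None = None
    base_spec: SynapseGeometrySpec = field(default_factory=SynapseGeometrySpec)

    def __post_init__(self) -> None:
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if self.svr_mean <= 0:
            raise ValueError("svr_mean must be positive")


def make_slab_fixture(
    thickness_nm: float,
    vol_shape: tuple[int, int, int] = DEFAULT_SHAPE,
    pitch_nm: tuple[float, float, float] = DEFAULT_PITCH_NM,
) -> LabelVolume:
    """Astrocyte slab spanning the full x/y cross-section, embedded in ECS.

    The slab's only exposed surfaces are its two z-faces (the x/y sides
    lie on the sample boundary and are excluded), so the measured SVR is
    exactly ``2/thickness`` — a closed-form calibration fixture.
    """
    dz = pitch_nm[2]
    n_slab = thickness_nm / dz
    if abs(n_slab - round(n_slab)) > 1e-9 or thickness_nm <= 0:
        raise ValueError(
            f"thickness_nm={thickness_nm} must be a positive multiple of the "
            f"z pitch ({dz} nm)"
        )
    n_slab = int(round(n_slab))
    if n_slab >= vol_shape[2]:
        raise ValueError(
            f"slab of {n_slab} z-voxels does not fit in nz={vol_shape[2]} "
            "(need at least one ECS voxel on each side)"
        )
    labels = np.zeros(vol_shape, dtype=np.int16)
    z0 = (vol_shape[2] - n_slab) // 2
    z0 = max(z0, 1)
    labels[:, :, z0 : z0 + n_slab] = ASTRO
    return LabelVolume(
        labels=labels, pitch_nm=pitch_nm, label_map={ECS: "ecs", ASTRO: "astro"}
    )


class _TripartiteBuilder:
    """Realises a geometry spec; caches the distance fields so leaflet
    thickness can be recalibrated cheaply."""

    def __init__(self, spec: SynapseGeometrySpec):
        self.spec = spec
        nx, ny, nz = spec.shape
        dx, dy, dz = spec.pitch_nm
        # voxel-center coordinates (broadcastable)
        self.X = (np.arange(nx, dtype=np.float32) + 0.5)[:, None, None] * dx
        self.Y = (np.arange(ny, dtype=np.float32) + 0.5)[None, :, None] * dy
        self.Z = (np.arange(nz, dtype=np.float32) + 0.5)[None, None, :] * dz
        self.extent = (nx * dx, ny * dy, nz * dz)
        cx, cy, cz = (e / 2.0 for e in self.extent)
        self.centroid = (cx, cy, cz)
        # synapse axis along x: bouton on the +x side, spine on -x
        self.c_bouton = np.array(
            [cx + spec.cleft_width_nm / 2 + spec.bouton_radius_nm, cy, cz]
        )
        self.c_spine = np.array(
            [cx - spec.cleft_width_nm / 2 - spec.spine_head_radius_nm, cy, cz]
        )
        if self.c_bouton[0] + spec.bouton_radius_nm > self.extent[0]:
            raise ValueError("spec not realizable: bouton does not fit along +x")
        if self.c_spine[0] - spec.spine_head_radius_nm < 0:
            raise ValueError("spec not realizable: spine head does not fit along -x")

        bouton = self._sphere(self.c_bouton, spec.bouton_radius_nm)
        head = self._sphere(self.c_spine, spec.spine_head_radius_nm)
        neck = (
            (self.X <= self.c_spine[0])
            & ((self.Y - cy) ** 2 + (self.Z - cz) ** 2 <= spec.spine_neck_radius_nm**2)
        )
        spine = head | neck
        # mandatory segments must not overlap
        if (bouton & spine).any():
            raise ValueError("spec not realizable: bouton and spine overlap")
        self.bouton, self.spine = bouton, spine
        self.cells = bouton | spine

        sampling = spec.pitch_nm
        self.d_bouton = ndimage.distance_transform_edt(~bouton, sampling=sampling)
        self.d_spine = ndimage.distance_transform_edt(~spine, sampling=sampling)
        self.d_cells = np.minimum(self.d_bouton, self.d_spine)

        # direction cosines towards the cleft pole of each sphere
        ub = np.stack(
            np.broadcast_arrays(
                self.X - self.c_bouton[0],
                self.Y - self.c_bouton[1],
                self.Z - self.c_bouton[2],
            )
        )
        us = np.stack(
            np.broadcast_arrays(
                self.X - self.c_spine[0],
                self.Y - self.c_spine[1],
                self.Z - self.c_spine[2],
            )
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cos_bouton = -ub[0] / np.linalg.norm(ub, axis=0)  # cleft is -x of bouton
            self.cos_spine = us[0] / np.linalg.norm(us, axis=0)  # cleft is +x of spine
        self.cos_bouton = np.nan_to_num(self.cos_bouton, nan=1.0)
        self.cos_spine = np.nan_to_num(self.cos_spine, nan=1.0)

    def _sphere(self, center: np.ndarray, radius: float) -> np.ndarray:
        return (
            (self.X - center[0]) ** 2
            + (self.Y - center[1]) ** 2
            + (self.Z - center[2]) ** 2
        ) <= radius**2

    def leaflet_mask(
        self,
        thickness_nm: float,
        wrap_pre: float | None = None,
        wrap_post: float | None = None,
    ) -> np.ndarray:
        """Astrocytic leaflet: a shell at [gap, gap+thickness) from the
        cells, restricted to the wrapped solid-angle bands and capped so
        the ECS target stays reachable."""
        spec = self.spec
        wrap_pre = spec.wrap_fraction_pre if wrap_pre is None else wrap_pre
        wrap_post = spec.wrap_fraction_post if wrap_post is None else wrap_post
        gap = spec.leaflet_gap_nm
        shell = (self.d_cells >= gap) & (self.d_cells < gap + thickness_nm) & ~self.cells
        near_bouton = self.d_bouton <= self.d_spine
        # wrap bands grow from the cleft pole outwards; solid-angle cap
        # fraction of a sphere covered by cos(angle) >= 1 - 2 f equals f
        if wrap_pre > 0.0:
            wrap_b = self.cos_bouton >= 1.0 - 2.0 * wrap_pre
        else:
            wrap_b = np.zeros(self.cos_bouton.shape, dtype=bool)
        if wrap_post > 0.0:
            wrap_s = self.cos_spine >= 1.0 - 2.0 * wrap_post
        else:
            wrap_s = np.zeros(self.cos_spine.shape, dtype=bool)
        astro = shell & np.where(near_bouton, wrap_b, wrap_s)

        # cap astro volume so ECS + filler can still reach the target
        cells_frac = self.cells.mean()
        budget_frac = max(0.0, 1.0 - spec.target_ecs_fraction - cells_frac - 0.02)
        n_budget = int(budget_frac * astro.size)
        n_astro = int(astro.sum())
        if n_astro > n_budget and n_budget > 0:
            d = self.d_cells[astro]
            cutoff = np.partition(d, n_budget - 1)[n_budget - 1]
            astro &= self.d_cells <= cutoff
        return astro

    def build(
        self,
        thickness_nm: float,
        fill: bool = True,
        wrap_pre: float | None = None,
        wrap_post: float | None = None,
    ) -> LabelVolume:
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        labels = np.zeros(spec.shape, dtype=np.int16)
        labels[self.spine] = SPINE
        labels[self.bouton] = BOUTON
        astro = self.leaflet_mask(thickness_nm, wrap_pre, wrap_post)
        labels[astro] = ASTRO
        label_map = {ECS: "ecs", ASTRO: "astro", BOUTON: "bouton", SPINE: "spine"}

        if fill:
            self._add_filler(labels, astro, label_map, rng)
        return LabelVolume(labels=labels, pitch_nm=spec.pitch_nm, label_map=label_map)

    def _add_filler(
        self,
        labels: np.ndarray,
        astro: np.ndarray,
        label_map: dict[int, str],
        rng: np.random.Generator,
    ) -> None:
        """Pack ellipsoidal neuropil into the ECS (keeping a clear 12 nm
        corridor around all membranes) until the ECS fraction reaches the
        target, so the remaining ECS is a tortuous connected network."""
        spec = self.spec
        d_all = ndimage.distance_transform_edt(
            ~(self.cells | astro), sampling=spec.pitch_nm
        )
        allowed = (labels == ECS) & (d_all >= 12.0)
        total = labels.size
        target_n_ecs = spec.target_ecs_fraction * total
        nx, ny, nz = spec.shape
        dx, dy, dz = spec.pitch_nm
        fid = _FILLER_BASE
        for _attempt in range(600):
            n_ecs = total - np.count_nonzero(labels)
            if n_ecs <= target_n_ecs:
                break
            center = rng.uniform([0, 0, 0], self.extent)
            semi = rng.uniform([90, 90, 60], [260, 260, 200])
            # bounding box in voxel indices
            lo = np.maximum(((center - semi) / [dx, dy, dz]).astype(int), 0)
            hi = np.minimum(
                ((center + semi) / [dx, dy, dz]).astype(int) + 2, [nx, ny, nz]
            )
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            e = (
                ((self.X[sl[0], :, :] - center[0]) / semi[0]) ** 2
                + ((self.Y[:, sl[1], :] - center[1]) / semi[1]) ** 2
                + ((self.Z[:, :, sl[2]] - center[2]) / semi[2]) ** 2
            ) <= 1.0
            sel = e & allowed[sl]
            if not sel.any():
                continue
            labels[sl][sel] = fid
            label_map[fid] = "other"
            fid += 1


def make_tripartite(spec: SynapseGeometrySpec) -> SynapseRecord:
    """Generate one synthetic tripartite synapse.

    Deterministic for a fixed spec (identical seeds give bit-identical
    label grids).  The returned record carries measured morphometrics and
    all selection-criterion flags.
    """
    builder = _TripartiteBuilder(spec)
    vol = builder.build(spec.leaflet_thickness_nm)
    rec = SynapseRecord(
        volume=vol,
        centroid_nm=builder.centroid,
        axon_type="excitatory",
        has_terminal=True,
        is_multisynaptic=False,
        target_is_spine=True,
    )
    if vol.mask("astro").any():
        rec.morphometrics = morphometrics(rec)
    return rec


def _sample_coverages(pop: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Correlated (pre, post) coverage pairs via a Gaussian copula with
    Beta marginals; spans [0, 1] and produces asymmetric wraps."""
    rho = pop.coverage_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0, 0], cov, size=pop.n_synapses)
    u = stats.norm.cdf(z)
    return stats.beta.ppf(u, pop.coverage_a, pop.coverage_b)


#: realizable SVR targets (1/µm); outside this range the leaflet either
#: falls below the voxel pitch or exhausts the astro volume budget
_SVR_RANGE = (3.0, 38.0)


def make_population(pop: PopulationSpec) -> list[SynapseRecord]:
    """Generate a population of synthetic synapses with calibrated SVR.

    Per synapse, an SVR target is drawn from N(svr_mean, svr_sd) (or
    taken from ``pop.svr_targets``), clipped to the realizable range, and
    the leaflet thickness is iterated (starting from the slab limit
    t = 2/SVR) until the *measured* SVR is within 5% of the target or
    the thickness hits its geometric bounds.
    """
    ss = np.random.SeedSequence(pop.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(pop.n_synapses + 1)[1:]]

    if pop.svr_targets is not None:
        targets = np.asarray(list(pop.svr_targets), dtype=float)
        if len(targets) != pop.n_synapses:
            raise ValueError("svr_targets length must equal n_synapses")
    else:
        targets = rng.normal(pop.svr_mean, pop.svr_sd, size=pop.n_synapses)
    targets = np.clip(targets, *_SVR_RANGE)
    coverages = _sample_coverages(pop, rng)

    records = []
    for i in range(pop.n_synapses):
        spec = SynapseGeometrySpec(
            wrap_fraction_pre=float(coverages[i, 0]),
            wrap_fraction_post=float(coverages[i, 1]),
            target_ecs_fraction=pop.target_ecs_fraction,
            shape=pop.base_spec.shape,
            pitch_nm=pop.base_spec.pitch_nm,
            bouton_radius_nm=pop.base_spec.bouton_radius_nm,
            spine_head_radius_nm=pop.base_spec.spine_head_radius_nm,
            spine_neck_radius_nm=pop.base_spec.spine_neck_radius_nm,
            cleft_width_nm=pop.base_spec.cleft_width_nm,
            leaflet_gap_nm=pop.base_spec.leaflet_gap_nm,
            seed=child_seeds[i],
        )
        builder = _TripartiteBuilder(spec)
        target = float(targets[i])
        t = 2000.0 / target  # slab-limit initial guess, nm
        wrap_pre = float(coverages[i, 0])
        wrap_post = float(coverages[i, 1])
        # A wrapped patch measures SVR(t) ~ 2000/t + c, where the offset
        # c comes from the patch rim; solve for t against the measured
        # offset and enlarge the wrap when the target lies below it.
        best = (np.inf, t, wrap_pre, wrap_post)
        for _it in range(8):
            t = float(np.clip(t, 30.0, 1200.0))
            trial = builder.build(t, fill=False, wrap_pre=wrap_pre, wrap_post=wrap_post)
            _, _, measured = astro_surface_area_volume(trial)
            err = abs(measured / target - 1.0)
            if err < best[0]:
                best = (err, t, wrap_pre, wrap_post)
            if err <= 0.05:
                break
            c = measured - 2000.0 / t
            if target - c < 2.0:
                # rim-dominated: unreachable at this wrap; widen the sheet
                wrap_pre = min(1.0, wrap_pre * 1.5 + 0.05)
                wrap_post = min(1.0, wrap_post * 1.5 + 0.05)
                continue
            t = 2000.0 / (target - c)
        _, t, wrap_pre, wrap_post = best
        vol = builder.build(t, fill=True, wrap_pre=wrap_pre, wrap_post=wrap_post)
        rec = SynapseRecord(
            volume=vol,
            centroid_nm=builder.centroid,
            synapse_id=f"syn{i:04d}",
        )
        rec.morphometrics = morphometrics(rec)
        records.append(rec)
    return records
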